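"""Bitmask kernel shared by the exhaustive searches and the simulation.

A family of c-tuples over n taxa is one integer: bit i is set when the
i-th tuple (in colex order) is induced.  The four-way partition property
then reduces to AND-tests against precomputed per-partition cover masks,
and fixing-taxon traceability to a fixpoint over the (c+1)-cliques of the
overlap graph.  The fixpoint whitens a gray tuple whenever it is the only
gray vertex of some clique -- exactly the condition under which the
clique's off-tuple taxon is a fixing taxon -- so its outcome coincides
with the queue-driven coloring algorithm (whose final coloring is order
independent).
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations
from math import comb


def ctuples_colex(n: int, c: int) -> list[tuple[int, ...]]:
    """All c-subsets of range(n) in colexicographic order."""
    return sorted(combinations(range(n), c), key=lambda t: t[::-1])


def rgs_four_blocks(n: int):
    """Assignment arrays of the 4-block set partitions of range(n)."""
    a = [0] * n

    def rec(i: int, mx: int):
        if i == n:
            if mx == 3:
                yield tuple(a)
            return
        top = min(mx + 1, 3)
        for b in range(top + 1):
            nmx = mx if b <= mx else b
            if 3 - nmx <= n - i - 1:
                a[i] = b
                yield from rec(i + 1, nmx)

    yield from rec(1, 0)


class TupleKernel:
    """Precomputed structures for fixed (n, c)."""

    def __init__(self, n: int, c: int = 4):
        if not 1 <= c <= n:
            raise ValueError("need 1 <= c <= n")
        self.n = n
        self.c = c
        self.tuples = ctuples_colex(n, c)
        self.total = len(self.tuples)
        self.full_mask = (1 << self.total) - 1
        self.index = {t: i for i, t in enumerate(self.tuples)}
        # one clique per (c+1)-subset of the taxa
        self.cliques: list[list[int]] = [
            [self.index[sub] for sub in combinations(s, c)]
            for s in combinations(range(n), c + 1)
        ]
        self._cover_masks: list[int] | None = None

    # -- decisiveness (c = 4 only) ------------------------------------

    def cover_masks(self) -> list[int]:
        """For each 4-partition, the mask of quadruples covering it."""
        if self.c != 4:
            raise ValueError("partition coverage is defined for c = 4")
        if self._cover_masks is None:
            masks = []
            for assignment in rgs_four_blocks(self.n):
                m = 0
                for i, t in enumerate(self.tuples):
                    if len({assignment[x] for x in t}) == 4:
                        m |= 1 << i
                masks.append(m)
            self._cover_masks = masks
        return self._cover_masks

    def is_decisive(self, mask: int) -> bool:
        """Four-way partition property of the quadruple family `mask`."""
        for m in self.cover_masks():
            if not mask & m:
                return False
        return True

    # -- traceability --------------------------------------------------

    def trace_fixpoint(self, mask: int) -> int:
        """Final white mask after iterated fixing-taxon resolution."""
        full = self.full_mask
        if mask == full or mask == 0:
            return mask
        changed = True
        while changed and mask != full:
            changed = False
            for members in self.cliques:
                gray = -1
                count = 0
                for i in members:
                    if not (mask >> i) & 1:
                        count += 1
                        if count > 1:
                            break
                        gray = i
                if count == 1:
                    mask |= 1 << gray
                    changed = True
        return mask

    def is_traceable(self, mask: int) -> bool:
        return self.trace_fixpoint(mask) == self.full_mask

    def resolved_count(self, mask: int) -> int:
        return (self.trace_fixpoint(mask) ^ mask).bit_count()

    # -- helpers --------------------------------------------------------

    def mask_of_index_tuples(self, tuples) -> int:
        m = 0
        for t in tuples:
            m |= 1 << self.index[tuple(sorted(t))]
        return m

    def subsets_of_size(self, k: int):
        """Masks of all k-subsets of the tuple family, one bit set each."""
        for combo in combinations(range(self.total), k):
            m = 0
            for i in combo:
                m |= 1 << i
            yield m

    def count_subsets(self, k: int) -> int:
        return comb(self.total, k)


@lru_cache(maxsize=32)
def kernel(n: int, c: int = 4) -> TupleKernel:
    return TupleKernel(n, c)
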