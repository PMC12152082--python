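"""Exact decisiveness decisions.

A collection S of taxon sets is phylogenetically decisive (unrooted) iff
every partition of X into four non-empty blocks is covered by an induced
quadruple with one member per block -- the four-way partition property.
The checker here is the exhaustive inner loop of the package: it iterates
the S2(n, 4) partitions, short-circuiting at the first uncovered one,
which then serves as a witness of non-decisiveness.

In the rooted setting decisiveness degenerates: it holds iff *all* C(n,3)
triples are induced, which is a polynomial count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import comb

from ._fast import kernel
from .combinatorics import (
    FourPartition,
    TaxonSetCollection,
    TaxonUniverse,
    induced_ctuples,
)

__all__ = [
    "DecisivenessReport",
    "is_decisive_unrooted",
    "is_decisive_rooted",
    "min_decisive_size_exhaustive",
    "max_nondecisive_size_exhaustive",
    "EXHAUSTIVE_GUARD_N",
]

#: largest n for which the subset-sweep searches run without `force`
EXHAUSTIVE_GUARD_N = 6


@dataclass(frozen=True)
class DecisivenessReport:
    """Outcome of the four-way partition check.

    `witness` is the first uncovered partition in canonical enumeration
    order when the collection is not decisive, else None.
    """

    decisive: bool
    witness: FourPartition | None
    partitions_checked: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "decisive": self.decisive,
                "witness_blocks": None
                if self.witness is None
                else [list(b) for b in self.witness.blocks],
                "partitions_checked": self.partitions_checked,
            }
        )


def is_decisive_unrooted(S: TaxonSetCollection) -> DecisivenessReport:
    """Check the four-way partition property of S.

    Operates on the induced quadruples of S, so member sets of any size
    are accepted (a 5-set contributes five quadruples).  Deterministic:
    the witness, if any, is the first uncovered partition in canonical
    order.
    """
    U = S.universe
    if U.n < 4:
        raise ValueError("unrooted decisiveness needs at least 4 taxa")
    quads = induced_ctuples(S, 4).as_index_sets()
    from ._fast import rgs_four_blocks

    checked = 0
    for assignment in rgs_four_blocks(U.n):
        checked += 1
        covered = False
        for t in quads:
            if len({assignment[i] for i in t}) == 4:
                covered = True
                break
        if not covered:
            blocks: list[list[str]] = [[], [], [], []]
            for idx, b in enumerate(assignment):
                blocks[b].append(U.labels[idx])
            witness = FourPartition(tuple(tuple(b) for b in blocks))
            return DecisivenessReport(False, witness, checked)
    return DecisivenessReport(True, None, checked)


def is_decisive_rooted(S: TaxonSetCollection) -> bool:
    """Rooted decisiveness: all C(n, 3) triples must be induced."""
    n = S.universe.n
    if n < 3:
        raise ValueError("rooted decisiveness needs at least 3 taxa")
    return len(induced_ctuples(S, 3)) == comb(n, 3)


def _guard(U: TaxonUniverse, force: bool) -> None:
    if U.n > EXHAUSTIVE_GUARD_N and not force:
        raise ValueError(
            f"exhaustive subset search over C({U.n},4) quadruples is "
            f"refused for n > {EXHAUSTIVE_GUARD_N}; pass force=True to "
            "override"
        )


def min_decisive_size_exhaustive(
    U: TaxonUniverse, force: bool = False
) -> int:
    """Least k such that some k-subset of quadruples is decisive.

    Searches sizes ascending, subsets in canonical (colex) order, so the
    answer is the minimum over *all* quadruple subsets of X.
    """
    if U.n < 4:
        raise ValueError("need at least 4 taxa")
    _guard(U, force)
    ker = kernel(U.n, 4)
    for k in range(1, ker.total + 1):
        for mask in ker.subsets_of_size(k):
            if ker.is_decisive(mask):
                return k
    raise RuntimeError("unreachable: the full quadruple set is decisive")


def max_nondecisive_size_exhaustive(
    U: TaxonUniverse, force: bool = False
) -> int:
    """Greatest k such that some k-subset of quadruples is non-decisive.

    Equals f_n - 1 = C(n,4) - (n-4) - 1: above that threshold every
    quadruple family is decisive.  Because decisiveness is monotone under
    adding quadruples, the search walks k downward and stops at the first
    size admitting a failure.
    """
    if U.n < 4:
        raise ValueError("need at least 4 taxa")
    _guard(U, force)
    ker = kernel(U.n, 4)
    for k in range(ker.total, -1, -1):
        for mask in ker.subsets_of_size(k):
            if not ker.is_decisive(mask):
                return k
    raise RuntimeError("unreachable: the empty set is non-decisive for n >= 4")
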