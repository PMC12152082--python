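"""Fixing-taxon detection and the iterative coloring decision procedure.

A cross c-tuple C has a *fixing taxon* x when every tuple obtained by
swapping one member of C for x is induced; the five tuples over C u {x}
then pin down the resolution of C in every supertree.  Resolution is
iterative: once a cross tuple is resolved ("whitened") it can in turn
supply fixing taxa for others.  A collection is *fixing taxon
c-traceable* when this process whitens every cross c-tuple; for c = 4
traceability implies phylogenetic decisiveness and -- unlike decisiveness
itself -- is decidable in polynomial time.

The decision procedure processes a queue of newly-whitened tuples: for a
white tuple C and an outside taxon x, the c-tuples within C u {x} form a
complete (c+1)-clique of the overlap graph; if exactly one of them is
gray, the clique's off-taxon fixes it.  Every whitening is logged, so the
returned certificate can be replayed and independently validated.
"""

from __future__ import annotations

import json
import random
from collections import deque
from dataclasses import dataclass
from itertools import combinations
from math import comb

import networkx as nx

from ._fast import kernel
from .combinatorics import (
    CTuple,
    CTupleSet,
    TaxonSetCollection,
    TaxonUniverse,
    induced_ctuples,
)

__all__ = [
    "TraceStep",
    "TraceCertificate",
    "fixing_taxa",
    "trace",
    "is_ftt",
    "min_ftt_size_exhaustive",
    "colored_overlap_graph",
]


@dataclass(frozen=True)
class TraceStep:
    """One whitening: which tuple was resolved, by which fixing taxon."""

    resolved_tuple: CTuple
    fixing_taxon: str
    step_index: int


@dataclass(frozen=True)
class TraceCertificate:
    """Ordered resolution log of the coloring run.

    `traceable` holds iff every initial cross tuple was resolved, i.e.
    resolved_count == initial_cross_count.  `replay` revalidates every
    step's fixing-taxon condition from the initial coloring.
    """

    universe: TaxonUniverse
    c: int
    steps: tuple[TraceStep, ...]
    traceable: bool
    initial_cross_count: int

    @property
    def resolved_count(self) -> int:
        return len(self.steps)

    def replay(self, S: TaxonSetCollection) -> bool:
        """Re-run the log from the initial coloring of S, checking each
        step's fixing-taxon condition; True iff every step is valid."""
        white = {t.as_set() for t in induced_ctuples(S, self.c)}
        for step in self.steps:
            tup = step.resolved_tuple.as_set()
            if tup in white or step.fixing_taxon in tup:
                return False
            for member in tup:
                swapped = tup - {member} | {step.fixing_taxon}
                if swapped not in white:
                    return False
            white.add(tup)
        return True

    def to_json(self) -> str:
        return json.dumps(
            {
                "traceable": self.traceable,
                "initial_cross_count": self.initial_cross_count,
                "resolved_count": self.resolved_count,
                "steps": [
                    {
                        "tuple": list(s.resolved_tuple.members),
                        "fixing_taxon": s.fixing_taxon,
                        "index": s.step_index,
                    }
                    for s in self.steps
                ],
            }
        )


def fixing_taxa(C: CTuple, white: CTupleSet) -> set[str]:
    """Every taxon x outside C whose c member swaps all land in `white`.

    `white` is the current set of resolved tuples (initially the induced
    tuples of the collection); C must be unresolved with respect to it.
    """
    if C in white:
        raise ValueError("tuple is already resolved w.r.t. this white set")
    U = white.universe
    members = C.as_set()
    white_sets = {t.as_set() for t in white}
    found: set[str] = set()
    for x in U.labels:
        if x in members:
            continue
        if all(
            (members - {m} | {x}) in white_sets for m in members
        ):
            found.add(x)
    return found


def trace(
    S: TaxonSetCollection,
    c: int = 4,
    shuffle_seed: int | None = None,
) -> TraceCertificate:
    """Run the iterative coloring and return its resolution certificate.

    White tuples start as the induced c-tuples of S, gray as the cross
    tuples; every white tuple enters a FIFO queue.  For a dequeued tuple
    C and each taxon x outside C, the c+1 tuples within C u {x} form a
    clique; if exactly one is gray it is whitened (its fixing taxon is
    the clique taxon it lacks), logged and enqueued.  The final coloring
    is independent of the processing order; `shuffle_seed` permutes the
    initial queue and taxon scan to exercise exactly that invariant.
    """
    U = S.universe
    n = U.n
    if c > n:
        raise ValueError("tuple size c exceeds the number of taxa")
    induced = {t.as_set() for t in induced_ctuples(S, c)}
    all_tuples = [frozenset(t) for t in combinations(U.labels, c)]
    gray = {t for t in all_tuples if t not in induced}
    initial_cross = len(gray)
    total = comb(n, c)

    queue = deque(
        t.as_set() for t in induced_ctuples(S, c)
    )  # colex order
    taxon_order = list(U.labels)
    if shuffle_seed is not None:
        rng = random.Random(shuffle_seed)
        perm = list(queue)
        rng.shuffle(perm)
        queue = deque(perm)
        rng.shuffle(taxon_order)

    counter = total - initial_cross
    steps: list[TraceStep] = []
    while counter < total and queue:
        current = queue.popleft()
        for x in taxon_order:
            if x in current:
                continue
            clique_taxa = current | {x}
            gray_found = None
            gray_count = 0
            for out in clique_taxa:
                member = clique_taxa - {out}
                if member in gray:
                    gray_count += 1
                    if gray_count > 1:
                        break
                    gray_found = member
            if gray_count == 1 and gray_found is not None:
                (fixer,) = clique_taxa - gray_found
                gray.remove(gray_found)
                steps.append(
                    TraceStep(
                        CTuple.of(U, gray_found), fixer, len(steps) + 1
                    )
                )
                queue.append(gray_found)
                counter += 1
    return TraceCertificate(
        universe=U,
        c=c,
        steps=tuple(steps),
        traceable=counter == total,
        initial_cross_count=initial_cross,
    )


def is_ftt(S: TaxonSetCollection, c: int = 4) -> bool:
    """Fixing taxon c-traceability of S (c = 4: 'fixing taxon traceable')."""
    return trace(S, c).traceable


def min_ftt_size_exhaustive(
    U: TaxonUniverse, c: int = 4, force: bool = False
) -> int:
    """Least k such that some k-subset of c-tuples is traceable.

    Equals C(n-1, c-1), attained by the star of tuples through one taxon;
    here it is recomputed by exhaustive ascending search.
    """
    if U.n < c:
        raise ValueError("need at least c taxa")
    if U.n > 6 and not force:
        raise ValueError(
            "exhaustive subset search is refused for n > 6; "
            "pass force=True to override"
        )
    ker = kernel(U.n, c)
    for k in range(1, ker.total + 1):
        for mask in ker.subsets_of_size(k):
            if ker.is_traceable(mask):
                return k
    raise RuntimeError("unreachable: the full tuple set is traceable")


def max_decisive_not_ftt_exhaustive(
    U: TaxonUniverse, force: bool = False
) -> int:
    """Greatest quadruple count among families on X that satisfy the
    four-way partition property but are not traceable.

    Sweeps subset sizes downward, classifying every k-subset with both
    checkers until a size admits a decisive non-traceable family; sizes
    above the answer are checked exhaustively, so the result is exact.
    Returns 0 when no such family exists (n < 6).
    """
    if U.n < 4:
        raise ValueError("need at least 4 taxa")
    if U.n > 6 and not force:
        raise ValueError(
            "exhaustive subset search is refused for n > 6; "
            "pass force=True to override"
        )
    ker = kernel(U.n, 4)
    for k in range(ker.total, 0, -1):
        for mask in ker.subsets_of_size(k):
            if not ker.is_traceable(mask) and ker.is_decisive(mask):
                return k
    return 0


def colored_overlap_graph(
    S: TaxonSetCollection, c: int = 4, taxa=None
) -> nx.Graph:
    """Overlap graph restricted to `taxa`, vertices colored by S.

    Induced tuples are 'white', cross tuples 'gray' -- the initial state
    of the coloring algorithm, suitable for DOT/GraphML export.
    """
    from .combinatorics import restrict_overlap_graph

    U = S.universe
    if taxa is None:
        taxa = U.labels
    g = restrict_overlap_graph(U, c, taxa)
    induced = {t.as_set() for t in induced_ctuples(S, c)}
    for node in g.nodes:
        g.nodes[node]["color"] = (
            "white" if node.as_set() in induced else "gray"
        )
    return g
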