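"""Extremal families and embedded worked-example fixtures.

Three constructions bracket the gap between traceability and
decisiveness:

* the *star* of all c-tuples through one taxon -- the smallest traceable
  family, C(n-1, c-1) tuples, the center fixes every cross tuple;
* the *recursive decisive family* -- C(n-1,3) - 1 quadruples that are
  decisive but not traceable, grown from a 9-quadruple seed on 6 taxa by
  adding every quadruple through the pair {1, counter};
* the *maximal decisive-not-traceable family* -- C(n,4) - 3n + 13
  quadruples, grown from a 10-quadruple seed whose cross quadruples form
  a 5-cycle in the overlap graph; adding any single cross quadruple
  makes it traceable.

The fixtures map holds the worked example collections verbatim.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

from .combinatorics import TaxonSetCollection, TaxonUniverse

__all__ = [
    "star_construction",
    "algorithm2",
    "algorithm3",
    "fixtures",
    "ALG3_BASE_CROSS",
]


def star_construction(
    U: TaxonUniverse, c: int = 4, center: str | None = None
) -> TaxonSetCollection:
    """All c-tuples containing `center` (default: the last taxon).

    C(n-1, c-1) tuples; traceable for every n >= c, since the center is
    a fixing taxon for every cross tuple.
    """
    if c > U.n:
        raise ValueError("tuple size c exceeds the number of taxa")
    if center is None:
        center = U.labels[-1]
    if center not in U:
        raise ValueError(f"center taxon {center!r} is not in the universe")
    rest = [x for x in U.labels if x != center]
    sets = [
        U.sort_labels(combo + (center,))
        for combo in combinations(rest, c - 1)
    ]
    sets.sort(key=lambda t: tuple(reversed([U.index(x) for x in t])))
    return TaxonSetCollection(U, tuple(frozenset(s) for s in sets))


# the 9-quadruple decisive, non-traceable seed on {1..6}
_ALG2_BASE = [
    (1, 2, 3, 5),
    (1, 2, 4, 5),
    (1, 2, 4, 6),
    (1, 3, 4, 6),
    (1, 3, 5, 6),
    (1, 4, 5, 6),
    (2, 3, 4, 5),
    (2, 3, 4, 6),
    (2, 3, 5, 6),
]


def algorithm2(n: int) -> TaxonSetCollection:
    """Recursive decisive-but-not-traceable family on n >= 6 taxa.

    Starts from the 9-quadruple seed on {1..6}; for counter = 7..n adds
    every quadruple {1, a, b, counter} with a < b from {2..counter-1}.
    Output size: C(n-1, 3) - 1.  Taxon 1 fixes all quadruples through
    the new taxon, which keeps the family decisive at every step, yet it
    stays below the C(n-1,3) traceability threshold.
    """
    if n < 6:
        raise ValueError("the recursive construction needs n >= 6")
    quads = [tuple(q) for q in _ALG2_BASE]
    for counter in range(7, n + 1):
        for a, b in combinations(range(2, counter), 2):
            quads.append((1, a, b, counter))
    assert len(quads) == comb(n - 1, 3) - 1
    return TaxonSetCollection.of_integers(quads, n)


#: the five cross quadruples of the 10-quadruple seed on {1..6}
ALG3_BASE_CROSS = [
    (1, 2, 5, 6),
    (2, 3, 5, 6),
    (2, 3, 4, 6),
    (1, 3, 4, 6),
    (1, 4, 5, 6),
]


def algorithm3(n: int) -> TaxonSetCollection:
    """Maximal decisive-but-not-traceable family on n >= 6 taxa.

    Starts from the 10 quadruples of {1..6} whose complement is the
    5-cycle of cross quadruples in `ALG3_BASE_CROSS`; for counter = 7..n
    adds every quadruple containing the new taxon except
    {2,5,6,counter}, {3,4,6,counter} and {4,5,6,counter} -- the three
    omissions that stop the new taxon from fixing any old cross
    quadruple.  Output size: C(n, 4) - 3n + 13; adding any single cross
    quadruple makes the family traceable.
    """
    if n < 6:
        raise ValueError("the maximal construction needs n >= 6")
    blocked = set(ALG3_BASE_CROSS)
    quads = [
        q for q in combinations(range(1, 7), 4) if q not in blocked
    ]
    for counter in range(7, n + 1):
        skip = {
            (2, 5, 6, counter),
            (3, 4, 6, counter),
            (4, 5, 6, counter),
        }
        for trio in combinations(range(1, counter), 3):
            q = trio + (counter,)
            if q not in skip:
                quads.append(q)
    assert len(quads) == comb(n, 4) - 3 * n + 13
    return TaxonSetCollection.of_integers(quads, n)


_FIXTURES: dict[str, tuple[int, list[tuple[int, ...]]]] = {
    # decisive with exactly one cross quadruple ({1,2,4,5}; taxon 3 fixes it)
    "ex2.5": (
        5,
        [(1, 2, 3, 4), (1, 2, 3, 5), (1, 3, 4, 5), (2, 3, 4, 5)],
    ),
    # 11 quadruples, four cross quadruples, traceable
    "ex3.3": (
        6,
        [
            (1, 2, 3, 5),
            (1, 2, 4, 5),
            (1, 2, 4, 6),
            (1, 2, 5, 6),
            (1, 2, 3, 6),
            (1, 3, 4, 6),
            (1, 3, 5, 6),
            (1, 4, 5, 6),
            (2, 3, 4, 5),
            (2, 3, 5, 6),
            (2, 3, 4, 6),
        ],
    ),
    # 9 quadruples, decisive, none of its six cross quadruples has a
    # fixing taxon: the canonical decisive-not-traceable family
    "ex3.10": (6, list(_ALG2_BASE)),
    # rooted setting: three of the four triples on {1..4}
    "ex3.19": (4, [(1, 2, 4), (1, 3, 4), (2, 3, 4)]),
    # 14 quadruples on 7 taxa, decisive, not traceable
    "ex3.23i": (
        7,
        [
            (1, 2, 3, 4),
            (1, 2, 5, 6),
            (1, 3, 5, 7),
            (1, 4, 6, 7),
            (3, 4, 5, 6),
            (2, 4, 5, 7),
            (2, 3, 6, 7),
            (1, 2, 4, 6),
            (1, 2, 5, 7),
            (1, 3, 4, 5),
            (1, 3, 6, 7),
            (4, 5, 6, 7),
            (2, 3, 5, 6),
            (2, 3, 4, 7),
        ],
    ),
    # 26 quadruples on 8 taxa, decisive, not traceable
    "ex3.23ii": (
        8,
        [
            (1, 2, 5, 6),
            (1, 2, 7, 8),
            (1, 3, 5, 7),
            (1, 3, 6, 8),
            (1, 4, 5, 8),
            (1, 4, 6, 7),
            (3, 4, 7, 8),
            (3, 4, 5, 6),
            (2, 4, 6, 8),
            (2, 4, 5, 7),
            (2, 3, 6, 7),
            (2, 3, 5, 8),
            (1, 2, 3, 8),
            (1, 2, 4, 6),
            (1, 2, 5, 7),
            (1, 3, 4, 5),
            (1, 3, 6, 7),
            (1, 4, 7, 8),
            (1, 5, 6, 8),
            (4, 5, 6, 7),
            (3, 5, 7, 8),
            (3, 4, 6, 8),
            (2, 6, 7, 8),
            (2, 4, 5, 8),
            (2, 3, 5, 6),
            (2, 3, 4, 7),
        ],
    ),
}
_FIXTURES["ex3.8"] = _FIXTURES["ex3.3"]  # same collection, later episode


def fixtures() -> dict[str, TaxonSetCollection]:
    """The worked-example collections, keyed by example number."""
    return {
        name: TaxonSetCollection.of_integers(quads, n)
        for name, (n, quads) in _FIXTURES.items()
    }
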