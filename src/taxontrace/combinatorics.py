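"""Ground types and combinatorial primitives.

Taxa are arbitrary string labels mapped to a canonical index order (the
order of the universe's label sequence).  All canonical forms -- tuple
member order, partition block order -- are defined through that index
order, so results are reported with labels while comparisons and hashing
stay well-defined.

The central objects are:

* :class:`TaxonUniverse` -- the ground set X of taxa,
* :class:`TaxonSetCollection` -- the input collection S = {Y_1, ..., Y_k},
* :class:`CTuple` / :class:`CTupleSet` -- size-c subsets of X (for c = 4
  these are the quadruples that carry resolution information),
* :class:`FourPartition` -- an unordered partition of X into four
  non-empty blocks, the object the four-way partition property quantifies
  over.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Iterator, Sequence

import networkx as nx

__all__ = [
    "TaxonUniverse",
    "TaxonSetCollection",
    "CTuple",
    "CTupleSet",
    "FourPartition",
    "induced_ctuples",
    "cross_ctuples",
    "enumerate_4partitions",
    "partition_covered",
    "overlap_neighbors",
    "restrict_overlap_graph",
]


def _label_sort_key(label: str):
    # Numeric labels sort numerically ("10" after "9"), others lexically.
    return (0, int(label), "") if label.isdigit() else (1, 0, label)


@dataclass(frozen=True)
class TaxonUniverse:
    """The ground set X with a canonical ordering of its labels."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) < 1:
            raise ValueError("a taxon universe needs at least one label")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("taxon labels must be unique")
        object.__setattr__(
            self, "_index", {lab: i for i, lab in enumerate(self.labels)}
        )

    @classmethod
    def of_size(cls, n: int) -> "TaxonUniverse":
        """Universe with labels "1".."n" (the conventional integer taxa)."""
        return cls(tuple(str(i) for i in range(1, n + 1)))

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "TaxonUniverse":
        """Universe from arbitrary labels, ordered canonically."""
        return cls(tuple(sorted(set(labels), key=_label_sort_key)))

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self._index[label]  # type: ignore[attr-defined]
        except KeyError:
            raise ValueError(f"taxon {label!r} is not in the universe") from None

    def __contains__(self, label: object) -> bool:
        return label in self._index  # type: ignore[attr-defined]

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def sort_labels(self, labels: Iterable[str]) -> tuple[str, ...]:
        """Labels in canonical (index) order."""
        return tuple(sorted(labels, key=self.index))


@dataclass(frozen=True)
class TaxonSetCollection:
    """The input collection S = {Y_1, ..., Y_k} of subsets of X.

    Member sets may be empty and may repeat; decisiveness and traceability
    depend only on the induced c-tuples, which are duplicate-free.
    """

    universe: TaxonUniverse
    sets: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        for y in self.sets:
            for lab in y:
                if lab not in self.universe:
                    raise ValueError(
                        f"taxon {lab!r} of a member set is not in the universe"
                    )

    @classmethod
    def from_iterables(
        cls,
        sets: Iterable[Iterable[str]],
        universe: TaxonUniverse | None = None,
    ) -> "TaxonSetCollection":
        members = tuple(frozenset(str(x) for x in y) for y in sets)
        if universe is None:
            universe = TaxonUniverse.from_labels(
                lab for y in members for lab in y
            )
        return cls(universe, members)

    @classmethod
    def of_integers(
        cls, sets: Iterable[Iterable[int]], n: int | None = None
    ) -> "TaxonSetCollection":
        """Convenience constructor for integer taxa 1..n."""
        members = [[str(x) for x in y] for y in sets]
        uni = TaxonUniverse.of_size(n) if n is not None else None
        return cls.from_iterables(members, uni)

    @property
    def k_sets(self) -> int:
        return len(self.sets)

    @property
    def n(self) -> int:
        return self.universe.n

    def __iter__(self) -> Iterator[frozenset[str]]:
        return iter(self.sets)


@dataclass(frozen=True)
class CTuple:
    """A size-c subset of the universe in canonical member order."""

    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members) or not self.members:
            raise ValueError("a c-tuple needs c >= 1 distinct members")

    @classmethod
    def of(cls, universe: TaxonUniverse, members: Iterable[str]) -> "CTuple":
        return cls(universe.sort_labels(members))

    @property
    def c(self) -> int:
        return len(self.members)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.members)

    def __iter__(self) -> Iterator[str]:
        return iter(self.members)

    def __str__(self) -> str:
        return "{" + ",".join(self.members) + "}"


@dataclass(frozen=True)
class CTupleSet:
    """A duplicate-free family of size-c subsets of the universe."""

    universe: TaxonUniverse
    c: int
    tuples: tuple[CTuple, ...]

    def __post_init__(self) -> None:
        if self.c < 1:
            raise ValueError("tuple size c must be >= 1")
        for t in self.tuples:
            if t.c != self.c:
                raise ValueError("all tuples must have the same size c")

    @classmethod
    def build(
        cls, universe: TaxonUniverse, c: int, members: Iterable[Iterable[str]]
    ) -> "CTupleSet":
        tuples = {CTuple.of(universe, m) for m in members}
        ordered = sorted(
            tuples,
            key=lambda t: tuple(reversed([universe.index(x) for x in t])),
        )  # colex order for reproducible output
        return cls(universe, c, tuple(ordered))

    def __len__(self) -> int:
        return len(self.tuples)

    def __iter__(self) -> Iterator[CTuple]:
        return iter(self.tuples)

    def __contains__(self, t: object) -> bool:
        return t in set(self.tuples)

    def as_index_sets(self) -> list[tuple[int, ...]]:
        return [
            tuple(self.universe.index(x) for x in t) for t in self.tuples
        ]

    def as_label_sets(self) -> list[tuple[str, ...]]:
        return [t.members for t in self.tuples]


@dataclass(frozen=True)
class FourPartition:
    """An unordered partition of X into four non-empty blocks.

    Blocks are stored canonically: each block in label-index order, blocks
    ordered by their smallest element, so two equal partitions compare
    equal regardless of construction order.
    """

    blocks: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if len(self.blocks) != 4 or any(not b for b in self.blocks):
            raise ValueError("a four-partition needs exactly 4 non-empty blocks")

    @classmethod
    def of(
        cls, universe: TaxonUniverse, blocks: Iterable[Iterable[str]]
    ) -> "FourPartition":
        blocks = [universe.sort_labels(b) for b in blocks]
        if len(blocks) != 4 or any(not b for b in blocks):
            raise ValueError("a four-partition needs exactly 4 non-empty blocks")
        seen: set[str] = set()
        for b in blocks:
            seen.update(b)
        if len(seen) != sum(len(b) for b in blocks) or seen != set(
            universe.labels
        ):
            raise ValueError("blocks must partition the universe")
        blocks.sort(key=lambda b: universe.index(b[0]))
        return cls(tuple(blocks))

    def block_of(self) -> dict[str, int]:
        """Map each taxon to the index of its block."""
        return {x: i for i, b in enumerate(self.blocks) for x in b}

    def __str__(self) -> str:
        return "|".join("{" + ",".join(b) + "}" for b in self.blocks)


# ---------------------------------------------------------------------------
# operations


def induced_ctuples(S: TaxonSetCollection, c: int) -> CTupleSet:
    """All size-c subsets of X contained in at least one member set of S.

    Members of S smaller than c contribute nothing; duplicates across
    member sets are merged.
    """
    if c < 1:
        raise ValueError("tuple size c must be >= 1")
    tuples: set[tuple[str, ...]] = set()
    for y in S.sets:
        if len(y) < c:
            continue
        for combo in combinations(S.universe.sort_labels(y), c):
            tuples.add(combo)
    return CTupleSet.build(S.universe, c, tuples)


def cross_ctuples(S: TaxonSetCollection, c: int) -> CTupleSet:
    """The size-c subsets of X contained in *no* member set of S.

    Complement of :func:`induced_ctuples` within all C(n, c) tuples;
    a cross tuple is one no input tree can resolve directly.
    """
    if c < 1:
        raise ValueError("tuple size c must be >= 1")
    induced = {t.members for t in induced_ctuples(S, c)}
    allt = (
        combo
        for combo in combinations(S.universe.labels, c)
        if combo not in induced
    )
    return CTupleSet.build(S.universe, c, allt)


def _rgs_four_blocks(n: int) -> Iterator[tuple[int, ...]]:
    """Restricted-growth strings over {0,1,2,3} using all four classes.

    Yields each unordered 4-block set partition of range(n) exactly once,
    in canonical order (blocks indexed by first occurrence).
    """
    a = [0] * n

    def rec(i: int, mx: int) -> Iterator[tuple[int, ...]]:
        if i == n:
            if mx == 3:
                yield tuple(a)
            return
        top = min(mx + 1, 3)
        for b in range(top + 1):
            nmx = mx if b <= mx else b
            # prune: the remaining positions must still introduce the
            # missing classes
            if 3 - nmx <= n - i - 1:
                a[i] = b
                yield from rec(i + 1, nmx)

    yield from rec(1, 0)


def enumerate_4partitions(U: TaxonUniverse) -> Iterator[FourPartition]:
    """Stream every partition of X into four non-empty blocks once.

    The total count is the Stirling number of the second kind S2(n, 4).
    Generated by restricted-growth strings with exactly four classes, so
    no deduplication pass is needed.
    """
    if U.n < 4:
        raise ValueError("no 4-partition exists for fewer than 4 taxa")
    for assignment in _rgs_four_blocks(U.n):
        blocks: list[list[str]] = [[], [], [], []]
        for idx, b in enumerate(assignment):
            blocks[b].append(U.labels[idx])
        yield FourPartition(tuple(tuple(b) for b in blocks))


def partition_covered(p: FourPartition, Q: CTupleSet) -> bool:
    """True iff some quadruple of Q has one member in each block of p."""
    if Q.c != 4:
        raise ValueError("partition coverage is defined for quadruple sets")
    block = p.block_of()
    for t in Q:
        try:
            sig = {block[x] for x in t}
        except KeyError:
            raise ValueError(
                "quadruple set and partition live on different universes"
            ) from None
        if len(sig) == 4:
            return True
    return False


def overlap_neighbors(t: CTuple, U: TaxonUniverse) -> CTupleSet:
    """All c-tuples sharing exactly c-1 members with t: c*(n-c) of them."""
    c = t.c
    if c > U.n:
        raise ValueError("tuple size exceeds universe size")
    members = set(t.members)
    for x in members:
        if x not in U:
            raise ValueError(f"taxon {x!r} is not in the universe")
    outside = [x for x in U.labels if x not in members]
    neighbors = [
        tuple(members - {drop} | {add})
        for drop in members
        for add in outside
    ]
    return CTupleSet.build(U, c, neighbors)


def restrict_overlap_graph(
    U: TaxonUniverse, c: int, taxa: Iterable[str]
) -> nx.Graph:
    """The (c-1)-overlap graph restricted to the c-tuples within `taxa`.

    Vertices are all c-tuples drawn from `taxa`; edges join tuples that
    overlap in c-1 members.  For |taxa| = c+1 this is a complete graph on
    c+1 vertices -- the cliques the full graph is glued from.
    """
    sub = U.sort_labels(taxa)
    if len(sub) < c:
        raise ValueError("need at least c taxa to form a c-tuple")
    g: nx.Graph = nx.Graph()
    verts = [CTuple(combo) for combo in combinations(sub, c)]
    g.add_nodes_from(verts)
    for u, v in combinations(verts, 2):
        if len(u.as_set() & v.as_set()) == c - 1:
            g.add_edge(u, v)
    return g
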