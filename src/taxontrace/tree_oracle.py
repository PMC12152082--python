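"""Definition-level ground truth on small trees.

Enumerates unrooted binary leaf-labeled trees, restricts them to taxon
subsets, counts supertrees and decides decisiveness straight from its
definition: a collection S is decisive iff for every tree T on X, the
restrictions of T to the members of S characterize T uniquely.  These
operations exist to validate the partition-property checker on small n,
not to scale; hard guards refuse large leaf sets.

A topology is represented by its set of non-trivial splits (bipartitions
induced by internal edges), which makes equality canonical and
restriction a pure set operation.  Newick is a boundary format only.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Iterator, Sequence

import dendropy

from .combinatorics import TaxonSetCollection

__all__ = [
    "LeafTree",
    "enumerate_trees",
    "restrict",
    "count_supertrees",
    "SupertreeCount",
    "decisive_by_definition",
    "from_newick",
    "ORACLE_GUARD_N",
]

#: hard cap on leaf-set size for the exhaustive oracle operations
ORACLE_GUARD_N = 7


def _canon_side(side: frozenset, leaves: frozenset) -> frozenset:
    """Store each split as the side not containing the reference leaf."""
    ref = min(leaves)
    return frozenset(leaves - side) if ref in side else frozenset(side)


@dataclass(frozen=True)
class LeafTree:
    """An unrooted binary topology as its set of non-trivial splits."""

    leaves: frozenset
    splits: frozenset

    def __post_init__(self) -> None:
        m = len(self.leaves)
        expected = max(m - 3, 0)
        if len(self.splits) != expected:
            raise ValueError(
                f"a binary topology on {m} leaves has {expected} "
                f"non-trivial splits, got {len(self.splits)}"
            )

    @classmethod
    def of(
        cls, leaves: Iterable[str], splits: Iterable[Iterable[str]] = ()
    ) -> "LeafTree":
        leafset = frozenset(str(x) for x in leaves)
        sides = frozenset(
            _canon_side(frozenset(str(x) for x in s), leafset)
            for s in splits
        )
        return cls(leafset, sides)

    def to_newick(self) -> str:
        """Emit the topology as an unrooted newick string."""
        if len(self.leaves) == 1:
            (leaf,) = self.leaves
            return f"{leaf};"
        if len(self.leaves) == 2:
            return "(" + ",".join(sorted(self.leaves)) + ");"
        ref = min(self.leaves)
        clades: list[frozenset] = [
            _canon_side(s, self.leaves) for s in self.splits
        ]
        clades += [frozenset({x}) for x in self.leaves if x != ref]

        def render(s: frozenset) -> str:
            if len(s) == 1:
                (leaf,) = s
                return leaf
            inner = [c for c in clades if c < s]
            maximal = [
                c
                for c in inner
                if not any(c < d for d in inner if d != c)
            ]
            return "(" + ",".join(sorted(render(c) for c in maximal)) + ")"

        top = frozenset(self.leaves - {ref})
        inner = [c for c in clades if c < top]
        maximal = [
            c for c in inner if not any(c < d for d in inner if d != c)
        ]
        parts = [ref] + sorted(render(c) for c in maximal)
        return "(" + ",".join(parts) + ");"


def _enumerate_edge_trees(leaves: Sequence[str]):
    """Edge lists of all unrooted binary trees, by iterative leaf
    insertion onto each edge (counts follow (2m-5)!!)."""
    if len(leaves) == 3:
        yield [(leaves[0], 0), (leaves[1], 0), (leaves[2], 0)]
        return
    new_leaf = leaves[-1]
    joint = len(leaves) - 3  # fresh internal node id
    for edges in _enumerate_edge_trees(leaves[:-1]):
        for i, (u, v) in enumerate(edges):
            yield edges[:i] + edges[i + 1 :] + [
                (u, joint),
                (v, joint),
                (new_leaf, joint),
            ]


def _edges_to_splits(edges, leafset: frozenset) -> frozenset:
    adj: dict = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    sides = set()
    for u, v in edges:
        if isinstance(u, str) or isinstance(v, str):
            continue  # pendant edge: trivial split
        # leaves on the u-side of edge (u, v)
        stack, seen = [u], {u, v}
        side = set()
        while stack:
            node = stack.pop()
            for nb in adj[node]:
                if nb in seen:
                    continue
                seen.add(nb)
                if isinstance(nb, str):
                    side.add(nb)
                else:
                    stack.append(nb)
        sides.add(_canon_side(frozenset(side), leafset))
    return frozenset(sides)


def enumerate_trees(leaves: Iterable[str]) -> Iterator[LeafTree]:
    """Yield each unrooted binary topology on `leaves` exactly once."""
    labels = sorted(str(x) for x in leaves)
    if len(labels) < 3:
        raise ValueError("tree enumeration needs at least 3 leaves")
    leafset = frozenset(labels)
    for edges in _enumerate_edge_trees(labels):
        yield LeafTree(leafset, _edges_to_splits(edges, leafset))


def restrict(T: LeafTree, Y: Iterable[str]) -> LeafTree:
    """The topology T displays on Y: delete other leaves, suppress
    degree-2 vertices.  Each split of T intersects down to Y; trivial
    and duplicate splits vanish."""
    Yset = frozenset(str(x) for x in Y)
    if not Yset <= T.leaves:
        raise ValueError("restriction set must be a subset of the leaves")
    if not Yset:
        return LeafTree(Yset, frozenset())
    sides = set()
    for s in T.splits:
        a = s & Yset
        b = Yset - a
        if len(a) >= 2 and len(b) >= 2:
            sides.add(_canon_side(a, Yset))
    return LeafTree(Yset, frozenset(sides))


@dataclass(frozen=True)
class SupertreeCount:
    """Number of supertrees, plus the trees themselves when few."""

    count: int
    supertrees: tuple[LeafTree, ...] | None


def count_supertrees(
    input_trees: Sequence[LeafTree],
    X: Iterable[str],
    cap: int = 25,
) -> SupertreeCount:
    """Count trees on X displaying every input tree, by exhaustive
    enumeration.  A count of 0 means the inputs are incompatible."""
    labels = frozenset(str(x) for x in X)
    if len(labels) > ORACLE_GUARD_N:
        raise ValueError(
            f"supertree counting is refused for more than "
            f"{ORACLE_GUARD_N} taxa"
        )
    for t in input_trees:
        if not t.leaves <= labels:
            raise ValueError("input tree leaves must be a subset of X")
    found: list[LeafTree] = []
    count = 0
    for T in enumerate_trees(labels):
        if all(restrict(T, t.leaves) == t for t in input_trees):
            count += 1
            if count <= cap:
                found.append(T)
    return SupertreeCount(count, tuple(found) if count <= cap else None)


def decisive_by_definition(S: TaxonSetCollection) -> bool:
    """Decisiveness straight from the definition: every tree on X is the
    unique tree with its restriction profile over the members of S.

    Implemented by grouping all enumerated trees by their profile and
    requiring every group to be a singleton.
    """
    n = S.universe.n
    if n > 6:
        raise ValueError(
            "definition-level decisiveness is refused for n > 6"
        )
    if n < 4:
        raise ValueError("need at least 4 taxa")
    profiles: dict[tuple, int] = {}
    for T in enumerate_trees(S.universe.labels):
        prof = tuple(restrict(T, y) for y in S.sets)
        profiles[prof] = profiles.get(prof, 0) + 1
    return all(v == 1 for v in profiles.values())


def from_newick(text: str) -> LeafTree:
    """Parse a newick string into a topology.

    The tree must be binary once any rooting bifurcation is suppressed;
    anything else is rejected.
    """
    tree = dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True
    )
    leaves = frozenset(
        lf.taxon.label for lf in tree.leaf_node_iter()
    )
    n = len(leaves)
    sides = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(
            lf.taxon.label for lf in node.leaf_iter()
        )
        if 2 <= len(below) <= n - 2:
            sides.add(_canon_side(below, leaves))
    expected = max(n - 3, 0)
    if len(sides) != expected:
        raise ValueError(
            "newick tree is not binary (after suppressing the root)"
        )
    return LeafTree(leaves, frozenset(sides))
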