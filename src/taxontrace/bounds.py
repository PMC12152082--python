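"""Closed-form thresholds and quadruple-count classification.

All arithmetic is exact integer arithmetic -- no floating point enters
any bound.  The thresholds, for n taxa and tuple size c (quadruple-only
quantities are defined for c = 4):

========================  =====================================================
f_n                       C(n,4) - (n-4); at or above it *every* quadruple
                          family is decisive
ftt_guarantee             C(n,c) - n + c; at or above it every family is
                          traceable (for c = 4 hence also decisive)
ftt_min                   C(n-1, c-1); below it no family is traceable
decisive_lower            ceil(C(n,3)/4) + 2; below it no family is decisive
decisive_upper            C(n-1,3) - 1; a decisive family of exactly this size
                          exists for every n >= 6 (recursive construction)
stirling_lower            ceil(S2(n,4) / 4^(n-4)); the weaker counting bound
                          each quadruple covers only 4^(n-4) partitions
max_decisive_not_ftt      C(n,4) - 3n + 13; size of the maximal construction
                          that is decisive but not traceable (n >= 6)
========================  =====================================================
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from math import comb, factorial

from .combinatorics import TaxonSetCollection, induced_ctuples

__all__ = ["BoundsTable", "compute_bounds", "stirling2", "classify", "Classification"]


def stirling2(n: int, j: int = 4) -> int:
    """Stirling number of the second kind, by inclusion-exclusion.

    S2(n, j) counts the partitions of an n-set into j non-empty blocks:
    S2(n,j) = (1/j!) * sum_{i=0}^{j} (-1)^(j-i) C(j,i) i^n.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    total = sum(
        (-1) ** (j - i) * comb(j, i) * i**n for i in range(j + 1)
    )
    q, r = divmod(total, factorial(j))
    assert r == 0
    return q


@dataclass(frozen=True)
class BoundsTable:
    n: int
    c: int
    f_n: int | None
    ftt_guarantee: int
    ftt_min: int
    decisive_lower: int | None
    decisive_upper: int | None
    stirling_lower: int | None
    max_decisive_not_ftt: int | None

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    def format(self) -> str:
        rows = [(k, v) for k, v in asdict(self).items() if v is not None]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


def _ceil_div(a: int, b: int) -> int:
    return -(-a // b)


def compute_bounds(n: int, c: int = 4) -> BoundsTable:
    """Evaluate every closed-form threshold for (n, c).

    Quadruple-only fields are None when c != 4; the maximal
    decisive-not-traceable size additionally needs n >= 6.
    """
    if n < c:
        raise ValueError("need n >= c")
    quad = c == 4
    return BoundsTable(
        n=n,
        c=c,
        f_n=comb(n, 4) - (n - 4) if quad else None,
        ftt_guarantee=comb(n, c) - n + c,
        ftt_min=comb(n - 1, c - 1),
        decisive_lower=_ceil_div(comb(n, 3), 4) + 2 if quad else None,
        decisive_upper=comb(n - 1, 3) - 1 if quad else None,
        stirling_lower=_ceil_div(stirling2(n, 4), 4 ** (n - 4))
        if quad
        else None,
        max_decisive_not_ftt=comb(n, 4) - 3 * n + 13
        if quad and n >= 6
        else None,
    )


@dataclass(frozen=True)
class Classification:
    """Shortcut verdict from the induced quadruple count alone."""

    verdict: str  # below-lower | above-guarantee | indeterminate
    k: int
    bounds: BoundsTable

    def to_json(self) -> str:
        return json.dumps(
            {
                "verdict": self.verdict,
                "k": self.k,
                "bounds": asdict(self.bounds),
            }
        )


def classify(S: TaxonSetCollection) -> Classification:
    """Place the induced quadruple count k of S against the thresholds.

    below-lower: k is too small for either property to hold;
    above-guarantee: both properties are guaranteed;
    indeterminate: run the exact checkers.
    """
    n = S.universe.n
    if n < 6:
        raise ValueError("classification thresholds assume n >= 6")
    k = len(induced_ctuples(S, 4))
    b = compute_bounds(n, 4)
    if k < b.decisive_lower:  # type: ignore[operator]
        verdict = "below-lower"
    elif k >= comb(n, 4) - n + 4:
        verdict = "above-guarantee"
    else:
        verdict = "indeterminate"
    return Classification(verdict, k, b)
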