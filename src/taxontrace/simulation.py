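"""Simulation study comparing traceability against decisiveness.

For each cell (n, k) the study draws (or exhaustively enumerates)
families of k distinct quadruples on n taxa, classifies each family with
the traceability algorithm and the four-way partition checker, and
tabulates the contingency counts.  Traceability implies decisiveness, so
the (traceable, non-decisive) cell is structurally empty and three
counts remain:

* TP -- traceable and decisive,
* FN -- decisive but not traceable (the families the polynomial test
  misses),
* TN -- not decisive (hence not traceable).

From these, TPR = TP/(TP+FN) measures the power of the traceability test
for detecting decisiveness, NPV = TN/(TN+FN) its reliability on negative
calls, and PREV = (TP+FN)/total the prevalence of decisive families.
k' = k + resolved-count records how far the coloring got on decisive
families it could not finish.

The admissible k range per n is [ceil(C(n,3)/4)+2, C(n,4)-n+3]: below it
no family can be decisive, above it every family is traceable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._fast import TupleKernel, kernel

__all__ = [
    "SimulationCellResult",
    "SimulationSummary",
    "admissible_k_range",
    "run_cell",
    "run_grid",
    "summarize",
    "cells_to_dataframe",
    "plot_metrics",
]

#: exhaustive enumeration is used automatically below this subset count
EXHAUSTIVE_CAP = 10_000


@dataclass(frozen=True)
class SimulationCellResult:
    n: int
    k: int
    mode: str  # "exhaustive" | "sampled"
    n_evaluated: int
    seed: int | None
    TP: int
    FN: int
    TN: int
    TPR: float | None
    NPV: float | None
    PREV: float | None
    max_kprime: int | None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SimulationSummary:
    """Per-n medians/IQRs over the admissible k cells, plus the bound
    extractions (each None when never observed)."""

    n: int
    k_values: tuple[int, ...]
    tpr_median: float | None
    tpr_iqr: tuple[float, float] | None
    npv_median: float | None
    npv_iqr: tuple[float, float] | None
    prev_median: float | None
    prev_iqr: tuple[float, float] | None
    min_k_decisive: int | None
    min_k_ftt: int | None
    max_k_nondecisive: int | None
    max_k_decisive_not_ftt: int | None
    max_kprime: int | None

    def to_json(self) -> str:
        d = asdict(self)
        d["k_values"] = list(self.k_values)
        return json.dumps(d)


def admissible_k_range(n: int) -> tuple[int, int]:
    """The sampled k interval: below it nothing is decisive, above it
    everything is traceable."""
    lo = -(-comb(n, 3) // 4) + 2
    hi = comb(n, 4) - n + 3
    return lo, hi


def _classify_mask(ker: TupleKernel, mask: int, k: int):
    """-> (decisive, traceable, kprime or None)."""
    final = ker.trace_fixpoint(mask)
    if final == ker.full_mask:
        return True, True, None
    if ker.is_decisive(mask):
        return True, False, k + (final ^ mask).bit_count()
    return False, False, None


def run_cell(
    n: int,
    k: int,
    mode: str = "auto",
    n_sim: int = 10_000,
    seed: int | None = None,
    enforce_range: bool = True,
) -> SimulationCellResult:
    """Classify one (n, k) cell.

    Exhaustive mode enumerates every k-subset of the C(n,4) quadruples
    exactly once; sampled mode draws `n_sim` families of k distinct
    quadruples uniformly (families may repeat across draws, matching the
    with-replacement estimator).  Each draw shuffles the canonical
    quadruple list with a seeded substream and takes a prefix; the
    substream is derived from (seed, n, k) so cells are independently
    reproducible.
    """
    lo, hi = admissible_k_range(n)
    if enforce_range and not lo <= k <= hi:
        raise ValueError(
            f"k={k} outside the admissible interval [{lo}, {hi}] for n={n}"
        )
    ker = kernel(n, 4)
    if not 1 <= k <= ker.total:
        raise ValueError(f"need 1 <= k <= {ker.total}")
    total_subsets = ker.count_subsets(k)
    if mode == "auto":
        mode = "exhaustive" if total_subsets <= EXHAUSTIVE_CAP else "sampled"
    if mode not in ("exhaustive", "sampled"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "exhaustive" and total_subsets > max(EXHAUSTIVE_CAP, n_sim):
        raise ValueError(
            f"exhaustive mode refused: C({ker.total},{k}) = "
            f"{total_subsets} subsets exceed the enumeration cap"
        )

    tp = fn = tn = 0
    max_kprime: int | None = None
    if mode == "exhaustive":
        masks: Iterable[int] = ker.subsets_of_size(k)
        n_evaluated = total_subsets
        cell_seed = None
    else:
        if seed is None:
            raise ValueError("sampled mode needs a seed")
        rng = np.random.default_rng(np.random.SeedSequence([seed, n, k]))
        cell_seed = seed

        def _draws():
            for _ in range(n_sim):
                prefix = rng.permutation(ker.total)[:k]
                m = 0
                for i in prefix:
                    m |= 1 << int(i)
                yield m

        masks = _draws()
        n_evaluated = n_sim

    for mask in masks:
        decisive, traceable, kprime = _classify_mask(ker, mask, k)
        if traceable:
            tp += 1
        elif decisive:
            fn += 1
            if max_kprime is None or kprime > max_kprime:  # type: ignore[operator]
                max_kprime = kprime
        else:
            tn += 1

    p = tp + fn
    return SimulationCellResult(
        n=n,
        k=k,
        mode=mode,
        n_evaluated=n_evaluated,
        seed=cell_seed,
        TP=tp,
        FN=fn,
        TN=tn,
        TPR=tp / p if p else None,
        NPV=tn / (tn + fn) if tn + fn else None,
        PREV=p / n_evaluated if n_evaluated else None,
        max_kprime=max_kprime,
    )


def run_grid(
    n: int,
    mode: str = "auto",
    n_sim: int = 10_000,
    seed: int | None = None,
    ks: Sequence[int] | None = None,
) -> list[SimulationCellResult]:
    """All cells of one n over the admissible k range (or a sub-range)."""
    lo, hi = admissible_k_range(n)
    if ks is None:
        ks = range(lo, hi + 1)
    return [
        run_cell(n, k, mode=mode, n_sim=n_sim, seed=seed) for k in ks
    ]


def _median_iqr(values: list[float], method: str):
    if not values:
        return None, None
    arr = np.asarray(values, dtype=float)
    med = float(np.median(arr))
    lo, hi = np.percentile(arr, [25, 75], method=method)
    return med, (float(lo), float(hi))


def summarize(
    cells: Sequence[SimulationCellResult],
    quantile_method: str = "linear",
) -> SimulationSummary:
    """Medians and IQRs over the k cells, plus the extracted bounds.

    TPR and PREV are summarized over the cells at or above the smallest
    k with a decisive family (below it TPR is undefined and PREV
    identically zero).  NPV is summarized over every supplied cell: a
    negative call exists in each one, so the metric is defined on the
    whole admissible range and its summary uses all of it.  Metrics
    recorded as undefined (zero denominator) are excluded.  The
    even-count median is the midpoint; the IQR rule is configurable via
    `quantile_method` (a numpy percentile method).
    """
    if not cells:
        raise ValueError("no cells to summarize")
    ns = {c.n for c in cells}
    if len(ns) > 1:
        raise ValueError("all cells must share the same n")
    (n,) = ns
    cells = sorted(cells, key=lambda c: c.k)

    dec_ks = [c.k for c in cells if c.TP + c.FN > 0]
    min_k_decisive = min(dec_ks) if dec_ks else None
    ftt_ks = [c.k for c in cells if c.TP > 0]
    nondec_ks = [c.k for c in cells if c.TN > 0]
    fn_ks = [c.k for c in cells if c.FN > 0]
    kprimes = [c.max_kprime for c in cells if c.max_kprime is not None]

    used = (
        [c for c in cells if c.k >= min_k_decisive]
        if min_k_decisive is not None
        else []
    )
    tpr_med, tpr_iqr = _median_iqr(
        [c.TPR for c in used if c.TPR is not None], quantile_method
    )
    npv_med, npv_iqr = _median_iqr(
        [c.NPV for c in cells if c.NPV is not None], quantile_method
    )
    prev_med, prev_iqr = _median_iqr(
        [c.PREV for c in used if c.PREV is not None], quantile_method
    )
    return SimulationSummary(
        n=n,
        k_values=tuple(c.k for c in used),
        tpr_median=tpr_med,
        tpr_iqr=tpr_iqr,
        npv_median=npv_med,
        npv_iqr=npv_iqr,
        prev_median=prev_med,
        prev_iqr=prev_iqr,
        min_k_decisive=min_k_decisive,
        min_k_ftt=min(ftt_ks) if ftt_ks else None,
        max_k_nondecisive=max(nondec_ks) if nondec_ks else None,
        max_k_decisive_not_ftt=max(fn_ks) if fn_ks else None,
        max_kprime=max(kprimes) if kprimes else None,
    )


def cells_to_dataframe(
    cells: Sequence[SimulationCellResult],
) -> pd.DataFrame:
    """One row per (n, k) cell with every recorded field."""
    return pd.DataFrame([c.to_dict() for c in cells])


def plot_metrics(cells: Sequence[SimulationCellResult], path: str) -> None:
    """TPR / NPV / PREV against k, one line each, written to `path`."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = cells_to_dataframe(cells).sort_values("k")
    fig, ax = plt.subplots(figsize=(6, 4))
    for col in ("TPR", "NPV", "PREV"):
        ax.plot(df["k"], df[col], marker="o", label=col)
    ax.set_xlabel("number of input quadruples k")
    ax.set_ylabel("proportion")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(f"n = {df['n'].iloc[0]}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
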