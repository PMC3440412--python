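"""Two-color array normalization in (A, M) space.

The pipeline order is fixed: MA conversion, then within-array LOESS of M on
A separately within GC-content strata (dye bias depends on probe GC), then
across-array A-quantile normalization (A values quantile-normalized over
the replicate set, M left untouched).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .array_io import TilingArray

__all__ = [
    "NormalizationParams",
    "compute_ma",
    "invert_ma",
    "gc_stratified_loess",
    "aquantile_across",
    "normalize_replicates",
]

MIN_GC_GROUP = 20  # GC strata smaller than this are merged with a neighbor


@dataclass(frozen=True)
class NormalizationParams:
    """Tuning knobs for the normalization stack.

    n_gc_groups
        Number of equal-count GC strata (quantile bins of gc fraction).
    loess_span
        Fraction of each stratum used in every local fit.
    loess_degree
        Local polynomial degree; only degree 1 is supported (the robust
        local-linear fit of the underlying smoother).
    loess_iterations
        Bisquare robustness iterations.
    loess_delta
        Points closer than this on the A axis share interpolated fits;
        0 disables the shortcut (exact but slower). Expressed as a
        fraction of the A range of the stratum.
    """

    n_gc_groups: int = 10
    loess_span: float = 0.3
    loess_degree: int = 1
    loess_iterations: int = 3
    loess_delta: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 < self.loess_span <= 1.0:
            raise ValueError("loess_span must lie in (0, 1]")
        if self.n_gc_groups < 1:
            raise ValueError("n_gc_groups must be >= 1")
        if self.loess_degree != 1:
            raise ValueError("only local-linear (degree 1) fits are supported")
        if self.loess_iterations < 0 or self.loess_delta < 0:
            raise ValueError("iterations and delta must be nonnegative")


def compute_ma(array: TilingArray) -> pd.DataFrame:
    """Convert the two log2 channels to (M, A): M = Cy5 - Cy3, A = (Cy5 + Cy3)/2."""
    cy5 = array.probes["cy5_log"].to_numpy(float)
    cy3 = array.probes["cy3_log"].to_numpy(float)
    return pd.DataFrame({"M": cy5 - cy3, "A": 0.5 * (cy5 + cy3)})


def invert_ma(ma: pd.DataFrame) -> pd.DataFrame:
    """Recover the channel intensities: Cy5 = A + M/2, Cy3 = A - M/2."""
    m = ma["M"].to_numpy(float)
    a = ma["A"].to_numpy(float)
    return pd.DataFrame({"cy5_log": a + 0.5 * m, "cy3_log": a - 0.5 * m})


def _gc_group_labels(gc: np.ndarray, n_groups: int) -> np.ndarray:
    """Equal-count quantile bins of gc, with undersized bins merged inward."""
    if n_groups == 1 or len(np.unique(gc)) < 2:
        return np.zeros(len(gc), dtype=int)
    try:
        labels = pd.qcut(gc, q=n_groups, labels=False, duplicates="drop")
    except ValueError:
        return np.zeros(len(gc), dtype=int)
    labels = np.asarray(labels, dtype=int)
    # merge groups below the minimum size with their nearest (lower) neighbor
    while True:
        uniq, counts = np.unique(labels, return_counts=True)
        small = uniq[counts < MIN_GC_GROUP]
        if len(small) == 0 or len(uniq) == 1:
            break
        g = small[0]
        neighbor = uniq[uniq < g].max() if (uniq < g).any() else uniq[uniq > g].min()
        labels[labels == g] = neighbor
    return labels


def gc_stratified_loess(
    ma: pd.DataFrame,
    gc: np.ndarray,
    params: NormalizationParams = NormalizationParams(),
) -> pd.DataFrame:
    """Remove the A-dependent trend of M within each GC stratum.

    Within each stratum the robust LOESS fit of M on A is subtracted from M;
    A is returned unchanged. A stratum whose A values are all identical has
    no trend to fit, so its median M is subtracted instead.
    """
    m = ma["M"].to_numpy(float).copy()
    a = ma["A"].to_numpy(float)
    gc = np.asarray(gc, dtype=float)
    if len(gc) != len(m):
        raise ValueError("gc vector length does not match the MA track")
    labels = _gc_group_labels(gc, params.n_gc_groups)
    out = m.copy()
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        ag, mg = a[idx], m[idx]
        if np.ptp(ag) == 0.0:
            out[idx] = mg - np.median(mg)
            continue
        delta = params.loess_delta * np.ptp(ag)
        fit = lowess(
            mg,
            ag,
            frac=params.loess_span,
            it=params.loess_iterations,
            delta=delta,
            return_sorted=False,
        )
        out[idx] = mg - fit
    return pd.DataFrame({"M": out, "A": a})


def aquantile_across(tracks: list[pd.DataFrame]) -> list[pd.DataFrame]:
    """Quantile-normalize A values across arrays; M values pass through.

    Each array's sorted A vector is replaced by the across-array mean of
    order statistics, mapped back through the array's own ranks. Ties within
    an array receive the mean of their tied order-statistic targets. The
    operation is idempotent.
    """
    if len(tracks) < 2:
        raise ValueError("A-quantile normalization needs >= 2 arrays")
    n = len(tracks[0])
    if any(len(t) != n for t in tracks):
        raise ValueError("all tracks must have identical length")
    a_mat = np.column_stack([t["A"].to_numpy(float) for t in tracks])
    mean_order_stats = np.sort(a_mat, axis=0).mean(axis=1)
    out = []
    for j, t in enumerate(tracks):
        a = a_mat[:, j]
        order = np.argsort(a, kind="mergesort")
        new_a = np.empty(n)
        new_a[order] = mean_order_stats
        # average targets over tied A values
        s = pd.Series(new_a).groupby(a).transform("mean").to_numpy()
        out.append(pd.DataFrame({"M": t["M"].to_numpy(float), "A": s}))
    return out


def normalize_replicates(
    arrays: list[TilingArray],
    params: NormalizationParams = NormalizationParams(),
) -> list[pd.DataFrame]:
    """Full stack on a replicate set: MA, per-array GC-LOESS, A-quantile."""
    within = [
        gc_stratified_loess(compute_ma(arr), arr.probes["gc"].to_numpy(float), params)
        for arr in arrays
    ]
    if len(within) == 1:
        return within
    return aquantile_across(within)
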