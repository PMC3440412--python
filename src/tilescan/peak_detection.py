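"""Sliding-window median smoothing and signed region calling.

After normalization each probe's M value is replaced by the median of all
probe M values within a 600 bp window on the same promoter (the size of the
immunoprecipitated fragments), then scored against a normal distribution
scaled to the array-wide mean and standard deviation of the smoothed M.
Maximal runs of >= 3 consecutive probes with one-sided p below 1e-3 become
regions: upper tail = factor-enriched (positive), lower tail = IgG-enriched
(negative). Replicate consensus re-analyzes the probe-wise mean of the
smoothed tracks and keeps a region only when every replicate independently
shows a same-sign overlapping region. Positive regions sitting next to a
larger-magnitude negative (IgG) peak are flagged questionable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .array_io import ReplicateSet
from .intervals import GenomicInterval
from .normalization import NormalizationParams, normalize_replicates

__all__ = [
    "DetectionParams",
    "EnrichedRegion",
    "ConsensusRegion",
    "smooth_track",
    "score_probes",
    "call_regions",
    "combine_replicates",
    "flag_questionable",
    "select_targets",
    "detect_targets",
    "DetectionResult",
]


@dataclass(frozen=True)
class DetectionParams:
    window_bp: int = 600
    probe_alpha: float = 1e-3
    min_consecutive: int = 3
    target_alpha: float = 1e-7
    relaxed_alpha: float = 1e-5
    adjacency_bp: int = 1000
    robust_z: bool = False  # median/MAD instead of moment estimators

    def __post_init__(self) -> None:
        if not (0.0 < self.target_alpha <= self.relaxed_alpha <= self.probe_alpha < 1.0):
            raise ValueError(
                "require 0 < target_alpha <= relaxed_alpha <= probe_alpha < 1"
            )
        if self.window_bp <= 0 or self.min_consecutive < 1 or self.adjacency_bp < 0:
            raise ValueError("window_bp, min_consecutive, adjacency_bp must be positive")


@dataclass
class EnrichedRegion:
    """A maximal run of significant consecutive probes in one replicate."""

    interval: GenomicInterval
    sign: int  # +1 factor-enriched, -1 IgG-enriched
    promoter_id: str
    probe_ids: list[str]
    region_p: float
    peak_z: float


@dataclass
class ConsensusRegion:
    """A region called on the replicate-averaged track with full support."""

    interval: GenomicInterval
    sign: int
    promoter_id: str
    probe_ids: list[str]
    region_p: float
    peak_z: float
    support: list[bool] = field(default_factory=list)
    questionable: bool = False
    masking_region: "ConsensusRegion | None" = None


def _promoter_blocks(grid: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    pid = grid["promoter_id"].to_numpy()
    starts = np.flatnonzero(np.r_[True, pid[1:] != pid[:-1]])
    return starts, np.r_[starts[1:], len(pid)]


def smooth_track(
    ma: pd.DataFrame, grid: pd.DataFrame, params: DetectionParams = DetectionParams()
) -> pd.DataFrame:
    """Windowed-median smoothing of M (and A) per probe, clipped at promoter edges.

    For probe *i* the smoothed value is the median over probes *j* of the
    same promoter with |center(j) - center(i)| <= window_bp / 2. Returns a
    DataFrame with columns M_smooth, A_smooth, window_count.
    """
    n = len(grid)
    if n == 0:
        return pd.DataFrame(columns=["M_smooth", "A_smooth", "window_count"])
    if len(ma) != n:
        raise ValueError("MA track and probe grid lengths differ")
    centers = 0.5 * (grid["start"].to_numpy(float) + grid["end"].to_numpy(float))
    half = params.window_bp / 2.0
    li = np.empty(n, dtype=np.int64)
    ri = np.empty(n, dtype=np.int64)
    for s, e in zip(*_promoter_blocks(grid)):
        c = centers[s:e]
        li[s:e] = s + np.searchsorted(c, c - half, side="left")
        ri[s:e] = s + np.searchsorted(c, c + half, side="right")
    widths = ri - li
    m = ma["M"].to_numpy(float)
    a = ma["A"].to_numpy(float)
    m_sm = np.empty(n)
    a_sm = np.empty(n)
    for w in np.unique(widths):
        rows = np.flatnonzero(widths == w)
        take = li[rows][:, None] + np.arange(w)
        m_sm[rows] = np.median(m[take], axis=1)
        a_sm[rows] = np.median(a[take], axis=1)
    return pd.DataFrame({"M_smooth": m_sm, "A_smooth": a_sm, "window_count": widths})


def score_probes(smoothed: pd.DataFrame, robust: bool = False) -> pd.DataFrame:
    """Z-scores and one-sided normal tail p-values for the smoothed M track.

    The reference normal is scaled to the array-wide (experimental) mean and
    standard deviation of the smoothed M values; with ``robust`` the
    median and normal-consistent MAD are used instead.
    """
    m = smoothed["M_smooth"].to_numpy(float)
    if robust:
        center = float(np.median(m))
        sd = 1.4826 * float(np.median(np.abs(m - center)))
    else:
        center = float(np.mean(m))
        sd = float(np.std(m))
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError("degenerate smoothed track: zero standard deviation")
    z = (m - center) / sd
    return pd.DataFrame({"z": z, "p_pos": sps.norm.sf(z), "p_neg": sps.norm.cdf(z)})


def call_regions(
    stats: pd.DataFrame,
    grid: pd.DataFrame,
    params: DetectionParams = DetectionParams(),
    sign: int = 1,
) -> list[EnrichedRegion]:
    """Maximal runs of consecutive significant probes, one sign at a time.

    A run qualifies when every member probe has the sign's tail p below
    ``probe_alpha`` and the run spans at least ``min_consecutive`` probes of
    one promoter's grid. The region interval spans the first probe's start
    to the last probe's end; region_p is the smallest member p and peak_z
    the most extreme member z.
    """
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    n = len(grid)
    if n == 0:
        return []
    p = stats["p_pos" if sign == 1 else "p_neg"].to_numpy(float)
    z = stats["z"].to_numpy(float)
    sig = p < params.probe_alpha
    regions: list[EnrichedRegion] = []
    for s, e in zip(*_promoter_blocks(grid)):
        block = sig[s:e]
        edges = np.flatnonzero(np.diff(np.r_[False, block, False]))
        for r0, r1 in zip(edges[::2], edges[1::2]):
            if r1 - r0 < params.min_consecutive:
                continue
            i0, i1 = s + r0, s + r1  # [i0, i1)
            iv = GenomicInterval(
                grid["chrom"].iat[i0],
                int(grid["start"].iat[i0]),
                int(grid["end"].iat[i1 - 1]),
            )
            zr = z[i0:i1]
            regions.append(
                EnrichedRegion(
                    interval=iv,
                    sign=sign,
                    promoter_id=grid["promoter_id"].iat[i0],
                    probe_ids=list(grid["probe_id"].iloc[i0:i1]),
                    region_p=float(p[i0:i1].min()),
                    peak_z=float(zr[np.argmax(np.abs(zr))]),
                )
            )
    return regions


def combine_replicates(
    per_replicate_regions: list[list[EnrichedRegion]],
    replicate_tracks: list[pd.DataFrame],
    grid: pd.DataFrame,
    params: DetectionParams = DetectionParams(),
    sign: int = 1,
) -> list[ConsensusRegion]:
    """Consensus regions from the probe-wise mean of smoothed replicate tracks.

    The averaged track is re-scored and re-called; a candidate survives only
    if every replicate contains a same-sign region overlapping it.
    """
    if len(per_replicate_regions) != len(replicate_tracks):
        raise ValueError("region lists and tracks must pair up one to one")
    n = len(grid)
    for t in replicate_tracks:
        if len(t) != n:
            raise ValueError("replicate track length does not match the probe grid")
    avg = pd.DataFrame(
        {
            "M_smooth": np.mean(
                [t["M_smooth"].to_numpy(float) for t in replicate_tracks], axis=0
            )
        }
    )
    called = call_regions(score_probes(avg, robust=params.robust_z), grid, params, sign=sign)
    out: list[ConsensusRegion] = []
    for reg in called:
        support = [
            any(
                r.sign == sign
                and r.promoter_id == reg.promoter_id
                and r.interval.overlaps(reg.interval)
                for r in rep_regions
            )
            for rep_regions in per_replicate_regions
        ]
        if all(support):
            out.append(
                ConsensusRegion(
                    interval=reg.interval,
                    sign=sign,
                    promoter_id=reg.promoter_id,
                    probe_ids=reg.probe_ids,
                    region_p=reg.region_p,
                    peak_z=reg.peak_z,
                    support=support,
                )
            )
    return out


def flag_questionable(
    positives: list[ConsensusRegion],
    negatives: list[ConsensusRegion],
    params: DetectionParams = DetectionParams(),
) -> list[ConsensusRegion]:
    """Flag positive regions masked by an adjacent larger IgG (negative) peak.

    A positive is questionable when a negative region of the same promoter
    lies within ``adjacency_bp`` (edge to edge; overlap counts as 0) and the
    negative peak has the larger |z|.
    """
    by_promoter: dict[str, list[ConsensusRegion]] = {}
    for neg in negatives:
        by_promoter.setdefault(neg.promoter_id, []).append(neg)
    out = []
    for pos in positives:
        masker = None
        for neg in by_promoter.get(pos.promoter_id, []):
            if (
                pos.interval.distance(neg.interval) <= params.adjacency_bp
                and abs(neg.peak_z) > abs(pos.peak_z)
            ):
                if masker is None or abs(neg.peak_z) > abs(masker.peak_z):
                    masker = neg
        out.append(
            replace(pos, questionable=masker is not None, masking_region=masker)
        )
    return out


def select_targets(
    consensus: list[ConsensusRegion], params: DetectionParams = DetectionParams()
) -> tuple[list[ConsensusRegion], list[ConsensusRegion]]:
    """Partition positive, non-questionable consensus regions by threshold.

    Returns ``(targets, relaxed)``: regions below ``target_alpha`` and the
    superset below ``relaxed_alpha``. One promoter may contribute several
    regions; use :func:`best_per_promoter` for a per-promoter summary.
    """
    eligible = [r for r in consensus if r.sign == 1 and not r.questionable]
    targets = [r for r in eligible if r.region_p < params.target_alpha]
    relaxed = [r for r in eligible if r.region_p < params.relaxed_alpha]
    return targets, relaxed


def best_per_promoter(regions: list[ConsensusRegion]) -> dict[str, ConsensusRegion]:
    best: dict[str, ConsensusRegion] = {}
    for r in regions:
        cur = best.get(r.promoter_id)
        if cur is None or r.region_p < cur.region_p:
            best[r.promoter_id] = r
    return best


@dataclass
class DetectionResult:
    """End-to-end detection output for one replicate set."""

    grid: pd.DataFrame
    positives: list[ConsensusRegion]
    negatives: list[ConsensusRegion]
    targets: list[ConsensusRegion]
    relaxed: list[ConsensusRegion]


def detect_targets(
    replicates: ReplicateSet,
    norm_params: NormalizationParams = NormalizationParams(),
    det_params: DetectionParams = DetectionParams(),
) -> DetectionResult:
    """Normalize, smooth, score, call and combine a full replicate set."""
    grid = replicates.probe_grid.reset_index(drop=True)
    tracks = normalize_replicates(list(replicates.arrays), norm_params)
    smoothed = [smooth_track(t, grid, det_params) for t in tracks]
    scored = [score_probes(s, robust=det_params.robust_z) for s in smoothed]
    pos_regs = [call_regions(sc, grid, det_params, sign=1) for sc in scored]
    neg_regs = [call_regions(sc, grid, det_params, sign=-1) for sc in scored]
    positives = combine_replicates(pos_regs, smoothed, grid, det_params, sign=1)
    negatives = combine_replicates(neg_regs, smoothed, grid, det_params, sign=-1)
    positives = flag_questionable(positives, negatives, det_params)
    targets, relaxed = select_targets(positives, det_params)
    return DetectionResult(grid, positives, negatives, targets, relaxed)
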