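"""Synthetic two-color promoter tiling-array experiments with ground truth.

Emulates the study design the analysis assumes: ~4.85 kb of tiled promoter
per gene (3880 bp upstream / 970 bp downstream of the TSS), 50-mer probes
every 100 bp, three biological replicates on an identical grid, a GC-
dependent dye bias on the factor channel, factor-bound regions of 400-600 bp
(the immunoprecipitated fragment size) spiked onto Cy5 with a fragment-
shaped taper, IgG-enriched artifacts spiked onto Cy3, and response-element
motifs planted into a configurable fraction of the bound regions. All
randomness flows through one seeded generator, so outputs are bitwise
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .array_io import ReplicateSet, TilingArray, write_probe_table
from .intervals import GenomicInterval, interval_to_string
from .motif_analysis import FACTOR_MOTIFS, IUPAC_CODES, IUPACMotif

__all__ = [
    "SimulationConfig",
    "PromoterTruth",
    "SyntheticTruth",
    "gc_bias_curve",
    "plant_motif",
    "generate_experiment",
    "write_experiment",
]

BASELINE_LOG2 = 10.0  # fixed baseline intensity for both channels
TAPER_BP = 500  # enrichment ramps linearly over one fragment length at edges
_N_CHROMS = 20
_PROMOTER_PITCH = 100_000  # genomic spacing between consecutive promoters


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    Defaults mirror the tiling design and the benchmark conditions of the
    analysis: spans (3880, 970) around the TSS, 50-mer probes every 100 bp,
    3 replicates, bound-region widths uniform in [400, 600] bp with a mean
    Cy5 enrichment of 1.5 log2 units, per-channel Gaussian noise sd 0.4,
    and a linear GC dye bias of 0.5 log2 units across the GC range.
    """

    n_promoters: int = 200
    promoter_span: tuple[int, int] = (3880, 970)
    probe_length: int = 50
    probe_spacing: int = 100
    n_replicates: int = 3
    fraction_spiked: float = 0.015
    spike_width: tuple[int, int] = (400, 600)
    spike_effect: float = 1.5
    fraction_igg_spiked: float = 0.015
    igg_effect: float = 1.5
    noise_sd: float = 0.4
    gc_bias_coeffs: tuple[float, ...] = (0.0, 0.5)
    fraction_direct: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_spiked", "fraction_igg_spiked", "fraction_direct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.spike_width
        if not 0 < lo <= hi:
            raise ValueError("spike_width bounds must satisfy 0 < lo <= hi")
        if hi > self.promoter_length:
            raise ValueError(
                f"spike_width {hi} exceeds promoter width {self.promoter_length}"
            )
        if self.probe_length <= 0 or self.probe_spacing <= 0 or self.n_replicates < 1:
            raise ValueError("probe geometry and replicate count must be positive")

    @property
    def promoter_length(self) -> int:
        return self.promoter_span[0] + self.promoter_span[1]

    @property
    def probes_per_promoter(self) -> int:
        return (self.promoter_length - self.probe_length) // self.probe_spacing + 1


@dataclass
class PromoterTruth:
    promoter_id: str
    interval: GenomicInterval
    bound: bool = False
    region: GenomicInterval | None = None
    motifs: list[tuple[str, int, str]] = field(default_factory=list)  # (name, start, strand)
    igg_region: GenomicInterval | None = None


@dataclass
class SyntheticTruth:
    """Per-promoter ground truth of one simulated experiment."""

    promoters: dict[str, PromoterTruth]

    def bound_regions(self) -> dict[str, GenomicInterval]:
        return {
            pid: t.region for pid, t in self.promoters.items() if t.bound and t.region
        }

    def to_json(self, path: str | Path) -> None:
        def enc(iv: GenomicInterval | None):
            return None if iv is None else interval_to_string(iv)

        payload = {
            pid: {
                "interval": enc(t.interval),
                "bound": t.bound,
                "region": enc(t.region),
                "motifs": t.motifs,
                "igg_region": enc(t.igg_region),
            }
            for pid, t in self.promoters.items()
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def gc_bias_curve(gc_fraction, coeffs) -> np.ndarray:
    """Smooth polynomial dye bias in (gc - 0.5): sum_k c_k (gc - 0.5)^k.

    With a centered curve (c_0 = 0) the bias vanishes at gc = 0.5.
    """
    gc = np.asarray(gc_fraction, dtype=float)
    if ((gc < 0) | (gc > 1)).any():
        raise ValueError("gc fractions must lie in [0, 1]")
    x = gc - 0.5
    out = np.zeros_like(x)
    for k, c in enumerate(coeffs):
        out += c * x**k
    return out


def plant_motif(
    sequence: str,
    motif: IUPACMotif,
    position: int,
    rng: np.random.Generator,
    occupied: list[tuple[int, int]] | None = None,
) -> str:
    """Write one realization of a degenerate motif into a sequence.

    Each degenerate position draws uniformly from its IUPAC class. Raises if
    the motif does not fit, or if it would overlap an interval in
    ``occupied`` (which is extended in place with the new placement).
    """
    L = len(motif)
    if position < 0 or position + L > len(sequence):
        raise ValueError(
            f"motif of length {L} does not fit at position {position} "
            f"in a sequence of length {len(sequence)}"
        )
    if occupied is not None:
        for lo, hi in occupied:
            if position < hi and lo < position + L:
                raise ValueError(
                    f"placement [{position}, {position + L}) overlaps existing "
                    f"plant [{lo}, {hi})"
                )
        occupied.append((position, position + L))
    word = "".join(
        IUPAC_CODES[c][rng.integers(len(IUPAC_CODES[c]))] for c in motif.pattern
    )
    return sequence[:position] + word + sequence[position + L:]


def _fragment_taper(centers: np.ndarray, start: float, end: float) -> np.ndarray:
    """Enrichment profile of a bound region under fragment hybridization.

    Every probe inside the region overlaps immunoprecipitated fragments, so
    the effect is full there; outside, coverage by ~fragment-length pieces
    decays linearly to zero over one fragment length (TAPER_BP).
    """
    inside = np.minimum(centers - start, end - centers)  # negative outside
    return np.clip(1.0 + inside / TAPER_BP, 0.0, 1.0)


def generate_experiment(
    config: SimulationConfig, factor: str = "SRY"
) -> tuple[ReplicateSet, list[SeqRecord], SyntheticTruth]:
    """Simulate a complete replicate set with sequences and ground truth.

    Returns the replicate arrays (identical probe grid, per-replicate
    noise), the promoter sequences as FASTA-ready records, and the truth
    needed for recovery benchmarking. Probe GC fractions are computed from
    the actual generated sequence under each probe, which is what couples
    the dye bias to sequence composition.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_promoters
    plen = config.promoter_length
    k = config.probes_per_promoter
    motif = FACTOR_MOTIFS[factor][0]

    # genomic layout: promoters tile _N_CHROMS chromosomes on a fixed pitch
    pids = [f"P{i:05d}" for i in range(n)]
    chrom_idx = np.arange(n) % _N_CHROMS
    chroms = [f"chr{c + 1}" for c in chrom_idx]
    prom_starts = 1_000_000 + (np.arange(n) // _N_CHROMS) * _PROMOTER_PITCH

    # sequences: i.i.d. uniform ACGT, base-coded for fast GC windows
    codes = rng.integers(0, 4, size=(n, plen), dtype=np.int8)
    base_arr = np.frombuffer(b"ACGT", dtype="S1")
    seqs = ["".join(np.char.decode(base_arr[row]).tolist()) for row in codes]

    # choose bound (spiked) promoters, their regions and planted motifs
    truth = {
        pid: PromoterTruth(
            pid,
            GenomicInterval(chroms[i], int(prom_starts[i]), int(prom_starts[i]) + plen),
        )
        for i, pid in enumerate(pids)
    }
    n_spiked = int(round(config.fraction_spiked * n))
    spiked = rng.choice(n, size=n_spiked, replace=False) if n_spiked else np.array([], int)
    n_direct = int(round(config.fraction_direct * n_spiked))
    direct = set(spiked[:n_direct].tolist())
    spike_lo = np.zeros(n)
    spike_hi = np.zeros(n)
    is_spiked = np.zeros(n, dtype=bool)
    for i in spiked:
        w = int(rng.integers(config.spike_width[0], config.spike_width[1] + 1))
        s = int(rng.integers(0, plen - w + 1))
        is_spiked[i] = True
        spike_lo[i], spike_hi[i] = s, s + w
        t = truth[pids[i]]
        t.bound = True
        t.region = GenomicInterval(
            chroms[i], int(prom_starts[i]) + s, int(prom_starts[i]) + s + w
        )
        if i in direct:
            occupied: list[tuple[int, int]] = []
            pos = int(rng.integers(s, s + w - len(motif) + 1))
            seqs[i] = plant_motif(seqs[i], motif, pos, rng, occupied)
            t.motifs.append((motif.name, int(prom_starts[i]) + pos, "+"))

    # IgG-enriched artifacts, sampled independently of factor spikes
    n_igg = int(round(config.fraction_igg_spiked * n))
    igg = rng.choice(n, size=n_igg, replace=False) if n_igg else np.array([], int)
    igg_lo = np.zeros(n)
    igg_hi = np.zeros(n)
    has_igg = np.zeros(n, dtype=bool)
    for i in igg:
        w = int(rng.integers(config.spike_width[0], config.spike_width[1] + 1))
        s = int(rng.integers(0, plen - w + 1))
        has_igg[i] = True
        igg_lo[i], igg_hi[i] = s, s + w
        truth[pids[i]].igg_region = GenomicInterval(
            chroms[i], int(prom_starts[i]) + s, int(prom_starts[i]) + s + w
        )

    # probe grid: local starts 0, spacing, ... ; GC from the actual sequence
    local_starts = np.arange(k) * config.probe_spacing
    is_gc = (codes == 1) | (codes == 2)  # C or G
    cs = np.concatenate(
        [np.zeros((n, 1), dtype=int), np.cumsum(is_gc, axis=1)], axis=1
    )
    gc_counts = cs[:, local_starts + config.probe_length] - cs[:, local_starts]
    gc = (gc_counts / config.probe_length).ravel()

    centers_local = local_starts + config.probe_length / 2.0
    spike_sig = np.zeros((n, k))
    rows = np.flatnonzero(is_spiked)
    if len(rows):
        spike_sig[rows] = config.spike_effect * _fragment_taper(
            centers_local[None, :], spike_lo[rows, None], spike_hi[rows, None]
        )
    igg_sig = np.zeros((n, k))
    rows = np.flatnonzero(has_igg)
    if len(rows):
        igg_sig[rows] = config.igg_effect * _fragment_taper(
            centers_local[None, :], igg_lo[rows, None], igg_hi[rows, None]
        )

    base = pd.DataFrame(
        {
            "probe_id": [f"{pid}_{j:03d}" for pid in pids for j in range(k)],
            "chrom": np.repeat(chroms, k),
            "start": (prom_starts[:, None] + local_starts[None, :]).ravel(),
            "end": (
                prom_starts[:, None] + local_starts[None, :] + config.probe_length
            ).ravel(),
            "gc": gc,
            "promoter_id": np.repeat(pids, k),
        }
    )
    bias = gc_bias_curve(gc, config.gc_bias_coeffs)
    cy5_clean = BASELINE_LOG2 + bias + spike_sig.ravel()
    cy3_clean = BASELINE_LOG2 + igg_sig.ravel()

    arrays = []
    for r in range(config.n_replicates):
        noise5 = rng.normal(0.0, config.noise_sd, size=len(base))
        noise3 = rng.normal(0.0, config.noise_sd, size=len(base))
        df = base.copy()
        df["cy5_log"] = cy5_clean + noise5
        df["cy3_log"] = cy3_clean + noise3
        arrays.append(TilingArray(f"{factor}_rep{r + 1}", df))

    records = [
        SeqRecord(
            Seq(seqs[i]),
            id=pids[i],
            description=interval_to_string(truth[pids[i]].interval),
        )
        for i in range(n)
    ]
    return ReplicateSet(factor, arrays), records, SyntheticTruth(truth)


def write_experiment(
    replicates: ReplicateSet,
    records: list[SeqRecord],
    truth: SyntheticTruth,
    out_dir: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write probe TSVs (one per replicate), promoters.fasta and truth.json."""
    from Bio import SeqIO

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for arr in replicates.arrays:
        write_probe_table(arr, out / f"{arr.array_id}.tsv", header_comment=header_comment)
    SeqIO.write(records, out / "promoters.fasta", "fasta")
    truth.to_json(out / "truth.json")
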