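"""End-to-end orchestration: simulate -> normalize -> call -> motifs -> report.

A run is driven by one :class:`RunConfig`; every stage output is a plain
text file carrying a header comment with the config hash and seed, and the
machine-readable result is the JSON report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .array_io import ReplicateSet, read_probe_table, write_regions_bed
from .intervals import interval_from_string, interval_to_string
from .motif_analysis import (
    FACTOR_MOTIFS,
    IUPACMotif,
    build_pfm,
    classify_targets,
    count_motifs_in_region,
    scan_iupac,
)
from .normalization import NormalizationParams
from .peak_detection import DetectionParams, DetectionResult, detect_targets
from .synthetic_data import SimulationConfig, generate_experiment, write_experiment

log = logging.getLogger("tilescan")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: Path
    factor: str = "SRY"
    seed: int = 0
    simulation: SimulationConfig | None = None
    input_dir: Path | None = None  # pre-existing probe TSVs + promoters.fasta
    normalization: NormalizationParams = field(default_factory=NormalizationParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    motifs: list[IUPACMotif] | None = None  # None -> the factor's default set
    both_strands: bool = False

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.simulation is None and self.input_dir is None:
            raise ValueError("need either a simulation config or an input_dir")

    def echo(self) -> dict:
        d = {
            "factor": self.factor,
            "seed": self.seed,
            "simulation": asdict(self.simulation) if self.simulation else None,
            "input_dir": str(self.input_dir) if self.input_dir else None,
            "normalization": asdict(self.normalization),
            "detection": asdict(self.detection),
            "motifs": [(m.name, m.pattern) for m in self.resolved_motifs()],
            "both_strands": self.both_strands,
        }
        return d

    def resolved_motifs(self) -> list[IUPACMotif]:
        return self.motifs if self.motifs is not None else FACTOR_MOTIFS[self.factor]

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.echo(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _load_input(input_dir: Path, factor: str):
    from Bio import SeqIO

    tsvs = sorted(input_dir.glob("*.tsv"))
    if not tsvs:
        raise FileNotFoundError(f"no probe TSVs under {input_dir}")
    replicates = ReplicateSet(factor, [read_probe_table(p) for p in tsvs])
    fasta = input_dir / "promoters.fasta"
    sequences = None
    if fasta.exists():
        sequences = {
            rec.id: (str(rec.seq), interval_from_string(rec.description.split()[-1]))
            for rec in SeqIO.parse(fasta, "fasta")
        }
    return replicates, sequences


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run report (also written as JSON)."""
    t0 = time.perf_counter()
    config.out_dir.mkdir(parents=True, exist_ok=True)
    header = f"tilescan {__version__} config={config.config_hash()} seed={config.seed}"
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.echo(),
        "stages": {},
    }

    def stage(name):
        log.info("stage %s ...", name)
        return time.perf_counter()

    # --- simulate / load -------------------------------------------------
    try:
        ts = stage("input")
        if config.simulation is not None:
            replicates, records, truth = generate_experiment(
                config.simulation, factor=config.factor
            )
            write_experiment(replicates, records, truth, config.out_dir / "input", header)
            sequences = {
                rec.id: (str(rec.seq), interval_from_string(rec.description.split()[-1]))
                for rec in records
            }
        else:
            replicates, sequences = _load_input(config.input_dir, config.factor)
        n_probes = len(replicates.arrays[0])
        report["stages"]["input"] = {
            "n_replicates": replicates.n_replicates,
            "n_probes": n_probes,
            "seconds": round(time.perf_counter() - ts, 3),
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineError("input", e) from e

    # --- normalize + call ------------------------------------------------
    try:
        ts = stage("detect")
        result: DetectionResult = detect_targets(
            replicates, config.normalization, config.detection
        )
        report["stages"]["detect"] = {
            "consensus_positive": len(result.positives),
            "consensus_negative": len(result.negatives),
            "questionable": sum(r.questionable for r in result.positives),
            "targets_at_target_alpha": len(result.targets),
            "targets_at_relaxed_alpha": len(result.relaxed),
            "seconds": round(time.perf_counter() - ts, 3),
        }
        write_regions_bed(
            [
                (r.interval, f"{r.promoter_id}|{'Q' if r.questionable else '+'}", r.region_p)
                for r in result.positives
            ],
            config.out_dir / "consensus_positive.bed",
            header,
        )
        write_regions_bed(
            [(r.interval, r.promoter_id, r.region_p) for r in result.negatives],
            config.out_dir / "consensus_negative.bed",
            header,
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("detect", e) from e

    # --- motifs + classification ----------------------------------------
    try:
        ts = stage("motifs")
        if sequences is None:
            raise FileNotFoundError("motif stage needs promoter sequences (FASTA)")
        motifs = config.resolved_motifs()
        candidates = [
            r for r in result.positives if r.region_p < config.detection.target_alpha
        ]
        counts = [
            count_motifs_in_region(
                r.interval,
                sequences[r.promoter_id][0],
                sequences[r.promoter_id][1],
                motifs,
                both_strands=config.both_strands,
            )
            for r in candidates
        ]
        calls = classify_targets(candidates, counts, config.factor)
        tally = {"direct": 0, "atypical": 0, "questionable": 0}
        for c in calls:
            tally[c.label] += 1
        with open(config.out_dir / "targets.tsv", "w") as fh:
            fh.write(f"# {header}\n")
            names = [m.name for m in motifs]
            fh.write(
                "promoter_id\tregion\tregion_p\tclass\t"
                + "\t".join(f"n_{n}" for n in names)
                + "\n"
            )
            for c in calls:
                fh.write(
                    f"{c.promoter_id}\t{interval_to_string(c.interval)}\t"
                    f"{c.region_p:.6g}\t{c.label}\t"
                    + "\t".join(str(c.motif_counts[n]) for n in names)
                    + "\n"
                )
        # consensus PFM over scan-anchored sites in direct target regions
        pfm_payload = None
        primary = motifs[0]
        hits = []
        site_seqs = {}
        for c in calls:
            if c.label != "direct":
                continue
            seq, span = sequences[c.promoter_id]
            lo = c.interval.start - span.start
            hi = c.interval.end - span.start
            region_seq = seq[lo:hi]
            site_seqs[c.promoter_id] = region_seq
            hits.extend(
                scan_iupac(region_seq, primary, both_strands=True, sequence_id=c.promoter_id)
            )
        if hits:
            pfm = build_pfm(hits, site_seqs)
            pfm_payload = pfm.to_dict()
            (config.out_dir / "pfm.json").write_text(json.dumps(pfm_payload, indent=1))
        report["stages"]["motifs"] = {
            "classified": len(calls),
            **tally,
            "pfm_sites": pfm_payload["n_sites"] if pfm_payload else 0,
            "pfm_consensus": pfm_payload["consensus"] if pfm_payload else None,
            "seconds": round(time.perf_counter() - ts, 3),
        }
    except Exception as e:  # noqa: BLE001
        raise PipelineError("motifs", e) from e

    report["total_seconds"] = round(time.perf_counter() - t0, 3)
    (config.out_dir / "report.json").write_text(json.dumps(report, indent=1))
    return report
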