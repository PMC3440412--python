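"""Readers/writers and in-memory containers for two-color promoter tiling arrays.

Probe tables are plain TSV with a mandatory header (columns ``probe_id,
chrom, start, end, gc, cy5_log, cy3_log, promoter_id``); regions go out as
BED6+. The two published target tables (direct binding targets of SRY and
of SOX9) ship as checksummed TSV fixtures.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, interval_from_string

__all__ = [
    "FormatError",
    "FixtureIntegrityError",
    "ProbeMeasurement",
    "TilingArray",
    "ReplicateSet",
    "TargetTableFixture",
    "read_probe_table",
    "write_probe_table",
    "write_regions_bed",
    "read_regions_bed",
    "load_target_fixture",
    "FIXTURE_NAMES",
]

PROBE_COLUMNS = [
    "probe_id",
    "chrom",
    "start",
    "end",
    "gc",
    "cy5_log",
    "cy3_log",
    "promoter_id",
]
_NUMERIC = {"start": int, "end": int, "gc": float, "cy5_log": float, "cy3_log": float}


class FormatError(ValueError):
    """A file violates the expected tabular format."""


class FixtureIntegrityError(RuntimeError):
    """A packaged fixture fails its recorded checksum."""


@dataclass(frozen=True)
class ProbeMeasurement:
    """One probe: coordinates, GC fraction and the two log2 channel intensities.

    ``cy5_log`` is the factor-ChIP channel, ``cy3_log`` the non-immune IgG
    control channel.
    """

    probe_id: str
    interval: GenomicInterval
    promoter_id: str
    gc_fraction: float
    cy5_log: float
    cy3_log: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError(f"gc_fraction out of [0,1]: {self.gc_fraction}")
        if not (np.isfinite(self.cy5_log) and np.isfinite(self.cy3_log)):
            raise ValueError(f"non-finite intensity on probe {self.probe_id}")


@dataclass
class TilingArray:
    """A single two-color hybridization: a coordinate-sorted probe table.

    ``probes`` is a DataFrame with :data:`PROBE_COLUMNS`; rows are sorted by
    (chrom, start) and probe_ids are unique.
    """

    array_id: str
    probes: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PROBE_COLUMNS if c not in self.probes.columns]
        if missing:
            raise FormatError(f"probe table missing column(s): {', '.join(missing)}")
        dup = self.probes["probe_id"][self.probes["probe_id"].duplicated()]
        if len(dup):
            raise FormatError(f"duplicate probe_id(s): {', '.join(dup.unique()[:5])}")
        self.probes = (
            self.probes.sort_values(["chrom", "start"], kind="mergesort")
            .reset_index(drop=True)
        )
        bad = ~(
            np.isfinite(self.probes["cy5_log"]) & np.isfinite(self.probes["cy3_log"])
        )
        if bad.any():
            raise FormatError(
                f"non-finite intensities on {int(bad.sum())} probe(s) "
                f"of array {self.array_id}"
            )
        gc = self.probes["gc"].to_numpy()
        if ((gc < 0) | (gc > 1)).any():
            raise FormatError("gc fractions must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.probes)

    def iter_probes(self) -> Iterator[ProbeMeasurement]:
        for row in self.probes.itertuples(index=False):
            yield ProbeMeasurement(
                probe_id=row.probe_id,
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                promoter_id=row.promoter_id,
                gc_fraction=float(row.gc),
                cy5_log=float(row.cy5_log),
                cy3_log=float(row.cy3_log),
            )


@dataclass
class ReplicateSet:
    """Biological replicates of one factor's ChIP, on an identical probe grid."""

    factor_name: str
    arrays: Sequence[TilingArray]

    def __post_init__(self) -> None:
        if len(self.arrays) < 1:
            raise ValueError("need at least one array")
        ref = self.arrays[0].probes
        for arr in self.arrays[1:]:
            p = arr.probes
            if len(p) != len(ref) or not (
                (p["probe_id"].to_numpy() == ref["probe_id"].to_numpy()).all()
                and (p["start"].to_numpy() == ref["start"].to_numpy()).all()
                and (p["chrom"].to_numpy() == ref["chrom"].to_numpy()).all()
            ):
                raise ValueError(
                    f"array {arr.array_id} does not share the probe grid of "
                    f"{self.arrays[0].array_id}"
                )

    @property
    def n_replicates(self) -> int:
        return len(self.arrays)

    @property
    def probe_grid(self) -> pd.DataFrame:
        return self.arrays[0].probes[["probe_id", "chrom", "start", "end", "promoter_id", "gc"]]


def read_probe_table(path: str | Path, array_id: str | None = None) -> TilingArray:
    """Read a probe TSV into a :class:`TilingArray`.

    The header must define all of :data:`PROBE_COLUMNS`. Non-numeric values
    in numeric columns raise :class:`FormatError` with the offending line.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing column(s): {', '.join(missing)}"
        )
    for col, typ in _NUMERIC.items():
        try:
            df[col] = df[col].astype(typ)
        except (TypeError, ValueError):
            conv = pd.to_numeric(df[col], errors="coerce")
            bad = int(np.flatnonzero(conv.isna() & df[col].notna())[0])
            raise FormatError(
                f"{path.name}: non-numeric value {df[col].iloc[bad]!r} in column "
                f"{col!r} at data line {bad + 2}"
            ) from None
    return TilingArray(array_id or path.stem, df[PROBE_COLUMNS])


def write_probe_table(
    array: TilingArray,
    path: str | Path,
    extra_columns: pd.DataFrame | None = None,
    header_comment: str | None = None,
) -> None:
    """Write a probe table as TSV, optionally with appended columns."""
    df = array.probes
    if extra_columns is not None:
        df = pd.concat([df.reset_index(drop=True), extra_columns.reset_index(drop=True)], axis=1)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def _bed_score(p: float) -> int:
    # conventional -log10(p) x 10 encoding, capped at the BED maximum
    with np.errstate(divide="ignore"):
        s = -10.0 * np.log10(p)
    return int(min(round(s), 1000))


def write_regions_bed(
    regions: Iterable[tuple[GenomicInterval, str, float]],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write (interval, name, p-value) records as BED6+1 (last column = raw p)."""
    with open(path, "w") as fh:
        fh.write("# BED6+1: chrom start end name score strand p_value\n")
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        for iv, name, p in regions:
            if not 0.0 < p <= 1.0:
                raise ValueError(f"p-value out of (0,1]: {p}")
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{_bed_score(p)}\t"
                f"{iv.strand}\t{p:.6g}\n"
            )


def read_regions_bed(path: str | Path) -> list[tuple[GenomicInterval, str, float]]:
    out: list[tuple[GenomicInterval, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 7:
                raise FormatError(f"line {lineno}: expected >= 7 BED columns")
            chrom, start, end, name, _score, strand, p = parts[:7]
            out.append(
                (GenomicInterval(chrom, int(start), int(end), strand), name, float(p))
            )
    return out


# ---------------------------------------------------------------------------
# Packaged target-table fixtures


@dataclass
class TargetTableFixture:
    """One published target table, row-for-row as printed.

    The source prose counts 71 SRY genes and 109 SOX9 promoters, but the
    printed tables enumerate 72 and 107 rows; the fixtures store the printed
    rows verbatim (including symbol spellings) rather than reconciling the
    counts.
    """

    name: str
    rows: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.rows)

    def gene_symbols(self) -> list[str]:
        return list(self.rows["gene_symbol"])

    def intervals(self) -> list[GenomicInterval]:
        return [interval_from_string(s) for s in self.rows["location"]]


FIXTURE_NAMES = {
    "sry_table1": "table1_sry_targets.tsv",
    "sox9_table2": "table2_sox9_targets.tsv",
}


def _data_path(filename: str) -> Path:
    return Path(importlib.resources.files("tilescan.data") / filename)


def load_target_fixture(name: str) -> TargetTableFixture:
    """Load a packaged target table (``sry_table1`` or ``sox9_table2``).

    The file's sha256 is verified against the recorded checksum.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(FIXTURE_NAMES))}"
        )
    path = _data_path(FIXTURE_NAMES[name])
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    recorded = json.loads(_data_path("checksums.json").read_text())
    if digest != recorded[FIXTURE_NAMES[name]]:
        raise FixtureIntegrityError(
            f"checksum mismatch for packaged fixture {FIXTURE_NAMES[name]}"
        )
    df = pd.read_csv(path, sep="\t", dtype=str)
    df["p_value"] = df["p_value"].astype(float)
    for col in ("sry_motifs", "sox9_motifs"):
        if col in df.columns:
            df[col] = df[col].astype("Int64")
    if not ((df["p_value"] > 0) & (df["p_value"] < 1)).all():
        raise FixtureIntegrityError(f"{name}: p-values outside (0,1)")
    for s in df["location"]:
        interval_from_string(s)  # validates the printed coordinate strings
    return TargetTableFixture(name, df)
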