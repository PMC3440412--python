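"""Genomic interval primitives and coordinate-convention conversion.

All internal coordinates are 0-based half-open (BED convention). The
1-based inclusive ``chrN:start-end`` strings used by the published target
tables are converted on load/save by :func:`interval_from_string` /
:func:`interval_to_string`, which are exact inverses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "GenomicInterval",
    "interval_from_string",
    "interval_to_string",
    "PromoterAnnotation",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    Parameters
    ----------
    chrom : str
        Chromosome name (non-empty).
    start, end : int
        Half-open bounds; ``start < end``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"require start < end, got {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance(self, other: "GenomicInterval") -> int:
        """Edge-to-edge distance; 0 when the intervals overlap or abut."""
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        if self.start < other.end and other.start < self.end:
            return 0
        return max(self.start, other.start) - min(self.end, other.end)

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


_REGION_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


def interval_from_string(s: str) -> GenomicInterval:
    """Parse a 1-based inclusive ``chrN:start-end`` string.

    ``chr1:101-200`` maps to the half-open interval ``(chr1, 100, 200)``.
    """
    m = _REGION_RE.match(s.strip())
    if m is None:
        raise ValueError(f"malformed region string {s!r}")
    chrom, start1, end1 = m.group(1), int(m.group(2)), int(m.group(3))
    return GenomicInterval(chrom, start1 - 1, end1)


def interval_to_string(iv: GenomicInterval) -> str:
    """Format as the 1-based inclusive convention of the target tables."""
    return f"{iv.chrom}:{iv.start + 1}-{iv.end}"


@dataclass(frozen=True)
class PromoterAnnotation:
    """A tiled promoter: its span, TSS and gene assignment.

    The tiling design covers ``upstream_span`` bases upstream of the TSS
    and ``downstream_span`` bases downstream (defaults elsewhere: 3880/970).
    """

    promoter_id: str
    gene_symbol: str
    interval: GenomicInterval
    tss: int
    upstream_span: int
    downstream_span: int

    def __post_init__(self) -> None:
        if not self.interval.contains_point(self.tss):
            raise ValueError(
                f"TSS {self.tss} outside promoter interval for {self.promoter_id}"
            )
        if self.upstream_span < 0 or self.downstream_span < 0:
            raise ValueError("spans must be nonnegative")
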