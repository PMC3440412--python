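"""Degenerate (IUPAC) motif scanning, target classification and PFM building.

SRY recognizes the HMG-box response element [T/A]AACAA[T/A] (pattern
``WAACAAW``) and its reverse complement [T/A]TTGTT[A/T] (``WTTGTTW``); SOX9
recognizes a SOX9-specific element [T/C]TTG[T/A]G (``YTTGWG``) in addition
to the shared HMG element. An enriched promoter region carrying at least
one of its factor's elements is a *direct* target; one without any element
is *atypical* (recruitment through protein-protein association); regions
masked by adjacent IgG peaks stay *questionable* regardless of motif
content. Consensus motifs are summarized as position frequency matrices
over scan-anchored sites with per-column information content in bits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval
from .peak_detection import ConsensusRegion

__all__ = [
    "IUPAC_CODES",
    "IUPACMotif",
    "MotifHit",
    "PositionFrequencyMatrix",
    "reverse_complement",
    "scan_iupac",
    "count_motifs_in_region",
    "TargetCall",
    "classify_targets",
    "build_pfm",
    "FACTOR_MOTIFS",
    "motif_match_probability",
]

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_SET_TO_CODE = {frozenset(v): k for k, v in IUPAC_CODES.items()}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class IUPACMotif:
    """A named degenerate nucleotide pattern."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        bad = set(self.pattern.upper()) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"invalid IUPAC code(s) in pattern: {sorted(bad)}")
        object.__setattr__(self, "pattern", self.pattern.upper())

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def regex(self) -> re.Pattern:
        # N in the subject never matches, so classes enumerate ACGT only
        return re.compile("".join(f"[{IUPAC_CODES[c]}]" for c in self.pattern))

    def match_probability(self) -> float:
        """Per-position match probability under i.i.d. uniform ACGT."""
        p = 1.0
        for c in self.pattern:
            p *= len(IUPAC_CODES[c]) / 4.0
        return p


# the per-position probability used in analytic background-rate arguments
def motif_match_probability(motif: IUPACMotif) -> float:
    return motif.match_probability()


FACTOR_MOTIFS: dict[str, list[IUPACMotif]] = {
    "SRY": [IUPACMotif("SRY_RE", "WAACAAW"), IUPACMotif("SRY_RE_RC", "WTTGTTW")],
    "SOX9": [IUPACMotif("SOX9_RE", "YTTGWG"), IUPACMotif("HMG_RE", "WAACAAW")],
}


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    sequence_id: str
    offset: int  # 0-based start in plus-strand coordinates
    strand: str  # '+' or '-'
    word: str  # matched word as read on its own strand

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.offset < 0:
            raise ValueError("negative offset")


def scan_iupac(
    sequence: str,
    motif: IUPACMotif,
    both_strands: bool = False,
    sequence_id: str = "",
) -> list[MotifHit]:
    """All (possibly overlapping) occurrences of a degenerate pattern.

    Minus-strand hits are reported in plus-strand coordinates. A palindromic
    word matching at the same offset on both strands is counted once (as the
    plus-strand hit).
    """
    seq = sequence.upper()
    pat = motif.regex
    hits = [
        MotifHit(motif.name, sequence_id, m.start(), "+", m.group())
        for m in _overlapping(pat, seq)
    ]
    if both_strands:
        rc = reverse_complement(seq)
        fwd_offsets = {h.offset for h in hits}
        for m in _overlapping(pat, rc):
            off = len(seq) - (m.start() + len(motif))
            word = m.group()
            if off in fwd_offsets and reverse_complement(word) == word:
                continue  # palindromic double-count guard
            hits.append(MotifHit(motif.name, sequence_id, off, "-", word))
    return sorted(hits, key=lambda h: (h.offset, h.strand))


def _overlapping(pat: re.Pattern, seq: str):
    pos = 0
    while True:
        m = pat.search(seq, pos)
        if m is None:
            return
        yield m
        pos = m.start() + 1


def count_motifs_in_region(
    region: GenomicInterval,
    sequence: str,
    sequence_interval: GenomicInterval,
    motifs: list[IUPACMotif],
    both_strands: bool = False,
) -> dict[str, int]:
    """Per-motif hit counts whose start lies inside a genomic region.

    ``sequence`` covers ``sequence_interval``; the region must lie within
    that mapped span. Hits are deduplicated by (offset, strand, motif).
    """
    if region.chrom != sequence_interval.chrom or not (
        sequence_interval.start <= region.start
        and region.end <= sequence_interval.end
    ):
        raise ValueError(
            f"region {region} outside mapped span {sequence_interval}"
        )
    counts: dict[str, int] = {}
    for motif in motifs:
        hits = scan_iupac(sequence, motif, both_strands=both_strands)
        genomic_starts = {
            (sequence_interval.start + h.offset, h.strand) for h in hits
        }
        counts[motif.name] = sum(
            1 for g, _ in genomic_starts if region.start <= g < region.end
        )
    return counts


@dataclass
class TargetCall:
    """A classified promoter target: direct, atypical or questionable."""

    promoter_id: str
    interval: GenomicInterval
    label: str  # 'direct' | 'atypical' | 'questionable'
    motif_counts: dict[str, int] = field(default_factory=dict)
    region_p: float = 1.0


def classify_targets(
    targets: list[ConsensusRegion],
    motif_counts: list[dict[str, int]],
    factor: str | None = None,
) -> list[TargetCall]:
    """Partition targets into direct / atypical / questionable.

    The questionable flag (IgG masking) takes precedence; otherwise a target
    is *direct* iff any of the factor's patterns hits at least once in its
    region, else *atypical*. ``factor`` is informational — the counts passed
    in define the pattern set.
    """
    if len(targets) != len(motif_counts):
        raise ValueError("targets and motif_counts must align")
    calls = []
    for reg, counts in zip(targets, motif_counts):
        if reg.questionable:
            label = "questionable"
        elif sum(counts.values()) >= 1:
            label = "direct"
        else:
            label = "atypical"
        calls.append(
            TargetCall(reg.promoter_id, reg.interval, label, dict(counts), reg.region_p)
        )
    return calls


@dataclass
class PositionFrequencyMatrix:
    """Base counts over aligned binding-site words (4 x L, rows A,C,G,T)."""

    counts: np.ndarray
    n_sites: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x L matrix")
        if (self.counts.sum(axis=0) != self.n_sites).any():
            raise ValueError("every column must sum to n_sites")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_sites

    def information_content(self) -> np.ndarray:
        """Per-column information in bits: 2 + sum_b f log2 f, in [0, 2]."""
        f = self.frequencies()
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(f > 0, f * np.log2(f), 0.0)
        return 2.0 + h.sum(axis=0)

    def consensus(self, degeneracy_threshold: float = 0.25) -> str:
        """Majority base per column, degenerate where a runner-up base
        reaches ``degeneracy_threshold`` of the sites."""
        out = []
        for col in self.counts.T:
            top = int(np.argmax(col))
            keep = {
                _BASES[i]
                for i in range(4)
                if i == top or col[i] >= degeneracy_threshold * self.n_sites
            }
            out.append(_SET_TO_CODE[frozenset(keep)])
        return "".join(out)

    def to_dict(self) -> dict:
        return {
            "bases": list(_BASES),
            "counts": self.counts.tolist(),
            "n_sites": self.n_sites,
            "information_content": [float(x) for x in self.information_content()],
            "consensus": self.consensus(),
        }


def build_pfm(
    hits: list[MotifHit],
    sequences: dict[str, str],
    flank: int = 0,
) -> PositionFrequencyMatrix:
    """Stack scan-anchored sites into a PFM.

    Minus-strand words are reverse-complemented before stacking so every row
    reads in motif orientation. With ``flank > 0`` each site is extended on
    both sides from its source sequence; sites whose flanks run off the
    sequence are dropped. All words must share one length.
    """
    if not hits:
        raise ValueError("cannot build a PFM from zero hits")
    words = []
    for h in hits:
        seq = sequences[h.sequence_id].upper()
        lo, hi = h.offset - flank, h.offset + len(h.word) + flank
        if lo < 0 or hi > len(seq):
            continue
        word = seq[lo:hi]
        if h.strand == "-":
            word = reverse_complement(word)
        words.append(word)
    if not words:
        raise ValueError("all hits lost their flanks at sequence edges")
    lengths = {len(w) for w in words}
    if len(lengths) != 1:
        raise ValueError(f"sites have differing lengths: {sorted(lengths)}")
    L = lengths.pop()
    counts = np.zeros((4, L), dtype=int)
    for w in words:
        for j, b in enumerate(w):
            counts[_BASE_INDEX[b], j] += 1
    return PositionFrequencyMatrix(counts, len(words))
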