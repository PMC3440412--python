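"""Gene-set overlap, functional-category tabulation and Fisher enrichment.

Implements the set-level characterization of final target lists: exact
symbol intersection between factors, percent overlap with the smaller set
as denominator, per-category counts, and one-sided Fisher's exact
(hypergeometric) over-representation of pathway membership with
Benjamini-Hochberg q-values reported alongside the raw p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "intersect_gene_sets",
    "overlap_report",
    "fisher_enrichment",
    "categorize",
    "UNMAPPED_CATEGORY",
]

UNMAPPED_CATEGORY = "Miscellaneous & Unknown"


@dataclass
class GeneSet:
    """A labelled set of gene symbols (case-preserving, whitespace-trimmed)."""

    label: str
    symbols: frozenset[str] = field(default_factory=frozenset)

    def __init__(self, label: str, symbols) -> None:
        self.label = label
        self.symbols = frozenset(s.strip() for s in symbols if s.strip())

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol.strip() in self.symbols


def intersect_gene_sets(a: GeneSet, b: GeneSet) -> GeneSet:
    """Exact symbol intersection; the label records both parents."""
    return GeneSet(f"{a.label} & {b.label}", a.symbols & b.symbols)


def overlap_report(a: GeneSet, b: GeneSet) -> dict:
    """Sizes, intersection size and percent overlap of two gene sets.

    Percent overlap uses the smaller set as denominator:
    ``100 * |a & b| / min(|a|, |b|)``.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("overlap_report requires non-empty gene sets")
    inter = a.symbols & b.symbols
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_intersection": len(inter),
        "percent_overlap": 100.0 * len(inter) / min(len(a), len(b)),
        "shared_symbols": sorted(inter),
    }


@dataclass(frozen=True)
class EnrichmentResult:
    """One pathway's 2x2 table, odds ratio and one-sided p-value.

    Cells: k targets in pathway, n - k targets outside, K - k non-target
    pathway genes, N - K - n + k remaining universe genes.
    """

    pathway: str
    k: int
    n: int
    K: int
    N: int
    odds_ratio: float
    p_value: float
    q_value: float = float("nan")

    @property
    def table(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (
            (self.k, self.n - self.k),
            (self.K - self.k, self.N - self.K - self.n + self.k),
        )


def fisher_enrichment(
    targets: GeneSet,
    pathways: dict[str, set[str] | frozenset[str] | list[str]],
    universe: GeneSet,
) -> list[EnrichmentResult]:
    """One-sided over-representation test per pathway, sorted by p-value.

    Pathway gene lists are intersected with the universe before counting;
    target genes must all belong to the universe. The p-value is the upper
    hypergeometric tail P(X >= k); q-values are Benjamini-Hochberg.
    """
    stray = targets.symbols - universe.symbols
    if stray:
        raise ValueError(
            f"target gene(s) absent from universe: {', '.join(sorted(stray)[:10])}"
        )
    N = len(universe)
    n = len(targets)
    results = []
    for name, genes in pathways.items():
        members = frozenset(g.strip() for g in genes) & universe.symbols
        K = len(members)
        k = len(members & targets.symbols)
        p = float(sps.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        a, b = k, n - k
        c, d = K - k, N - K - n + k
        odds = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else float("nan")
        results.append(EnrichmentResult(name, k, n, K, N, odds, min(p, 1.0)))
    results.sort(key=lambda r: (r.p_value, r.pathway))
    if results:
        q = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        results = [
            EnrichmentResult(r.pathway, r.k, r.n, r.K, r.N, r.odds_ratio, r.p_value, float(qi))
            for r, qi in zip(results, q)
        ]
    return results


def categorize(targets: GeneSet, category_map: dict[str, str]) -> pd.Series:
    """Counts of targets per functional category.

    Symbols absent from the (possibly partial) map fall under
    ``Miscellaneous & Unknown``. Counts sum to ``len(targets)``.
    """
    if len(targets) == 0:
        return pd.Series(dtype=int)
    cleaned = {k.strip(): v.strip() for k, v in category_map.items()}
    cats = [cleaned.get(s, UNMAPPED_CATEGORY) for s in targets.symbols]
    return pd.Series(cats).value_counts().sort_index()
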