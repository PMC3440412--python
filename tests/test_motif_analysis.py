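"""IUPAC scanning, target classification and PFM construction."""

import numpy as np
import pytest
from scipy.stats import poisson

from tilescan import (
    FACTOR_MOTIFS,
    GenomicInterval,
    IUPACMotif,
    build_pfm,
    classify_targets,
    count_motifs_in_region,
    reverse_complement,
    scan_iupac,
)
from tilescan.motif_analysis import MotifHit, motif_match_probability
from tilescan.peak_detection import ConsensusRegion

WAACAAW = FACTOR_MOTIFS["SRY"][0]
WTTGTTW = FACTOR_MOTIFS["SRY"][1]


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestScan:
    def test_taacaat_matches_at_zero(self):
        hits = scan_iupac("TAACAAT", WAACAAW)
        assert len(hits) == 1
        assert (hits[0].offset, hits[0].strand, hits[0].word) == (0, "+", "TAACAAT")

    def test_no_hits_in_poly_g(self):
        assert scan_iupac("G" * 30, WAACAAW) == []
        assert scan_iupac("G" * 30, WAACAAW, both_strands=True) == []

    def test_n_never_matches(self):
        assert scan_iupac("TAACAAN", WAACAAW) == []

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            IUPACMotif("bad", "WAAXAA")

    def test_overlapping_hits_reported(self):
        # AACAA core shared: TAACAATAACAAT has hits at 0 and 6
        hits = scan_iupac("TAACAATAACAAT", WAACAAW)
        assert [h.offset for h in hits] == [0, 6]

    def test_sry_elements_are_mutual_reverse_complements(self, rng):
        """Forward hits of WAACAAW on s mirror WTTGTTW hits on revcomp(s)."""
        for _ in range(25):
            s = _random_seq(rng, 100)
            fwd = {h.offset for h in scan_iupac(s, WAACAAW)}
            rc = {
                len(s) - (h.offset + 7)
                for h in scan_iupac(reverse_complement(s), WTTGTTW)
            }
            # exhaustive coordinate-mapping oracle
            direct = {
                i
                for i in range(len(s) - 6)
                if s[i] in "TA" and s[i + 1 : i + 6] == "AACAA" and s[i + 6] in "TA"
            }
            assert fwd == rc == direct

    def test_strand_closure(self, rng):
        """Both-strand scan = forward scan of s plus mapped forward scan of revcomp."""
        motif = IUPACMotif("sox", "YTTGWG")
        for _ in range(25):
            s = _random_seq(rng, 120)
            both = {(h.offset, h.strand) for h in scan_iupac(s, motif, both_strands=True)}
            fwd = {(h.offset, "+") for h in scan_iupac(s, motif)}
            minus = {
                (len(s) - (h.offset + len(motif)), "-")
                for h in scan_iupac(reverse_complement(s), motif)
            }
            # palindromic guard: drop minus hits that coincide with a
            # self-reverse-complementary plus hit
            guarded = {
                (off, st)
                for off, st in minus
                if not (
                    (off, "+") in fwd
                    and reverse_complement(s[off : off + len(motif)])
                    == s[off : off + len(motif)]
                )
            }
            assert both == fwd | guarded

    def test_palindrome_counted_once(self):
        pal = IUPACMotif("pal", "AATT")
        hits = scan_iupac("GGAATTGG", pal, both_strands=True)
        assert len(hits) == 1 and hits[0].strand == "+"


class TestCountInRegion:
    SPAN = GenomicInterval("chr5", 1000, 1100)

    def test_planted_motif_counted(self, rng):
        seq = "G" * 40 + "TAACAAT" + "G" * 53
        counts = count_motifs_in_region(
            GenomicInterval("chr5", 1030, 1060), seq, self.SPAN, [WAACAAW, WTTGTTW]
        )
        assert counts == {"SRY_RE": 1, "SRY_RE_RC": 0}

    def test_shifted_region_excludes_plant(self):
        seq = "G" * 40 + "TAACAAT" + "G" * 53
        counts = count_motifs_in_region(
            GenomicInterval("chr5", 1050, 1090), seq, self.SPAN, [WAACAAW]
        )
        assert counts["SRY_RE"] == 0

    def test_region_outside_span_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            count_motifs_in_region(
                GenomicInterval("chr5", 900, 950), "G" * 100, self.SPAN, [WAACAAW]
            )

    def test_background_rate_matches_analytic_expectation(self, rng):
        """Hits in i.i.d. sequence follow the closed-form match probability.

        Per-position probability of WAACAAW on one strand is
        (2/4)*(1/4)^5*(2/4) = 2.44e-4; a 10 kb scan is checked against the
        Poisson 99% band around the analytic mean.
        """
        p = motif_match_probability(WAACAAW)
        assert p == pytest.approx(2.44e-4, rel=0.01)
        L, trials = 10_000, 20
        lam = trials * 2 * (L - 6) * p  # both strands
        total = 0
        for _ in range(trials):
            seq = _random_seq(rng, L)
            hits = scan_iupac(seq, WAACAAW, both_strands=True)
            total += len(hits)
        lo, hi = poisson.ppf(0.005, lam), poisson.ppf(0.995, lam)
        assert lo <= total <= hi


def _target(questionable=False, pid="P0"):
    return ConsensusRegion(
        GenomicInterval("chr1", 0, 500), 1, pid, [], 1e-9, 6.0, [True] * 3, questionable
    )


class TestClassify:
    def test_direct_atypical_questionable(self):
        targets = [_target(), _target(), _target(questionable=True)]
        counts = [{"SRY_RE": 1}, {"SRY_RE": 0}, {"SRY_RE": 2}]
        calls = classify_targets(targets, counts, "SRY")
        assert [c.label for c in calls] == ["direct", "atypical", "questionable"]

    def test_partition_is_total(self, rng):
        targets = [_target(questionable=bool(rng.integers(2))) for _ in range(30)]
        counts = [{"m": int(rng.integers(3))} for _ in range(30)]
        calls = classify_targets(targets, counts, "SRY")
        assert all(c.label in {"direct", "atypical", "questionable"} for c in calls)

    def test_any_pattern_suffices_for_direct(self):
        calls = classify_targets(
            [_target()], [{"SOX9_RE": 0, "HMG_RE": 1}], "SOX9"
        )
        assert calls[0].label == "direct"


class TestPFM:
    def test_identical_words_give_two_bits(self):
        hits = [MotifHit("m", f"s{i}", 0, "+", "TAACAAT") for i in range(10)]
        seqs = {f"s{i}": "TAACAAT" for i in range(10)}
        pfm = build_pfm(hits, seqs)
        assert pfm.n_sites == 10
        np.testing.assert_allclose(pfm.information_content(), 2.0, atol=1e-12)
        assert pfm.consensus() == "TAACAAT"

    def test_uniform_sites_near_zero_information(self, rng):
        n = 10_000
        words = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(n)]
        hits = [MotifHit("m", f"s{i}", 0, "+", w) for i, w in enumerate(words)]
        pfm = build_pfm(hits, {f"s{i}": w for i, w in enumerate(words)})
        assert pfm.information_content().mean() < 0.05

    def test_columns_conserve_site_count(self, rng):
        words = ["".join(rng.choice(list("ACGT"), size=6)) for _ in range(37)]
        hits = [MotifHit("m", f"s{i}", 0, "+", w) for i, w in enumerate(words)]
        pfm = build_pfm(hits, {f"s{i}": w for i, w in enumerate(words)})
        np.testing.assert_array_equal(pfm.counts.sum(axis=0), 37)

    def test_minus_strand_words_oriented(self):
        # site on minus strand: plus-strand sequence holds the revcomp
        seqs = {"s": "ATTGTTA"}  # revcomp -> TAACAAT
        hits = [MotifHit("m", "s", 0, "-", "TAACAAT")]
        pfm = build_pfm(hits, seqs)
        assert pfm.consensus() == "TAACAAT"

    def test_degenerate_consensus_with_25pct_runner_up(self):
        words = ["TAACAAT"] * 6 + ["AAACAAT"] * 4  # first column 60% T / 40% A
        hits = [MotifHit("m", f"s{i}", 0, "+", w) for i, w in enumerate(words)]
        pfm = build_pfm(hits, {f"s{i}": w for i, w in enumerate(words)})
        assert pfm.consensus() == "WAACAAT"

    def test_zero_hits_rejected(self):
        with pytest.raises(ValueError, match="zero hits"):
            build_pfm([], {})

    def test_flank_extension_and_edge_drop(self):
        seqs = {"a": "GGTAACAATCC", "b": "TAACAAT"}
        hits = [MotifHit("m", "a", 2, "+", "TAACAAT"), MotifHit("m", "b", 0, "+", "TAACAAT")]
        pfm = build_pfm(hits, seqs, flank=2)
        assert pfm.n_sites == 1 and pfm.length == 11  # 'b' has no room for flanks
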