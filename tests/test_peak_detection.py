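"""Smoothing, scoring and region calling against brute-force enumerations."""

import math

import numpy as np
import pandas as pd
import pytest

from tilescan import (
    DetectionParams,
    call_regions,
    combine_replicates,
    flag_questionable,
    score_probes,
    select_targets,
    smooth_track,
)
from tilescan.intervals import GenomicInterval
from tilescan.peak_detection import ConsensusRegion, EnrichedRegion
from tests.conftest import make_array


def _grid(array):
    return array.probes[["probe_id", "chrom", "start", "end", "promoter_id", "gc"]]


def _ma(array):
    from tilescan import compute_ma

    return compute_ma(array)


def bruteforce_median_smooth(m, centers, promoter_ids, window_bp):
    """Direct enumeration of every probe's window."""
    out = np.empty(len(m))
    for i in range(len(m)):
        sel = [
            j
            for j in range(len(m))
            if promoter_ids[j] == promoter_ids[i]
            and abs(centers[j] - centers[i]) <= window_bp / 2
        ]
        out[i] = np.median([m[j] for j in sel])
    return out


def bruteforce_runs(sig, promoter_ids, min_len):
    """All maximal runs of True within one promoter, as (start, stop) index pairs."""
    runs = []
    i = 0
    n = len(sig)
    while i < n:
        if sig[i]:
            j = i
            while j + 1 < n and sig[j + 1] and promoter_ids[j + 1] == promoter_ids[i]:
                j += 1
            if j - i + 1 >= min_len:
                runs.append((i, j + 1))
            i = j + 1
        else:
            i += 1
    return runs


class TestSmoothTrack:
    def test_constant_track(self):
        arr = make_array([3.3] * 10)
        sm = smooth_track(_ma(arr), _grid(arr))
        np.testing.assert_allclose(sm["M_smooth"], 3.3, atol=1e-12)

    def test_three_probe_example(self):
        # probes at 0/100/200 bp with M = (0, 10, 0) and a 600 bp window:
        # every window holds all three values, so every median is 0
        arr = make_array([0.0, 10.0, 0.0])
        sm = smooth_track(_ma(arr), _grid(arr))
        np.testing.assert_array_equal(sm["M_smooth"], 0.0)
        np.testing.assert_array_equal(sm["window_count"], 3)

    def test_isolated_probe_keeps_own_value(self):
        arr = make_array([1.0, 5.0], spacing=1000)
        sm = smooth_track(_ma(arr), _grid(arr))
        np.testing.assert_array_equal(sm["M_smooth"], [1.0, 5.0])
        np.testing.assert_array_equal(sm["window_count"], 1)

    def test_window_clipped_at_promoter_boundary(self, rng):
        m = rng.normal(size=20)
        arr = make_array(m)
        df = arr.probes.copy()
        df.loc[10:, "promoter_id"] = "P1"
        from tilescan import TilingArray

        arr2 = TilingArray("two_prom", df)
        sm = smooth_track(_ma(arr2), _grid(arr2))
        pid = arr2.probes["promoter_id"].to_numpy()
        centers = 0.5 * (arr2.probes["start"] + arr2.probes["end"]).to_numpy()
        expected = bruteforce_median_smooth(m, centers, pid, 600)
        np.testing.assert_allclose(sm["M_smooth"], expected, atol=1e-12)

    def test_matches_bruteforce_on_irregular_grid(self, rng):
        n = 60
        starts = np.sort(rng.choice(5000, size=n, replace=False))
        m = rng.normal(size=n)
        from tilescan import TilingArray

        df = pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(n)],
                "chrom": "chr1",
                "start": starts,
                "end": starts + 50,
                "gc": 0.5,
                "cy5_log": 10 + m / 2,
                "cy3_log": 10 - m / 2,
                "promoter_id": np.where(np.arange(n) < 25, "P0", "P1"),
            }
        )
        arr = TilingArray("irr", df)
        sm = smooth_track(_ma(arr), _grid(arr))
        centers = 0.5 * (arr.probes["start"] + arr.probes["end"]).to_numpy()
        expected = bruteforce_median_smooth(
            arr.probes["cy5_log"].to_numpy() - arr.probes["cy3_log"].to_numpy(),
            centers,
            arr.probes["promoter_id"].to_numpy(),
            600,
        )
        np.testing.assert_allclose(sm["M_smooth"], expected, atol=1e-12)

    def test_bounded_by_window_extremes(self, rng):
        m = rng.normal(size=100)
        arr = make_array(m)
        sm = smooth_track(_ma(arr), _grid(arr))
        assert (sm["M_smooth"] >= m.min() - 1e-12).all()
        assert (sm["M_smooth"] <= m.max() + 1e-12).all()

    def test_empty_track(self):
        out = smooth_track(
            pd.DataFrame({"M": [], "A": []}),
            pd.DataFrame(columns=["probe_id", "chrom", "start", "end", "promoter_id"]),
        )
        assert len(out) == 0


class TestScoreProbes:
    def test_mean_probe_scores_half(self):
        sm = pd.DataFrame({"M_smooth": [-1.0, 0.0, 1.0]})
        st = score_probes(sm)
        assert st["z"].iloc[1] == pytest.approx(0.0)
        assert st["p_pos"].iloc[1] == pytest.approx(0.5)

    def test_tail_probability_matches_erf(self):
        sm = pd.DataFrame({"M_smooth": np.arange(11.0)})  # mean 5, sd sqrt(10)
        st = score_probes(sm)
        for z, p in zip(st["z"], st["p_pos"]):
            assert p == pytest.approx(0.5 * math.erfc(z / math.sqrt(2)), rel=1e-12)
        # the z=2 tail of the standard normal
        assert 0.5 * math.erfc(2 / math.sqrt(2)) == pytest.approx(0.0227501, abs=1e-7)

    def test_tails_sum_to_one(self, rng):
        st = score_probes(pd.DataFrame({"M_smooth": rng.normal(size=50)}))
        np.testing.assert_allclose(st["p_pos"] + st["p_neg"], 1.0, atol=1e-12)

    def test_degenerate_track_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            score_probes(pd.DataFrame({"M_smooth": [1.0, 1.0, 1.0]}))

    def test_robust_scoring_resists_outliers(self, rng):
        m = np.r_[rng.normal(0, 1, 200), [50.0] * 5]  # gross outliers
        st = score_probes(pd.DataFrame({"M_smooth": m}), robust=True)
        # MAD-based scale ignores the outliers, so their z stays extreme
        assert st["z"].iloc[-1] > 20
        st_moment = score_probes(pd.DataFrame({"M_smooth": m}))
        assert st_moment["z"].iloc[-1] < st["z"].iloc[-1]


def _stats_from_p(p_pos):
    p = np.asarray(p_pos, dtype=float)
    from scipy.stats import norm

    z = norm.isf(p)
    return pd.DataFrame({"z": z, "p_pos": p, "p_neg": 1 - p})


class TestCallRegions:
    def test_three_consecutive_significant_probes(self):
        arr = make_array(np.zeros(3))
        regs = call_regions(_stats_from_p([1e-4] * 3), _grid(arr))
        assert len(regs) == 1
        assert len(regs[0].probe_ids) == 3
        assert regs[0].interval == GenomicInterval("chr1", 0, 250)

    def test_short_run_rejected_longer_kept(self):
        arr = make_array(np.zeros(6))
        regs = call_regions(
            _stats_from_p([1e-4, 1e-4, 0.5, 1e-4, 1e-4, 1e-4]), _grid(arr)
        )
        assert len(regs) == 1
        assert regs[0].probe_ids == list(arr.probes["probe_id"].iloc[3:6])

    def test_no_significant_probes_empty(self):
        arr = make_array(np.zeros(5))
        assert call_regions(_stats_from_p([0.5] * 5), _grid(arr)) == []

    def test_region_p_is_min_and_peak_z_extreme(self):
        arr = make_array(np.zeros(4))
        regs = call_regions(_stats_from_p([1e-4, 1e-9, 1e-5, 1e-4]), _grid(arr))
        assert regs[0].region_p == pytest.approx(1e-9)
        from scipy.stats import norm

        assert regs[0].peak_z == pytest.approx(norm.isf(1e-9))

    def test_matches_bruteforce_run_enumeration(self, rng):
        for trial in range(20):
            n = int(rng.integers(5, 200))
            p = 10.0 ** rng.uniform(-6, 0, n)
            pid = np.sort(rng.integers(0, 4, n)).astype(str)
            arr = make_array(np.zeros(n))
            df = arr.probes.copy()
            df["promoter_id"] = pid
            from tilescan import TilingArray

            grid = _grid(TilingArray("t", df))
            regs = call_regions(_stats_from_p(p), grid, DetectionParams())
            runs = bruteforce_runs(p < 1e-3, grid["promoter_id"].to_numpy(), 3)
            got = [
                (grid["probe_id"].iloc[i], grid["probe_id"].iloc[j - 1])
                for i, j in runs
            ]
            assert [(r.probe_ids[0], r.probe_ids[-1]) for r in regs] == got

    def test_sign_symmetry(self, rng):
        n = 80
        m = rng.normal(size=n)
        arr = make_array(m)
        neg = make_array(-m)
        grid = _grid(arr)
        st_pos = score_probes(smooth_track(_ma(arr), grid))
        st_neg = score_probes(smooth_track(_ma(neg), grid))
        pos = call_regions(st_pos, grid, sign=1)
        swapped = call_regions(st_neg, grid, sign=-1)
        assert [(r.probe_ids, r.interval) for r in pos] == [
            (r.probe_ids, r.interval) for r in swapped
        ]


def _region(p_start, p_end, sign=1, pid="P0", p=1e-9, z=6.0):
    return EnrichedRegion(
        GenomicInterval("chr1", p_start, p_end), sign, pid, [], p, z if sign > 0 else -z
    )


class TestCombineReplicates:
    def _tracks_with_peak(self, n=100, peak=slice(10, 13), height=10.0, n_rep=3):
        # a sharp 3-probe peak: z of peak probes ~ 5.7 -> p well below 1e-3
        tracks = []
        for r in range(n_rep):
            m = np.zeros(n)
            m[peak] = height
            m += np.linspace(-0.01, 0.01, n)  # break sd degeneracy
            tracks.append(pd.DataFrame({"M_smooth": m}))
        return tracks

    def test_full_support_kept(self):
        arr = make_array(np.zeros(100))
        grid = _grid(arr)
        tracks = self._tracks_with_peak()
        regs = [call_regions(score_probes(t), grid) for t in tracks]
        cons = combine_replicates(regs, tracks, grid)
        assert len(cons) == 1 and cons[0].support == [True, True, True]

    def test_two_of_three_dropped(self):
        arr = make_array(np.zeros(100))
        grid = _grid(arr)
        tracks = self._tracks_with_peak()
        regs = [call_regions(score_probes(t), grid) for t in tracks]
        regs[2] = []  # third replicate shows nothing
        assert combine_replicates(regs, tracks, grid) == []

    def test_disjoint_single_replicate_regions_no_consensus(self):
        arr = make_array(np.zeros(100))
        grid = _grid(arr)
        tracks = self._tracks_with_peak()
        # replicate regions exist but none overlaps the averaged-track call
        fake = [[_region(2500, 2800)], [_region(0, 200)], [_region(2500, 2800)]]
        cons = combine_replicates(fake, tracks, grid)
        assert cons == []

    def test_grid_mismatch_rejected(self):
        arr = make_array(np.zeros(10))
        tracks = [pd.DataFrame({"M_smooth": np.zeros(5)})] * 2
        with pytest.raises(ValueError, match="grid"):
            combine_replicates([[], []], tracks, _grid(arr))


def _cons(p_start, p_end, sign=1, pid="P0", p=1e-9, z=6.0, questionable=False):
    return ConsensusRegion(
        GenomicInterval("chr1", p_start, p_end), sign, pid, [], p,
        z if sign > 0 else -z, [True] * 3, questionable,
    )


class TestFlagAndSelect:
    def test_masked_by_larger_adjacent_negative(self):
        pos = _cons(1000, 1400, z=4.0)
        neg = _cons(1600, 2000, sign=-1, z=6.0)
        out = flag_questionable([pos], [neg])
        assert out[0].questionable and out[0].masking_region is neg

    def test_unflagged_without_negative(self):
        out = flag_questionable([_cons(0, 400, z=4.0)], [])
        assert not out[0].questionable

    def test_smaller_negative_does_not_mask(self):
        out = flag_questionable(
            [_cons(1000, 1400, z=4.0)], [_cons(1600, 2000, sign=-1, z=3.0)]
        )
        assert not out[0].questionable

    def test_distant_negative_does_not_mask(self):
        out = flag_questionable(
            [_cons(0, 400, z=4.0)], [_cons(5000, 5400, sign=-1, z=8.0)]
        )
        assert not out[0].questionable

    def test_other_promoter_negative_ignored(self):
        out = flag_questionable(
            [_cons(1000, 1400, z=4.0)],
            [_cons(1600, 2000, sign=-1, z=8.0, pid="P9")],
        )
        assert not out[0].questionable

    def test_threshold_partition(self):
        regions = [
            _cons(0, 300, p=1e-8),
            _cons(400, 700, p=1e-6),
            _cons(800, 1100, p=1e-4),
            _cons(1200, 1500, p=1e-9, questionable=True),
        ]
        targets, relaxed = select_targets(regions)
        assert [r.interval.start for r in targets] == [0]
        assert [r.interval.start for r in relaxed] == [0, 400]
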