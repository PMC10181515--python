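import numpy as np
import pytest

from apneascreen.rqa import (
    RQA_FEATURE_NAMES,
    estimate_delay,
    fan_recurrence,
    line_histograms,
    rqa_features,
    rqa_measures,
    takens_embed,
)

from conftest import modulated_frame
from oracles import fan_matrix_naive, line_histograms_naive, rqa_measures_naive


class TestTakensEmbed:
    def test_direct_substitution(self):
        traj = takens_embed(np.array([1.0, 2, 3, 4, 5]), m=2, tau=1)
        np.testing.assert_array_equal(
            traj.states, [[1, 2], [2, 3], [3, 4], [4, 5]]
        )

    def test_m1_is_identity(self):
        u = np.arange(10.0)
        np.testing.assert_array_equal(takens_embed(u, 1, 3).states.ravel(), u)

    def test_state_count(self):
        u = np.random.default_rng(0).standard_normal(300)
        assert takens_embed(u, m=8, tau=5).states.shape == (265, 8)

    def test_too_short_fails_with_required_length(self):
        with pytest.raises(ValueError, match="at least 37"):
            takens_embed(np.arange(30.0), m=8, tau=5)


class TestFanRecurrence:
    def test_exact_column_sums(self):
        u = np.random.default_rng(1).standard_normal(100)
        rm = fan_recurrence(takens_embed(u, 1, 1), fraction=0.05, theiler=1)
        np.testing.assert_array_equal(rm.entries.sum(axis=0), 4)  # floor(0.05*99)

    def test_column_density_near_five_percent(self):
        u = np.random.default_rng(2).standard_normal(400)
        traj = takens_embed(u, 8, 5)
        rm = fan_recurrence(traj, 0.05, 1)
        n_elig = rm.n - 1
        density = rm.entries.sum(axis=0) / n_elig
        assert np.allclose(density, np.floor(0.05 * n_elig) / n_elig)
        assert abs(density[0] - 0.05) < 1 / n_elig

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # duplicated points force distance ties at the cutoff
        u = rng.integers(0, 4, size=60).astype(float)
        traj = takens_embed(u, 2, 1)
        rm = fan_recurrence(traj, 0.1, 1)
        np.testing.assert_array_equal(
            rm.entries, fan_matrix_naive(traj.states, 0.1, 1)
        )

    def test_zero_neighbors_fails(self):
        traj = takens_embed(np.arange(10.0), 1, 1)
        with pytest.raises(ValueError, match="zero"):
            fan_recurrence(traj, 0.01, 1)

    def test_constant_series_is_deterministic(self):
        traj = takens_embed(np.zeros(50), 2, 1)
        rm = fan_recurrence(traj, 0.1, 1)
        k = int(np.floor(0.1 * (rm.n - 1)))
        np.testing.assert_array_equal(rm.entries.sum(axis=0), k)
        # all distances tie -> lowest eligible row indices win
        assert rm.entries[0, 5] == 1 and rm.entries[rm.n - 1, 5] == 0


class TestLineHistograms:
    def test_all_ones_five_by_five(self):
        diag, vert, white = line_histograms(np.ones((5, 5), int))
        assert sorted(diag) == [1, 1, 2, 2, 3, 3, 4, 4]
        # LOI zeroed: column i splits into runs of length i and 4-i
        assert sorted(vert) == [1, 1, 2, 2, 3, 3, 4, 4]
        assert sorted(white) == [1, 1, 1, 1, 1]

    def test_identity_matrix_is_empty(self):
        diag, vert, white = line_histograms(np.eye(6, dtype=int))
        assert diag == [] and vert == []
        assert sorted(white) == [6] * 6

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_double_loop(self, seed):
        r = (np.random.default_rng(seed).random((10, 10)) < 0.4).astype(int)
        ours = line_histograms(r)
        naive = line_histograms_naive(r)
        for a, b in zip(ours, naive):
            assert sorted(a) == sorted(b)


class TestRqaMeasures:
    def test_all_ones_matrix(self):
        n = 6
        m = rqa_measures(np.ones((n, n), int)).values
        assert m["REC"] == pytest.approx(1.0)
        assert m["Clust"] == pytest.approx(1.0)
        assert m["Trans"] == pytest.approx(1.0)
        # the two corner diagonals have length 1, everything else >= 2
        assert m["DET"] == pytest.approx((n * n - n - 2) / (n * n - n))
        assert m["Lmax"] == n - 1

    def test_isolated_points_have_no_determinism(self):
        """A dot grid (ones on even rows x even columns) has only length-1
        runs on every diagonal and column, so DET = LAM = 0 at lmin=2."""
        n = 8
        i, j = np.indices((n, n))
        r = ((i % 2 == 0) & (j % 2 == 0)).astype(int)
        m = rqa_measures(r).values
        assert m["DET"] == 0.0
        assert m["LAM"] == 0.0

    def test_single_line_length_has_zero_entropy(self):
        r = np.zeros((8, 8), int)
        r[2, 5] = r[3, 6] = r[4, 7] = 1  # one diagonal of length 3
        m = rqa_measures(r).values
        assert m["ENTR"] == 0.0
        assert m["L"] == 3.0 and m["Lmax"] == 3

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_reference(self, seed):
        r = (np.random.default_rng(seed).random((15, 15)) < 0.3).astype(int)
        ours = rqa_measures(r).values
        ref = rqa_measures_naive(r)
        for name in RQA_FEATURE_NAMES:
            assert ours[name] == pytest.approx(ref[name], abs=1e-12), name

    def test_measures_bounded(self):
        for seed in range(5):
            r = (np.random.default_rng(seed).random((20, 20)) < 0.2).astype(int)
            m = rqa_measures(r).values
            for k in ("REC", "DET", "LAM", "Clust", "Trans"):
                assert 0.0 <= m[k] <= 1.0
            assert m["ENTR"] >= 0.0 and m["Lmax"] <= 19


class TestRqaFeatures:
    def test_output_is_17_named_values(self, cvhr_frame):
        feats = rqa_features(cvhr_frame, m=8, tau=5)
        assert list(feats) == RQA_FEATURE_NAMES
        assert all(np.isfinite(v) for v in feats.values())

    def test_periodic_beats_shuffled_on_determinism(self):
        """Periodic RR modulation shows more diagonal structure than its
        shuffled surrogate in nearly every paired trial."""
        wins = 0
        trials = 20
        for seed in range(trials):
            frame = modulated_frame(0.02, depth=0.15, noise=0.005, seed=seed)
            det_p = rqa_features(frame, m=8, tau=5)["DET"]
            rng = np.random.default_rng(seed + 1000)
            shuffled = frame.rr_segment.intervals.copy()
            rng.shuffle(shuffled)
            frame.rr_segment.intervals = shuffled
            det_s = rqa_features(frame, m=8, tau=5)["DET"]
            wins += det_p > det_s
        assert wins >= 0.95 * trials

    def test_constant_segment_still_finite(self):
        frame = modulated_frame(0.02)
        frame.rr_segment.intervals = np.full(200, 0.8)
        feats = rqa_features(frame, m=8, tau=5)
        assert all(np.isfinite(v) for v in feats.values())

    def test_too_short_segment_fails(self, cvhr_frame):
        frame = modulated_frame(0.02)
        frame.rr_segment.intervals = frame.rr_segment.intervals[:20]
        with pytest.raises(ValueError, match="too few"):
            rqa_features(frame, m=8, tau=5)


def test_delay_estimate_on_sinusoid():
    """Quarter period of a sine is the first autocorrelation zero crossing."""
    u = np.sin(2 * np.pi * np.arange(400) / 40)
    assert estimate_delay(u) in (10, 11)
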