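"""2PL curve fitting, inversion, recommendation, runtime extrapolation."""

import numpy as np
import pytest

from foreststab import (
    TwoPLStabilityModel,
    estimate_numtrees,
    estimate_runtime,
    fit_2pl,
    predict_stability,
    recommend_num_trees,
)
from foreststab.exceptions import InputError
from foreststab.model import SCAN_STEP, SEARCH_MAX, SEARCH_MIN

GRID = np.array([250.0, 500.0, 750.0, 1000.0, 2000.0])


def two_pl(t, th1, th2):
    return 1.0 / (1.0 + (th1 / np.asarray(t, dtype=float)) ** th2)


def scan_oracle(th1, th2, rec_thresh, round_to=1000):
    """Brute-force forward-difference scan over the full 10-step grid."""
    t = SEARCH_MIN
    while t < SEARCH_MAX:
        gain = two_pl(t + SCAN_STEP, th1, th2) - two_pl(t, th1, th2)
        if gain <= rec_thresh:
            return int(np.ceil(t / round_to) * round_to)
        t += SCAN_STEP
    return SEARCH_MAX


class TestFit:
    def test_noiseless_recovery_to_1e6_relative(self):
        fit = fit_2pl(GRID, two_pl(GRID, 300.0, 1.5))
        assert fit.theta1_ == pytest.approx(300.0, rel=1e-6)
        assert fit.theta2_ == pytest.approx(1.5, rel=1e-6)
        assert np.max(np.abs(fit.residuals_)) < 1e-10

    def test_noisy_recovery_within_five_percent(self, rng):
        s = two_pl(GRID, 300.0, 1.5) + rng.uniform(-1e-3, 1e-3, size=GRID.size)
        fit = fit_2pl(GRID, s)
        assert fit.theta1_ == pytest.approx(300.0, rel=0.05)
        assert fit.theta2_ == pytest.approx(1.5, rel=0.05)

    def test_flat_points_flagged_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_2pl(GRID, np.full(5, 0.999))
        assert fit.degenerate_

    def test_nonpositive_stabilities_excluded_with_warning(self):
        s = two_pl(GRID, 300.0, 1.5)
        s[0] = -0.02
        with pytest.warns(UserWarning, match="non-positive"):
            fit = fit_2pl(GRID, s)
        assert fit.n_points_ == 4
        assert fit.theta1_ == pytest.approx(300.0, rel=1e-5)

    def test_fewer_than_three_usable_points_rejected(self):
        with pytest.raises(InputError):
            fit_2pl([100, 200], [0.4, 0.6])

    def test_nan_rows_are_dropped(self):
        s = two_pl(GRID, 300.0, 1.5)
        s[2] = np.nan
        fit = fit_2pl(GRID, s)
        assert fit.n_points_ == 4
        assert fit.theta1_ == pytest.approx(300.0, rel=1e-5)


class TestPredict:
    def test_stability_at_theta1_is_exactly_half(self):
        for th1, th2 in [(500.0, 2.0), (300.0, 1.5), (7.0, 0.3), (12345.6, 4.2)]:
            m = TwoPLStabilityModel.from_parameters(th1, th2)
            assert m.estimate_stability(th1) == pytest.approx(0.5, abs=1e-15)

    def test_hand_evaluation(self):
        m = TwoPLStabilityModel.from_parameters(500.0, 1.0)
        assert m.estimate_stability(1000) == pytest.approx(2 / 3)

    def test_asymptote_reaches_one(self):
        m = TwoPLStabilityModel.from_parameters(500.0, 2.0)
        assert m.estimate_stability(1e9) >= 1 - 1e-6

    def test_strictly_increasing_and_in_unit_interval(self):
        m = TwoPLStabilityModel.from_parameters(777.0, 1.3)
        t = np.geomspace(1, 1e8, 200)
        s = m.predict(t)
        assert np.all(np.diff(s) > 0)
        assert np.all((s > 0) & (s < 1))

    def test_nonpositive_tree_count_rejected(self):
        m = TwoPLStabilityModel.from_parameters(500.0, 2.0)
        with pytest.raises(InputError):
            m.predict(0)


class TestInverse:
    def test_target_half_returns_theta1(self):
        m = TwoPLStabilityModel.from_parameters(500.0, 2.0)
        assert m.estimate_numtrees(0.5) == 500

    def test_hand_inversion(self):
        m = TwoPLStabilityModel.from_parameters(500.0, 1.0)
        assert m.estimate_numtrees(2 / 3) == 1000

    @pytest.mark.parametrize("target", [0.5, 0.9, 0.99, 0.999])
    def test_round_trip_reaches_target(self, target):
        m = TwoPLStabilityModel.from_parameters(431.0, 1.7)
        t = m.estimate_numtrees(target)
        assert m.estimate_stability(t) >= target
        if t > 1:  # one tree less falls short (ceiling is tight)
            assert m.estimate_stability(t - 1) < target or t - 1 < 1

    def test_out_of_range_target_rejected(self):
        m = TwoPLStabilityModel.from_parameters(500.0, 2.0)
        for bad in (0.0, 1.0, -0.5, 1.5):
            with pytest.raises(InputError):
                m.estimate_numtrees(bad)


class TestRecommendation:
    def test_equals_scan_oracle_on_random_parameters(self, rng):
        for _ in range(20):
            th1 = float(np.exp(rng.uniform(np.log(50), np.log(5000))))
            th2 = float(rng.uniform(0.5, 3.0))
            m = TwoPLStabilityModel.from_parameters(th1, th2)
            rec = m.recommend()
            assert rec.num_trees == scan_oracle(th1, th2, 1e-6)

    def test_monotone_non_increasing_in_threshold(self):
        m = TwoPLStabilityModel.from_parameters(300.0, 1.5)
        recs = [m.recommend(rec_thresh=th).num_trees for th in (1e-7, 1e-6, 1e-5, 1e-4)]
        assert recs == sorted(recs, reverse=True)

    def test_huge_threshold_hits_scan_floor(self):
        m = TwoPLStabilityModel.from_parameters(300.0, 1.5)
        rec = m.recommend(rec_thresh=1.0)
        assert rec.num_trees == 1000  # t=10 qualifies, rounded up to 1,000

    def test_saturation_returns_interval_end_with_warning(self):
        # shallow slope, enormous theta1: the per-ten-trees gain stays above
        # the threshold across the whole search interval
        m = TwoPLStabilityModel.from_parameters(1e12, 0.3)
        with pytest.warns(UserWarning, match="saturates"):
            rec = m.recommend(rec_thresh=1e-12)
        assert rec.num_trees == SEARCH_MAX
        assert rec.saturated

    def test_functional_facade_matches_method(self):
        m = TwoPLStabilityModel.from_parameters(450.0, 1.2)
        assert recommend_num_trees(m, 1e-6).num_trees == m.recommend(1e-6).num_trees
        assert predict_stability(m, 450.0) == pytest.approx(0.5)
        assert estimate_numtrees(m, 0.9) == m.estimate_numtrees(0.9)


class TestRuntime:
    def test_exact_linear_extrapolation(self):
        t = [250, 500, 1000]
        r = [1 + 0.002 * x for x in t]
        assert estimate_runtime(t, r, 10_000) == pytest.approx(21.0)

    def test_doubling_trees_scales_linearly(self):
        t = [100, 200, 400]
        r = [0.5 + 0.01 * x for x in t]
        a = estimate_runtime(t, r, 1000)
        b = estimate_runtime(t, r, 2000)
        assert b - 0.5 == pytest.approx(2 * (a - 0.5))

    def test_single_point_rejected(self):
        with pytest.raises(InputError):
            estimate_runtime([500], [1.0], 1000)

    def test_negative_slope_clamped(self):
        out = estimate_runtime([100, 200, 300], [3.0, 2.0, 1.0], 10_000)
        assert out == pytest.approx(2.0)  # falls back to the mean
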