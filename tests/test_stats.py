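import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from xylemscale.stats import (
    kendall_tau,
    loglog_fit,
    piecewise_fit,
    residual_diagnostics,
    theil_sen,
)


def brute_force_theil_sen(x, y):
    slopes = [
        (y[j] - y[i]) / (x[j] - x[i])
        for i, j in itertools.combinations(range(len(x)), 2)
        if x[j] != x[i]
    ]
    slope = float(np.median(slopes))
    return slope, float(np.median(np.asarray(y) - slope * np.asarray(x)))


def brute_force_tau_b(x, y):
    con = dis = tx = ty = 0
    for i, j in itertools.combinations(range(len(x)), 2):
        dx, dy = x[j] - x[i], y[j] - y[i]
        if dx == 0 and dy == 0:
            continue
        if dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            con += 1
        else:
            dis += 1
    n0 = len(x) * (len(x) - 1) / 2
    return (con - dis) / np.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))


def _tie_term(v):
    _, counts = np.unique(v, return_counts=True)
    return sum(c * (c - 1) / 2 for c in counts)


class TestTheilSen:
    def test_exact_line(self):
        fit = theil_sen([1, 2, 3], [3, 5, 7])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)

    def test_pairwise_median_hand_case(self):
        fit = theil_sen([0, 1, 2, 3], [0, 1, 2, 10])
        assert fit.slope == pytest.approx((1 + 10 / 3) / 2)

    def test_matches_brute_force_on_random_points(self, rng):
        x = rng.uniform(0, 10, 50)
        y = 2.5 * x + rng.normal(0, 1, 50)
        fit = theil_sen(x, y)
        slope, intercept = brute_force_theil_sen(x, y)
        assert fit.slope == pytest.approx(slope, rel=1e-12)
        assert fit.intercept == pytest.approx(intercept, rel=1e-9)
        assert fit.ci_low <= fit.slope <= fit.ci_high

    def test_agrees_with_scipy_slope(self, rng):
        x = rng.uniform(0, 5, 40)
        y = -1.3 * x + rng.normal(0, 0.5, 40)
        fit = theil_sen(x, y)
        ref = sps.theilslopes(y, x)
        assert fit.slope == pytest.approx(ref.slope, rel=1e-9)

    @given(
        shift=st.floats(-100, 100),
        scale=st.floats(0.01, 100),
    )
    def test_shift_invariance_and_scale_equivariance(self, shift, scale):
        x = np.array([0.0, 1.0, 2.0, 3.5, 5.0])
        y = np.array([1.0, 2.2, 2.9, 4.6, 6.0])
        base = theil_sen(x, y)
        shifted = theil_sen(x, y + shift)
        scaled = theil_sen(x, y * scale)
        assert shifted.slope == pytest.approx(base.slope, rel=1e-12)
        assert scaled.slope == pytest.approx(base.slope * scale, rel=1e-12)

    def test_all_x_equal_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            theil_sen([2, 2, 2], [1, 2, 3])


class TestKendallTau:
    def test_monotone_limits(self):
        x = np.arange(8.0)
        tau_up, _ = kendall_tau(x, x**3)
        tau_dn, _ = kendall_tau(x, -x)
        assert tau_up == pytest.approx(1.0, abs=1e-12)
        assert tau_dn == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_pair_count_n5(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, 5).astype(float)
        y = rng.integers(0, 5, 5).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            pytest.skip("degenerate draw")
        tau, _ = kendall_tau(x, y)
        assert tau == pytest.approx(brute_force_tau_b(x, y), rel=1e-12)

    def test_tau_bounded(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        tau, p = kendall_tau(x, y)
        assert -1.0 <= tau <= 1.0
        assert 0.0 <= p <= 1.0

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            kendall_tau([1, 1, 1], [1, 2, 3])


class TestLogLogFit:
    def test_power_law_exponent(self):
        x = np.linspace(1, 10, 20)
        assert loglog_fit(x, x**2).slope == pytest.approx(2.0, abs=1e-12)
        assert loglog_fit(x, 7.3 * x).slope == pytest.approx(1.0, abs=1e-12)

    def test_simulation_envelope_slope_recovery(self):
        """y = 3*x^0.946 with 1% noise, n=58: slope lands in [0.91, 0.98]."""
        slopes = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.uniform(1.0, 30.0, 58)
            y = 3.0 * x**0.946 * rng.lognormal(0, 0.01, 58)
            slopes.append(loglog_fit(x, y).slope)
        assert np.min(slopes) >= 0.91
        assert np.max(slopes) <= 0.98

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            loglog_fit([1.0, -2.0, 3.0], [1.0, 2.0, 3.0])


class TestPiecewiseFit:
    def test_noise_free_hinge_recovered_exactly(self):
        x = np.arange(0.0, 11.0)
        y = np.where(x <= 5, x, 5 + 3 * (x - 5))
        fit = piecewise_fit(x, y)
        assert fit.breakpoint == pytest.approx(5.0, abs=1e-6)
        assert fit.left_slope == pytest.approx(1.0, abs=1e-9)
        assert fit.right_slope == pytest.approx(3.0, abs=1e-9)
        assert fit.sse == pytest.approx(0.0, abs=1e-15)

    def test_pure_line_degenerates_to_equal_slopes(self):
        x = np.arange(0.0, 12.0)
        fit = piecewise_fit(x, 2 * x + 1)
        assert fit.left_slope == pytest.approx(2.0, abs=1e-9)
        assert fit.right_slope == pytest.approx(2.0, abs=1e-9)

    def test_noisy_breakpoint_recovery(self):
        """sigma=0.1 noise around a hinge at 10: recovered within +-1 in >=95%."""
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            x = np.sort(rng.uniform(0, 20, 100))
            y = np.where(x <= 10, 0.5 * x, 5 + 2.0 * (x - 10)) + rng.normal(0, 0.1, 100)
            fit = piecewise_fit(x, y)
            hits += abs(fit.breakpoint - 10.0) <= 1.0
        assert hits / n_rep >= 0.95

    def test_insufficient_points_rejected(self):
        with pytest.raises(ValueError):
            piecewise_fit([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])


class TestResidualDiagnostics:
    def test_durbin_watson_hand_value(self):
        diag = residual_diagnostics(
            np.arange(5.0), [1.0, -1.0, 1.0, -1.0, 1.0], n_sims=200, seed=1
        )
        assert diag.durbin_watson == pytest.approx(16 / 5)

    def test_durbin_watson_bounds(self, rng):
        e = rng.normal(size=50)
        diag = residual_diagnostics(np.arange(50.0), e, n_sims=200, seed=1)
        assert 0.0 <= diag.durbin_watson <= 4.0

    def test_constant_residuals_give_zero_breusch_pagan(self):
        diag = residual_diagnostics(np.arange(6.0), np.full(6, 0.7), n_sims=100, seed=1)
        assert diag.breusch_pagan_stat == 0.0

    def test_heteroscedastic_residuals_detected(self, rng):
        x = np.linspace(0, 1, 200)
        e = rng.normal(0, 0.1 + 2 * x)
        diag = residual_diagnostics(x, e, n_sims=200, seed=1)
        assert diag.breusch_pagan_p < 0.01

    def test_lilliefors_null_p_values_uniform(self):
        """On normal residuals the Monte-Carlo p value is uniform over seeds."""
        pvals = []
        for seed in range(100):
            rng = np.random.default_rng(10_000 + seed)
            e = rng.standard_normal(100)
            diag = residual_diagnostics(np.arange(100.0), e, n_sims=1000, seed=seed)
            pvals.append(diag.lilliefors_p)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_lilliefors_rejects_heavy_tails(self):
        rng = np.random.default_rng(5)
        e = rng.standard_cauchy(200)
        diag = residual_diagnostics(np.arange(200.0), e, n_sims=1000, seed=3)
        assert diag.lilliefors_p < 0.01

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            residual_diagnostics([1, 2, 3], [0.1, -0.1, 0.2])
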