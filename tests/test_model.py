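"""Unit and property tests for the segmented design, densities and likelihood."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import itscount as ic
from itscount.errors import EvaluationError, ExplosionError, InvalidDesignError
from itscount.model import conditional_means

from conftest import bruteforce_loglik, random_small_series


class TestBuildDesign:
    def test_equal_split_log_design(self):
        d = ic.build_design(18, "log", "auto")
        assert d.intervention_index == 10
        assert d.n_pre == 9 and d.n_post == 9
        assert d.T[0] == 0.0
        assert d.D[9] == 0.0  # beta2 alone carries the level change at t0

    def test_identity_design_small(self):
        d = ic.build_design(4, "identity", "auto")
        assert np.allclose(d.T, [1, 2, 3, 4])
        assert np.allclose(d.X, [0, 0, 1, 1])
        assert np.allclose(d.D, [0, 0, 0, 1])

    def test_log_elapsed_time_is_log_ratio(self):
        d = ic.build_design(96, "log", "auto")
        assert d.D[95] == pytest.approx(math.log(96 / 49), abs=1e-12)

    def test_raw_anchor_subtracts_raw_index(self):
        d = ic.build_design(8, "log", "auto", anchor="raw")
        assert d.D[7] == pytest.approx((math.log(8) - 5) * 1.0)

    @pytest.mark.parametrize("bad_n", [3, 7, 17, 2, 0, -4])
    def test_rejects_odd_or_small_n(self, bad_n):
        with pytest.raises(InvalidDesignError):
            ic.build_design(bad_n)

    @pytest.mark.parametrize("bad_idx", [0, 1, 19, 100])
    def test_rejects_out_of_range_intervention(self, bad_idx):
        with pytest.raises(InvalidDesignError):
            ic.build_design(18, "log", bad_idx)

    @given(
        n=st.integers(2, 100).map(lambda k: 2 * k),
        transform=st.sampled_from(["log", "identity"]),
    )
    @settings(derandomize=True, max_examples=40)
    def test_invariants_hold_on_any_valid_design(self, n, transform):
        d = ic.build_design(n, transform, "auto")
        # monotone step indicator with an exact half/half split
        assert np.all(np.diff(d.X) >= 0)
        assert int(d.X.sum()) == n // 2
        # D vanishes pre-intervention and is nonnegative (monotone transform)
        assert np.all(d.D[d.X == 0] == 0)
        assert np.all(d.D >= 0)


class TestLinearPredictor:
    def test_zero_coefficients(self):
        d = ic.build_design(18)
        reg = ic.RegressionParams(0.0)
        assert ic.linear_predictor(d, reg, 5) == 0.0

    def test_pre_and_first_post_values(self):
        d = ic.build_design(18)
        reg = ic.RegressionParams(2.0, 0.1, -0.5, -0.05)
        assert ic.linear_predictor(d, reg, 3) == pytest.approx(2 + 0.1 * math.log(3))
        # first post point: level change applies, elapsed-time term is zero
        assert ic.linear_predictor(d, reg, 10) == pytest.approx(
            2 + 0.1 * math.log(10) - 0.5
        )

    def test_out_of_range_index(self):
        d = ic.build_design(18)
        with pytest.raises(IndexError):
            ic.linear_predictor(d, ic.RegressionParams(0.0), 19)


class TestConditionalMean:
    def test_no_feedback(self):
        assert ic.conditional_mean(1.5, 0.0, 7) == pytest.approx(math.exp(1.5))

    def test_zero_previous_count_kills_feedback(self):
        assert ic.conditional_mean(0.3, 0.9, 0) == pytest.approx(math.exp(0.3))

    def test_feedback_power_law(self):
        assert ic.conditional_mean(0.0, 0.5, 6) == pytest.approx(math.sqrt(7))

    def test_overflow_raises_explosion(self):
        with pytest.raises(ExplosionError):
            ic.conditional_mean(800.0, 0.0, 0)

    @given(gamma1=st.floats(-5, 5), eta=st.floats(-10, 10))
    @settings(derandomize=True, max_examples=50)
    def test_y_prev_zero_independent_of_gamma1(self, gamma1, eta):
        assert ic.conditional_mean(eta, gamma1, 0) == ic.conditional_mean(eta, 0.0, 0)


class TestDensities:
    def test_poisson_point_values(self):
        assert ic.log_pmf_poisson(0, 3.0) == pytest.approx(-3.0, abs=1e-12)
        assert ic.log_pmf_poisson(2, 3.0) == pytest.approx(
            -3 + 2 * math.log(3) - math.log(2), abs=1e-12
        )

    def test_negbin_zero_count_closed_form(self):
        # Gamma terms cancel at y=0: phi*ln(phi/(phi+mu))
        assert ic.log_pmf_negbin(0, 2.0, 2.0) == pytest.approx(-2 * math.log(2), abs=1e-12)

    @pytest.mark.parametrize("mu", [0.5, 2.0, 10.0])
    @pytest.mark.parametrize("phi", [0.5, 2.0, 10.0])
    def test_normalization_and_moments(self, mu, phi):
        y = np.arange(0, 2000)
        for logp, var_expected in [
            (ic.log_pmf_poisson(y, mu), mu),
            (ic.log_pmf_negbin(y, mu, phi), mu + mu * mu / phi),
        ]:
            p = np.exp(logp)
            assert p.sum() == pytest.approx(1.0, abs=1e-8)
            assert (y * p).sum() == pytest.approx(mu, abs=1e-6)
            var = (y * y * p).sum() - (y * p).sum() ** 2
            assert var == pytest.approx(var_expected, abs=1e-6)

    @pytest.mark.parametrize("mu", [1.0, 5.0, 20.0])
    def test_negbin_large_phi_limits_to_poisson(self, mu):
        # the exact gap at finite phi is (y(y-1)/2 - y*mu - mu^2/2)/phi
        # + O(1/phi^2), up to ~1.2e-5 on this grid at phi=1e8
        phi = 1e8
        y = np.arange(0, 51)
        diff = ic.log_pmf_negbin(y, mu, phi) - ic.log_pmf_poisson(y, mu)
        envelope = (y * (y - 1) / 2 - y * mu - mu * mu / 2) / phi
        # 5e-6 covers the float64 noise of differencing gammaln at 1e8
        assert np.max(np.abs(diff - envelope)) < 5e-6
        assert np.max(np.abs(diff)) < 1.2e-5

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ic.log_pmf_poisson(-1, 2.0)
        with pytest.raises(ValueError):
            ic.log_pmf_poisson(2, 0.0)
        with pytest.raises(ValueError):
            ic.log_pmf_negbin(2, 1.0, 0.0)


class TestConditionalVariance:
    def test_family_formulas(self):
        assert ic.conditional_variance(5.0, "poisson") == 5.0
        assert ic.conditional_variance(2.0, "negbin", 2.0) == 4.0
        assert ic.conditional_variance(2.0, "negbin", 1e12) == pytest.approx(2.0)

    def test_missing_phi_is_an_error(self):
        with pytest.raises(ValueError):
            ic.conditional_variance(2.0, "negbin")


class TestLogLikelihood:
    def test_no_feedback_reduces_to_independent_sum(self):
        d = ic.build_design(8)
        rng = np.random.default_rng(3)
        y = rng.integers(0, 12, size=8)
        series = ic.CountSeries(design=d, y=y)
        reg = ic.RegressionParams(1.2, 0.3, -0.4, 0.1)
        spec = ic.ModelSpec("poisson", reg, ic.DependenceParams(0.0))
        mu = np.exp(
            [ic.linear_predictor(d, reg, t) for t in range(1, 9)]
        )
        expected = float(np.sum(ic.log_pmf_poisson(y, mu)))
        assert ic.log_likelihood(series, spec) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_poisson_series(self):
        d = ic.build_design(4, "identity")
        series = ic.CountSeries(design=d, y=np.zeros(4, dtype=int))
        spec = ic.ModelSpec(
            "poisson", ic.RegressionParams(0.5, 0.0, 0.0, 0.0), ic.DependenceParams(0.7)
        )
        # y_prev = 0 throughout, so every mu_t = exp(0.5) and ll = -sum(mu)
        assert ic.log_likelihood(series, spec) == pytest.approx(-4 * math.exp(0.5))

    @pytest.mark.parametrize("family", ["poisson", "negbin"])
    def test_matches_bruteforce_recursion_on_random_series(self, family):
        rng = np.random.default_rng(42)
        for _ in range(100):
            series, beta, gamma1, phi = random_small_series(rng, family)
            spec = ic.ModelSpec(
                family,
                ic.RegressionParams(*beta),
                ic.DependenceParams(gamma1),
                phi=phi if family == "negbin" else None,
            )
            expected = bruteforce_loglik(
                series.y, series.y0, series.design, beta, gamma1, family, phi
            )
            assert ic.log_likelihood(series, spec) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.filterwarnings("ignore::itscount.NonstationaryWarning")
    def test_nonfinite_mean_carries_failing_index(self):
        d = ic.build_design(4, "identity")
        series = ic.CountSeries(design=d, y=np.array([1000000, 2, 3, 1]))
        spec = ic.ModelSpec(
            "poisson", ic.RegressionParams(100.0), ic.DependenceParams(60.0)
        )
        with pytest.raises(EvaluationError) as exc:
            ic.log_likelihood(series, spec)
        assert exc.value.index == 2  # first index driven by the huge y_1

    def test_realized_means_follow_observed_history(self):
        d = ic.build_design(6)
        series = ic.CountSeries(design=d, y=np.array([1, 0, 2, 3, 1, 4]), y0=2)
        spec = ic.ModelSpec(
            "poisson", ic.RegressionParams(0.5), ic.DependenceParams(0.3)
        )
        mu = conditional_means(series, spec)
        assert mu[0] == pytest.approx(math.exp(0.5 + 0.3 * math.log(3)))
        assert mu[3] == pytest.approx(math.exp(0.5 + 0.3 * math.log(3)))


class TestParameterTypes:
    def test_nonstationary_gamma1_warns_but_constructs(self):
        with pytest.warns(ic.NonstationaryWarning):
            dep = ic.DependenceParams(1.1)
        assert dep.gamma1 == 1.1

    def test_only_first_order_feedback_supported(self):
        with pytest.raises(ValueError):
            ic.DependenceParams(0.3, order_p=1)

    def test_negbin_spec_requires_positive_phi(self):
        reg = ic.RegressionParams(1.0)
        dep = ic.DependenceParams(0.0)
        with pytest.raises(ValueError):
            ic.ModelSpec("negbin", reg, dep)
        with pytest.raises(ValueError):
            ic.ModelSpec("negbin", reg, dep, phi=-1.0)

    def test_count_series_validation(self):
        d = ic.build_design(4)
        with pytest.raises(ValueError):
            ic.CountSeries(design=d, y=np.array([1, -1, 0, 2]))
        with pytest.raises(ValueError):
            ic.CountSeries(design=d, y=np.array([1, 2, 3]))
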