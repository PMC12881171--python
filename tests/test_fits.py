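import math

import numpy as np
import pytest

from agelaw.errors import DomainError, UnderdeterminedError
from agelaw.fits import (
    fit_linear,
    fracpoly_scan,
    gaussian_loglik,
    loo_r2,
    r2_difference,
    round_half_away,
    supralinearity_check,
)

AGES = np.arange(27.5, 58.0, 5.0)


class TestFitLinear:
    def test_noiseless_exponential_loglog_r2(self, exp_series):
        """The calibration benchmark: a true exponential fitted as a power
        law on the adult 5-year grid leaves R^2 = 0.989 (3 dp)."""
        fit = fit_linear(exp_series, "loglog")
        assert round_half_away(fit.r_squared, 3) == 0.989

    def test_noiseless_exponential_semilog_exact(self, exp_series, exp_truth):
        fit = fit_linear(exp_series, "semilog")
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(exp_truth.b, rel=1e-9)
        assert fit.coefficients[0] == pytest.approx(math.log(exp_truth.a_e), rel=1e-9)

    def test_noiseless_power_law_loglog_exact(self, pow_series, pow_truth):
        fit = fit_linear(pow_series, "loglog")
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(pow_truth.k - 1, rel=1e-9)

    def test_quadratic_never_fits_worse(self, noisy_fixture_suite):
        for series in noisy_fixture_suite:
            for scale in ("loglog", "semilog"):
                lin = fit_linear(series, scale, 1)
                quad = fit_linear(series, scale, 2)
                assert quad.rss <= lin.rss + 1e-12

    def test_loglik_identity(self, noisy_fixture_suite):
        for series in noisy_fixture_suite:
            fit = fit_linear(series, "loglog")
            assert fit.loglik == pytest.approx(gaussian_loglik(fit.rss, fit.n))

    def test_agrees_with_normal_equations(self):
        # brute-force oracle: explicit normal equations solved independently
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = rng.integers(5, 30)
            t = np.sort(rng.uniform(20, 80, n))
            y = rng.normal(0, 1, n) + 0.1 * t
            fit = fit_linear((t, np.exp(y)), "semilog")
            X = np.column_stack([np.ones(n), t])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert np.allclose(fit.coefficients, beta, rtol=1e-10, atol=1e-12)

    def test_domain_and_size_errors(self):
        with pytest.raises(DomainError):
            fit_linear((np.array([30.0, 40, 50, 60]), np.array([1.0, 0.0, 2, 3])), "loglog")
        with pytest.raises(UnderdeterminedError):
            fit_linear((np.array([30.0, 40]), np.array([1.0, 2.0])), "loglog")

    def test_r2_invariant_to_units_and_log_base(self, noisy_fixture_suite):
        # rescaling incidence (per 100k -> per million) is an affine shift
        # of ln I; R^2 must not move.  Base-10 display is the same shift.
        for series in noisy_fixture_suite[:2]:
            t = np.array(series.midpoints)
            i = np.array(series.incidences)
            for scale in ("loglog", "semilog"):
                r2a = fit_linear((t, i), scale).r_squared
                r2b = fit_linear((t, i * 10.0), scale).r_squared
                assert r2a == pytest.approx(r2b, rel=1e-12)


class TestR2Difference:
    def test_noiseless_exponential_value(self, exp_series):
        """Calibration: Delta R^2 = 1.000 - 0.989 = 0.011 at 3 dp."""
        assert round_half_away(r2_difference(exp_series), 3) == 0.011

    def test_noiseless_power_law_negative(self, pow_series):
        assert r2_difference(pow_series) < 0

    def test_constant_incidence_gives_zero(self):
        t = AGES
        i = np.full_like(t, 4.2)
        assert r2_difference((t, i)) == 0.0


class TestSupralinearity:
    def test_exponential_curvature_signatures(self, exp_series):
        assert supralinearity_check(exp_series, "loglog") == "supralinear"
        assert supralinearity_check(exp_series, "semilog") == "linear"

    def test_power_law_curvature_signatures(self, pow_series):
        assert supralinearity_check(pow_series, "loglog") == "linear"
        assert supralinearity_check(pow_series, "semilog") == "sublinear"


class TestFracpoly:
    def test_exact_representations(self, exp_series, pow_series):
        assert fracpoly_scan(exp_series).x_opt == 1.0
        assert fracpoly_scan(pow_series).x_opt == 0.0

    def test_profile_matches_linear_fits_at_grid_anchors(self, noisy_fixture_suite):
        for series in noisy_fixture_suite:
            fp = fracpoly_scan(series)
            ll = {x: v for x, v in zip(fp.x_grid, fp.loglik_per_x)}
            assert ll[0.0] == pytest.approx(fit_linear(series, "loglog").loglik, rel=1e-12)
            assert ll[1.0] == pytest.approx(fit_linear(series, "semilog").loglik, rel=1e-12)

    def test_needs_four_points(self):
        with pytest.raises(UnderdeterminedError):
            fracpoly_scan((np.array([30.0, 40, 50]), np.array([1.0, 2, 3])))


class TestLooR2:
    def test_collinear_data_scores_one(self):
        t = AGES
        i = np.exp(0.1 * t - 2)
        assert loo_r2((t, i), "semilog") == pytest.approx(1.0, abs=1e-10)

    def test_three_point_toy_matches_hand_computation(self):
        # points (t, I) = (1, e), (2, e^2), (3, e^4); semilog response
        # y = (1, 2, 4).  The three two-point subfits predict 0, 2.5, 3,
        # so PRESS = 1 + 0.25 + 1 = 2.25 and TSS = 42/9.
        t = np.array([1.0, 2.0, 3.0])
        i = np.exp([1.0, 2.0, 4.0])
        expected = 1.0 - 2.25 / (42.0 / 9.0)
        assert loo_r2((t, i), "semilog") == pytest.approx(expected, rel=1e-12)

    def test_never_beats_in_sample_r2_on_noisy_fixtures(self, noisy_fixture_suite):
        for series in noisy_fixture_suite:
            for scale in ("loglog", "semilog"):
                assert loo_r2(series, scale) <= fit_linear(series, scale).r_squared + 1e-12


class TestSlopeEstimator:
    def test_semilog_slope_unbiased_under_exponential_truth(self, exp_truth, bins7):
        """<= 1% relative bias over 200 Poisson replicates at >= 1e5 cases."""
        from agelaw.synth import simulate_registry

        slopes = []
        for rep in range(200):
            s = simulate_registry(exp_truth, bins7, 2e8, seed=5000 + rep)
            slopes.append(fit_linear(s, "semilog").slope)
        assert abs(np.mean(slopes) - exp_truth.b) / exp_truth.b < 0.01


def test_round_half_away():
    assert round_half_away(0.0115, 3) == 0.012
    assert round_half_away(-0.0115, 3) == -0.012
    assert round_half_away(0.98849, 3) == 0.988
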