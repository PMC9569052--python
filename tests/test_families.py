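"""Survival, density, hazard, sampling and transforms for the seven families.

Closed-form checks use hand-derived values; distributional checks use
scipy.stats as an independent oracle (the implementation evaluates its own
numpy/scipy.special formulas, never scipy.stats).
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import survelicit as sv
from survelicit.families import log_pdf, log_sf, natural_from_unconstrained

from conftest import TYPICAL_PARAMS

ALL_FAMILIES = list(sv.FAMILY_NAMES)


def scipy_dist(name, values):
    """Independent scipy.stats counterpart of each family."""
    if name == "exponential":
        (lam,) = values
        return stats.expon(scale=1.0 / lam)
    if name == "weibull":
        v, lam = values
        return stats.weibull_min(c=v, scale=lam ** (-1.0 / v))
    if name == "gompertz":
        a, b = values
        assert a > 0, "scipy gompertz covers positive shape only"
        return stats.gompertz(c=b / a, scale=1.0 / a)
    if name == "lognormal":
        mu, sig = values
        return stats.lognorm(s=sig, scale=np.exp(mu))
    if name == "loglogistic":
        beta, alpha = values
        return stats.fisk(c=beta, scale=alpha)
    if name == "gamma":
        k, r = values
        return stats.gamma(a=k, scale=1.0 / r)
    if name == "gengamma":
        r, lam, b = values
        return stats.gengamma(a=r, c=b, scale=1.0 / lam)
    raise ValueError(name)


class TestSurvival:
    def test_exponential_half_life(self):
        theta = sv.params("exponential", np.log(2.0))
        assert sv.survival(theta, 1.0) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("family", ALL_FAMILIES)
    def test_survival_at_zero_is_one(self, family):
        theta = sv.params(family, *TYPICAL_PARAMS[family])
        assert sv.survival(theta, 0.0) == 1.0

    def test_gompertz_small_shape_matches_exponential(self):
        theta = sv.params("gompertz", 1e-8, 0.3)
        assert sv.survival(theta, 2.0) == pytest.approx(np.exp(-0.6), abs=1e-6)

    @pytest.mark.parametrize("family", ALL_FAMILIES)
    def test_monotone_and_bounded_on_grid(self, family):
        theta = sv.params(family, *TYPICAL_PARAMS[family])
        t = np.linspace(0.0, 30.0, 200)
        s = sv.survival(theta, t)
        assert np.all((s >= 0.0) & (s <= 1.0))
        assert np.all(np.diff(s) <= 1e-12)

    def test_gompertz_negative_shape_plateaus_at_cure_fraction(self):
        theta = sv.params("gompertz", -0.5, 0.4)
        plateau = np.exp(0.4 / -0.5)
        assert sv.survival(theta, 1e6) == pytest.approx(plateau, abs=1e-12)
        from survelicit.families import cure_fraction

        assert cure_fraction(theta) == pytest.approx(plateau)

    @pytest.mark.parametrize("family", ALL_FAMILIES)
    def test_matches_scipy_oracle(self, family):
        values = TYPICAL_PARAMS[family]
        theta = sv.params(family, *values)
        t = np.array([0.05, 0.5, 1.0, 2.5, 8.0])
        dist = scipy_dist(family, values)
        np.testing.assert_allclose(
            np.log(sv.survival(theta, t)), dist.logsf(t), rtol=1e-10, atol=1e-12
        )
        np.testing.assert_allclose(
            sv.log_density(theta, t), dist.logpdf(t), rtol=1e-10, atol=1e-12
        )

    def test_invalid_parameter_named_in_error(self):
        with pytest.raises(sv.DomainError, match="rate"):
            sv.params("exponential", -1.0)
        with pytest.raises(sv.DomainError, match="sdlog"):
            sv.params("lognormal", 0.0, -0.5)

    def test_negative_time_rejected(self):
        theta = sv.params("exponential", 1.0)
        with pytest.raises(sv.DomainError):
            sv.survival(theta, -0.1)


class TestLogDensity:
    def test_exponential_closed_form(self):
        theta = sv.params("exponential", 0.5)
        assert sv.log_density(theta, 2.0) == pytest.approx(np.log(0.5) - 1.0, abs=1e-12)

    def test_weibull_shape_one_nests_exponential(self):
        lam = 0.7
        wei = sv.params("weibull", 1.0, lam)
        expo = sv.params("exponential", lam)
        for t in (0.2, 1.0, 4.0):
            assert sv.log_density(wei, t) == pytest.approx(
                sv.log_density(expo, t), abs=1e-12
            )

    def test_gengamma_nests_gamma_and_weibull(self):
        t = np.array([0.3, 1.0, 2.7])
        gg_gamma = sv.params("gengamma", 1.3, 0.5, 1.0)
        gamma = sv.params("gamma", 1.3, 0.5)
        np.testing.assert_allclose(
            sv.log_density(gg_gamma, t), sv.log_density(gamma, t), atol=1e-8
        )
        # gengamma(r=1, rate=lam, power=b) == weibull(shape=b, rate=lam**b)
        gg_wei = sv.params("gengamma", 1.0, 0.6, 1.8)
        wei = sv.params("weibull", 1.8, 0.6 ** 1.8)
        np.testing.assert_allclose(
            sv.log_density(gg_wei, t), sv.log_density(wei, t), atol=1e-8
        )
        np.testing.assert_allclose(
            np.log(sv.survival(gg_wei, t)), np.log(sv.survival(wei, t)), atol=1e-8
        )

    @pytest.mark.parametrize("family", ALL_FAMILIES)
    def test_density_is_negative_derivative_of_survival(self, family):
        theta = sv.params(family, *TYPICAL_PARAMS[family])
        t = np.array([0.3, 0.8, 1.5, 3.0, 6.0])
        h = 1e-5
        dS = (sv.survival(theta, t + h) - sv.survival(theta, t - h)) / (2 * h)
        f = np.exp(sv.log_density(theta, t))
        np.testing.assert_allclose(-dS, f, rtol=1e-4)

    def test_nonpositive_time_rejected(self):
        theta = sv.params("gamma", 1.0, 1.0)
        with pytest.raises(sv.DomainError):
            sv.log_density(theta, 0.0)


class TestHazard:
    def test_exponential_hazard_constant(self):
        theta = sv.params("exponential", 0.3)
        for t in (0.1, 1.0, 50.0):
            assert sv.hazard(theta, t) == pytest.approx(0.3, abs=1e-12)

    def test_weibull_increasing_shape_gt_one(self):
        theta = sv.params("weibull", 1.8, 0.3)
        t = np.linspace(0.1, 10.0, 50)
        h = sv.hazard(theta, t)
        assert np.all(np.diff(h) > 0)

    def test_lognormal_hazard_decreasing_tail(self):
        theta = sv.params("lognormal", 0.0, 1.0)
        assert sv.hazard(theta, 5.0) > sv.hazard(theta, 50.0)

    def test_undefined_hazard_when_survival_is_zero(self):
        theta = sv.params("gamma", 1.4, 0.6)  # upper incomplete gamma hits 0
        with pytest.raises(sv.DomainError, match="hazard"):
            sv.hazard(theta, 1e4)


class TestSampling:
    def test_exponential_mean_law_of_large_numbers(self):
        n = 100_000
        x = sv.sample_event_times(sv.params("exponential", 1.0), n, rng_seed=7)
        assert abs(x.mean() - 1.0) < 3.0 / np.sqrt(n)

    def test_fixed_seed_reproducible(self):
        theta = sv.params("weibull", 1.2, 0.5)
        a = sv.sample_event_times(theta, 100, rng_seed=11)
        b = sv.sample_event_times(theta, 100, rng_seed=11)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("family", ALL_FAMILIES)
    def test_ks_agreement_with_analytic_cdf(self, family):
        values = TYPICAL_PARAMS[family]
        x = sv.sample_event_times(sv.params(family, *values), 10_000, rng_seed=3)
        stat = stats.kstest(x, scipy_dist(family, values).cdf).statistic
        assert stat < 1.628 / np.sqrt(10_000)  # 1% critical value

    def test_gompertz_negative_shape_cure_fraction(self):
        theta = sv.params("gompertz", -0.5, 0.4)
        x = sv.sample_event_times(theta, 50_000, rng_seed=5)
        frac_inf = np.mean(np.isinf(x))
        assert frac_inf == pytest.approx(np.exp(0.4 / -0.5), abs=0.01)
        cond = sv.sample_event_times(theta, 5_000, rng_seed=5, on_infinite="condition")
        assert np.all(np.isfinite(cond))


class TestTransforms:
    @pytest.mark.parametrize("family", ALL_FAMILIES)
    def test_round_trip_identity(self, family):
        theta = sv.params(family, *TYPICAL_PARAMS[family])
        u = sv.to_unconstrained(theta)
        back = sv.from_unconstrained(family, u)
        np.testing.assert_allclose(back.array, theta.array, atol=1e-12)

    def test_gompertz_layout_identity_then_log(self):
        theta = sv.params("gompertz", -0.3, 2.0)
        u = sv.to_unconstrained(theta)
        np.testing.assert_allclose(u, [-0.3, np.log(2.0)])

    def test_log_jacobian_single_log_component(self):
        u = np.array([0.7])
        assert sv.log_jacobian("exponential", u) == pytest.approx(0.7)
        # gompertz: only the rate is log-mapped
        assert sv.log_jacobian("gompertz", np.array([5.0, 0.7])) == pytest.approx(0.7)

    def test_non_finite_input_rejected(self):
        with pytest.raises(sv.DomainError):
            sv.from_unconstrained("weibull", np.array([np.nan, 0.0]))
        with pytest.raises(sv.DomainError):
            sv.log_jacobian("weibull", np.array([np.inf, 0.0]))

    def test_vectorized_back_transform_matches_scalar(self):
        u = np.array([[0.1, -0.2], [1.0, 0.5]])
        out = natural_from_unconstrained("weibull", u)
        for row_u, row_v in zip(u, out):
            np.testing.assert_allclose(
                sv.from_unconstrained("weibull", row_u).array, row_v
            )


class TestBroadcasting:
    def test_draws_by_times_surface(self):
        draws = np.array([[1.0, 0.2], [1.5, 0.4]])  # weibull (shape, rate)
        t = np.array([0.5, 1.0, 2.0])
        surface = log_sf("weibull", draws, t)
        assert surface.shape == (2, 3)
        for i in range(2):
            np.testing.assert_allclose(
                surface[i], log_sf("weibull", draws[i], t), atol=1e-14
            )
        surface_pdf = log_pdf("weibull", draws, t)
        assert surface_pdf.shape == (2, 3)


@given(
    lam=st.floats(0.05, 5.0),
    v=st.floats(0.3, 3.0),
    t1=st.floats(0.01, 20.0),
    dt=st.floats(0.01, 10.0),
)
def test_weibull_survival_monotone_property(lam, v, t1, dt):
    theta = sv.params("weibull", v, lam)
    s1, s2 = sv.survival(theta, t1), sv.survival(theta, t1 + dt)
    assert 0.0 <= s2 <= s1 <= 1.0


@given(
    family=st.sampled_from(ALL_FAMILIES),
    scale=st.floats(-2.0, 2.0),
)
def test_transform_round_trip_property(family, scale):
    base = np.asarray(TYPICAL_PARAMS[family])
    theta = sv.params(family, *(base * np.exp(scale)))
    u = sv.to_unconstrained(theta)
    np.testing.assert_allclose(
        sv.from_unconstrained(family, u).array, theta.array, rtol=1e-12
    )
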