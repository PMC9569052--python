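"""Elicited-triplet conversion and truncated-normal constraint densities.

scipy.stats.truncnorm and scipy quadrature serve as independent oracles for
the hand-written density; the sigma-from-limits rule is checked against the
inverse standard-normal CDF directly.
"""

import json

import numpy as np
import pytest
from scipy import integrate, stats

import survelicit as sv
from survelicit.elicitation import Z99

Z99_ORACLE = float(stats.norm.ppf(0.99))


class TestConstraintFromElicitation:
    def test_sigma_from_interval_width(self):
        e = sv.ElicitedTimePoint(t_E=3.0, LPL=0.05, MLV=0.12, UPL=0.20)
        c = sv.constraint_from_elicitation(e)
        assert c.y == 0.12
        assert c.sigma == pytest.approx(0.15 / (2 * Z99_ORACLE), abs=1e-9)
        assert c.sigma == pytest.approx(0.0322394, abs=5e-7)

    def test_boundary_mlv_zero_accepted(self):
        e = sv.ElicitedTimePoint(t_E=10.0, LPL=0.0, MLV=0.0, UPL=0.05)
        c = sv.constraint_from_elicitation(e)
        assert c.y == 0.0
        assert c.sigma == pytest.approx(0.05 / (2 * Z99_ORACLE), abs=1e-9)
        assert c.sigma == pytest.approx(0.0107465, abs=5e-7)

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError, match="zero-width"):
            sv.ElicitedTimePoint(t_E=3.0, LPL=0.3, MLV=0.3, UPL=0.3)

    def test_out_of_order_quantiles_rejected(self):
        with pytest.raises(ValueError, match="out of order"):
            sv.ElicitedTimePoint(t_E=3.0, LPL=0.4, MLV=0.3, UPL=0.5)

    def test_equal_width_gives_equal_sigma(self):
        a = sv.constraint_from_elicitation(
            sv.ElicitedTimePoint(t_E=3.0, LPL=0.10, MLV=0.15, UPL=0.30)
        )
        b = sv.constraint_from_elicitation(
            sv.ElicitedTimePoint(t_E=3.0, LPL=0.55, MLV=0.70, UPL=0.75)
        )
        assert a.sigma == pytest.approx(b.sigma, abs=1e-15)

    def test_z99_constant_matches_oracle(self):
        assert Z99 == pytest.approx(Z99_ORACLE, abs=1e-12)


class TestTruncnormLogDensity:
    @pytest.mark.parametrize(
        "y,mu,sigma",
        [
            (0.5, 0.5, 0.1),
            (0.0, 0.0, 0.01),
            (1.0, 0.9, 0.2),
            (0.12, 0.3, 0.05),
            (0.97, 0.02, 0.3),
        ],
    )
    def test_matches_scipy_truncnorm(self, y, mu, sigma):
        oracle = stats.truncnorm.logpdf(
            y, (0.0 - mu) / sigma, (1.0 - mu) / sigma, loc=mu, scale=sigma
        )
        assert sv.truncnorm_log_density(y, mu, sigma) == pytest.approx(oracle, abs=1e-10)

    def test_central_value(self):
        # phi(0)/0.1 over essentially full mass
        assert sv.truncnorm_log_density(0.5, 0.5, 0.1) == pytest.approx(
            1.383647, abs=5e-6
        )

    def test_half_mass_boundary_value(self):
        # mu at the lower bound: truncation keeps half the normal mass
        assert sv.truncnorm_log_density(0.0, 0.0, 0.01) == pytest.approx(
            np.log(2 * stats.norm.pdf(0) / 0.01), abs=1e-10
        )
        assert sv.truncnorm_log_density(0.0, 0.0, 0.01) == pytest.approx(4.379, abs=5e-4)

    @pytest.mark.parametrize("mu,sigma", [(0.3, 0.05), (0.0, 0.02), (0.9, 0.2)])
    def test_integrates_to_one(self, mu, sigma):
        val, _ = integrate.quad(
            lambda y: np.exp(sv.truncnorm_log_density(y, mu, sigma)), 0.0, 1.0,
            limit=200,
        )
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_y_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            sv.truncnorm_log_density(1.2, 0.5, 0.1)
        with pytest.raises(ValueError):
            sv.truncnorm_log_density(-0.1, 0.5, 0.1)

    def test_without_truncation_constant_is_plain_normal_kernel(self):
        y, mu, sigma = 0.2, 0.6, 0.1
        got = sv.truncnorm_log_density(y, mu, sigma, include_truncation_constant=False)
        assert got == pytest.approx(stats.norm.logpdf(y, mu, sigma), abs=1e-12)


class TestExpertLogLikelihood:
    def test_empty_set_contributes_zero(self):
        theta = sv.params("weibull", 1.2, 0.4)
        assert sv.expert_log_likelihood(theta, sv.ElicitationSet()) == 0.0

    def test_maximized_when_model_matches_mlv(self):
        # single constraint at t=3 with y=0.3: the exponential rate whose
        # survival hits y exactly should maximize the expert term
        y, t_E, sigma = 0.3, 3.0, 0.03
        cons = sv.ElicitationSet((sv.ExpertConstraint(t_E=t_E, y=y, sigma=sigma),))
        lam_star = -np.log(y) / t_E
        grid = np.linspace(0.05, 1.5, 400)
        vals = [
            sv.expert_log_likelihood(sv.params("exponential", lam), cons)
            for lam in grid
        ]
        lam_hat = grid[int(np.argmax(vals))]
        assert lam_hat == pytest.approx(lam_star, abs=2 * (grid[1] - grid[0]))

    def test_quadratic_curvature_halves_with_doubled_sigma(self):
        # in the mid-range of [0,1] truncation is negligible and the kernel is
        # an ordinary normal: the penalty for a fixed 0.05 deviation scales
        # as 1/sigma^2
        t_E, y = 3.0, 0.5
        lam_at = lambda s: -np.log(s) / t_E
        for sigma, ratio in [(0.05, 4.0)]:
            cons1 = sv.ElicitationSet((sv.ExpertConstraint(t_E, y, sigma),))
            cons2 = sv.ElicitationSet((sv.ExpertConstraint(t_E, y, 2 * sigma),))
            d1 = sv.expert_log_likelihood(
                sv.params("exponential", lam_at(y)), cons1
            ) - sv.expert_log_likelihood(sv.params("exponential", lam_at(y + 0.05)), cons1)
            d2 = sv.expert_log_likelihood(
                sv.params("exponential", lam_at(y)), cons2
            ) - sv.expert_log_likelihood(sv.params("exponential", lam_at(y + 0.05)), cons2)
            assert d1 / d2 == pytest.approx(ratio, rel=0.1)

    def test_vague_sigma_switches_constraint_off(self):
        grid = np.linspace(0.05, 1.5, 50)

        def variation(sigma):
            cons = sv.ElicitationSet((sv.ExpertConstraint(3.0, 0.3, sigma),))
            vals = [
                sv.expert_log_likelihood(sv.params("exponential", lam), cons)
                for lam in grid
            ]
            return max(vals) - min(vals)

        assert variation(100.0) < variation(1.0) < variation(0.05)
        assert variation(1000.0) < 1e-4

    def test_unimodal_along_monotone_path(self):
        cons = sv.ElicitationSet((sv.ExpertConstraint(3.0, 0.3, 0.05),))
        grid = np.linspace(0.02, 2.0, 300)
        vals = np.array(
            [sv.expert_log_likelihood(sv.params("exponential", g), cons) for g in grid]
        )
        peak = int(np.argmax(vals))
        assert np.all(np.diff(vals[: peak + 1]) >= -1e-12)
        assert np.all(np.diff(vals[peak:]) <= 1e-12)


class TestElicitationSet:
    def test_horizons_must_increase(self):
        c3 = sv.ExpertConstraint(3.0, 0.3, 0.02)
        c5 = sv.ExpertConstraint(5.0, 0.15, 0.02)
        with pytest.raises(ValueError, match="increasing"):
            sv.ElicitationSet((c5, c3))

    def test_from_elicited(self):
        pts = [
            sv.ElicitedTimePoint(3.0, 0.25, 0.30, 0.35),
            sv.ElicitedTimePoint(5.0, 0.10, 0.15, 0.20),
        ]
        es = sv.ElicitationSet.from_elicited(pts)
        assert len(es) == 2
        np.testing.assert_allclose(es.y, [0.30, 0.15])


class TestLoader:
    def _entries(self):
        return [
            {"time": 3, "lpl": 0.25, "mlv": 0.30, "upl": 0.35},
            {"time": 60, "time_unit": "months", "lpl": 0.10, "mlv": 0.15, "upl": 0.20},
        ]

    def test_json_and_yaml_round_trip(self, tmp_path):
        import yaml

        entries = self._entries()
        pj = tmp_path / "e.json"
        pj.write_text(json.dumps(entries))
        py = tmp_path / "e.yaml"
        py.write_text(yaml.safe_dump(entries))
        for p in (pj, py):
            pts = sv.load_elicitation(p)
            assert [pt.t_E for pt in pts] == [3.0, 5.0]  # months converted
            assert pts[1].MLV == 0.15

    def test_bad_entry_named_in_error(self, tmp_path):
        entries = self._entries()
        entries[1]["lpl"] = 0.5  # above MLV
        p = tmp_path / "e.json"
        p.write_text(json.dumps(entries))
        with pytest.raises(ValueError, match="entry 1"):
            sv.load_elicitation(p)

    def test_missing_key_named(self, tmp_path):
        p = tmp_path / "e.json"
        p.write_text(json.dumps([{"time": 3, "lpl": 0.1, "upl": 0.3}]))
        with pytest.raises(ValueError, match="mlv"):
            sv.load_elicitation(p)
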