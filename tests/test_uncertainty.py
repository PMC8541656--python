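"""PSA distribution construction, coefficient sampling, tornado and PSA runs."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import grainmod as gm
from grainmod.uncertainty import (DistributionSpec, build_psa_specs,
                                  default_owsa_parameters, OWSAParameter,
                                  _effectiveness_setter)


class TestDistributionConstruction:
    @pytest.mark.parametrize("mean, printed_se", [
        (3315.0, 423.0), (4401.0, 561.0), (7632.0, 974.0), (584.0, 74.0),
    ])
    def test_pm25_ses_match_published_values(self, mean, printed_se):
        """SEs implied by a +/-25% 95% CI reproduce the published cost SEs
        to the euro they were printed at."""
        assert gm.se_from_pm25(mean) == pytest.approx(printed_se, abs=1.0)

    def test_gamma_method_of_moments(self):
        spec = gm.gamma_from_moments(3315.0, 423.0)
        assert spec.params["shape"] == pytest.approx((3315 / 423) ** 2, rel=1e-12)
        assert spec.params["scale"] == pytest.approx(423 ** 2 / 3315, rel=1e-12)
        # analytic moment round-trip
        assert spec.params["shape"] * spec.params["scale"] == pytest.approx(3315.0)
        assert np.sqrt(spec.params["shape"]) * spec.params["scale"] \
            == pytest.approx(423.0)

    def test_gamma_mean_equal_se_is_exponential(self):
        spec = gm.gamma_from_moments(5.0, 5.0)
        assert spec.params["shape"] == pytest.approx(1.0, rel=1e-12)

    def test_gamma_monte_carlo_mean(self):
        spec = gm.gamma_from_moments(3315.0, 423.0)
        draws = spec.sample(np.random.default_rng(0), size=10**6)
        assert abs(draws.mean() - 3315.0) < 3 * 423.0 / 1000.0

    @pytest.mark.parametrize("mean, se, alpha, beta", [
        (0.906, 0.003, 8573, 889),     # baseline utility, women 30-44
        (0.041, 0.012, 11.19, 261.9),  # T2D disutility
        (0.770, 0.008, 2130, 636),     # baseline utility, women 65+
    ])
    def test_beta_parameters_match_published_tables(self, mean, se, alpha, beta):
        spec = gm.beta_from_moments(mean, se)
        assert spec.params["alpha"] == pytest.approx(alpha, rel=0.01)
        assert spec.params["beta"] == pytest.approx(beta, rel=0.01)
        # analytic moment round-trip
        a, b = spec.params["alpha"], spec.params["beta"]
        assert a / (a + b) == pytest.approx(mean, rel=1e-12)
        assert np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1))) \
            == pytest.approx(se, rel=1e-9)

    def test_complication_disutility_se(self):
        assert gm.se_from_pm25(0.119) == pytest.approx(0.015, abs=5e-4)

    def test_beta_symmetry_at_half(self):
        spec = gm.beta_from_moments(0.5, 0.05)
        assert spec.params["alpha"] == pytest.approx(spec.params["beta"], rel=1e-12)

    def test_beta_overdispersion_rejected(self):
        with pytest.raises(ValueError):
            gm.beta_from_moments(0.5, 0.6)

    def test_lognormal_se_from_ci_matches_published(self):
        spec = gm.lognormal_from_hr_ci(2.36, 1.70, 3.29)
        assert spec.se == pytest.approx(0.41, abs=5e-3)

    def test_lognormal_median_is_hazard_ratio(self):
        spec = gm.lognormal_from_hr_ci(2.36, 1.70, 3.29)
        draws = spec.sample(np.random.default_rng(1), size=10**6)
        assert np.median(draws) == pytest.approx(2.36, rel=5e-3)

    def test_degenerate_ci_is_point_mass(self):
        spec = gm.lognormal_from_hr_ci(0.73, 0.73, 0.73)
        assert spec.se == 0.0
        assert spec.sample(np.random.default_rng(2)) == 0.73

    def test_invalid_ci_ordering_rejected(self):
        with pytest.raises(ValueError):
            gm.lognormal_from_hr_ci(2.36, 3.29, 1.70)


class TestWeibullCoefficientSampling:
    def test_zero_covariance_returns_point_estimates(self, bundle):
        fit = replace(bundle.incidence_fit,
                      covariance=np.zeros_like(bundle.incidence_fit.covariance))
        shape, coefs = gm.sample_weibull_coefficients(fit, 7)
        assert shape == bundle.incidence_fit.shape
        assert coefs == bundle.incidence_fit.coefficients

    def test_sample_covariance_matches_fit_covariance(self, bundle):
        fit = bundle.incidence_fit
        rng = np.random.default_rng(5)
        draws = np.array([
            np.concatenate([[np.log(s)], list(c.values())])
            for s, c in (gm.sample_weibull_coefficients(fit, rng)
                         for _ in range(20_000))
        ])
        emp = np.cov(draws.T)
        rel = (np.linalg.norm(emp - fit.covariance, "fro")
               / np.linalg.norm(fit.covariance, "fro"))
        assert rel < 0.05

    def test_fixed_seed_reproducible(self, bundle):
        a = gm.sample_weibull_coefficients(bundle.incidence_fit, 11)
        b = gm.sample_weibull_coefficients(bundle.incidence_fit, 11)
        assert a == b


class TestOWSA:
    def test_zero_width_parameter_gives_zero_bar(self, bundle):
        base = bundle.econ.cost_medication
        params = [OWSAParameter("cost_medication", base, base,
                                lambda b, v: (b.with_updates(
                                    econ=replace(b.econ, cost_medication=v)), None))]
        tornado = gm.run_owsa(bundle, scenario="I", horizon=10, parameters=params)
        assert tornado.loc[0, "savings_range"] == pytest.approx(0.0, abs=1e-6)

    def test_discount_zero_beats_five_percent(self, bundle):
        params = [p for p in default_owsa_parameters(
            bundle.econ, bundle.util, bundle.hrs, bundle.effect)
            if p.name == "discount_rate"]
        tornado = gm.run_owsa(bundle, scenario="I", horizon=20, parameters=params)
        row = tornado.iloc[0]
        assert row["savings_low"] > row["savings_high"]  # 0% rate > 5% rate
        assert row["qaly_low"] > row["qaly_high"]

    def test_effectiveness_is_widest_bar_against_cost_bars(self, bundle):
        """When the comparison set is the effect HRs at their CIs versus
        costs at +/-25%, the effectiveness bar dominates the tornado."""
        pm25 = lambda v: (0.75 * v, 1.25 * v)
        e = bundle.effect

        def cost_setter(name):
            return lambda b, v: (b.with_updates(econ=replace(b.econ, **{name: v})), None)

        params = [OWSAParameter("effectiveness",
                                (e.ci_one[0], e.ci_two_plus[0]),
                                (e.ci_one[1], e.ci_two_plus[1]),
                                _effectiveness_setter)]
        for name in ("cost_t2d_secondary", "cost_complications",
                     "cost_medication", "cost_primary_male", "cost_primary_female"):
            params.append(OWSAParameter(name, *pm25(getattr(bundle.econ, name)),
                                        cost_setter(name)))
        tornado = gm.run_owsa(bundle, scenario="I", horizon=20, parameters=params)
        assert tornado.loc[0, "parameter"] == "effectiveness"


class TestPSA:
    def test_zero_variance_psa_equals_deterministic_base_case(self, bundle):
        specs = {name: DistributionSpec(spec.kind, spec.mean, 0.0)
                 for name, spec in build_psa_specs(
                     bundle.econ, bundle.util, bundle.hrs, bundle.effect).items()}
        frozen = bundle.with_updates(
            incidence_fit=replace(bundle.incidence_fit,
                                  covariance=np.zeros_like(bundle.incidence_fit.covariance)),
            complication_fit=replace(bundle.complication_fit,
                                     covariance=np.zeros_like(bundle.complication_fit.covariance)),
        )
        psa = gm.run_psa(frozen, ("I",), (10,), n_iterations=1, seed=0, specs=specs)
        deterministic = gm.evaluate_scenarios(frozen, ("I",), (10,))
        expected = deterministic.summaries["I"].table.loc[(10, "total", True)]
        row = psa.draws.iloc[0]
        assert row["savings_with_productivity"] == pytest.approx(
            expected["savings"], rel=1e-9)
        assert row["qaly_gain"] == pytest.approx(expected["qaly_gain"], rel=1e-9)

    def test_fixed_seed_reproduces_draws_exactly(self, bundle):
        a = gm.run_psa(bundle, ("I",), (10,), n_iterations=3, seed=42)
        b = gm.run_psa(bundle, ("I",), (10,), n_iterations=3, seed=42)
        pd.testing.assert_frame_equal(a.draws, b.draws)
        pd.testing.assert_frame_equal(a.parameters, b.parameters)

    def test_draws_land_in_southeast_quadrant(self, bundle):
        """Positive savings and positive QALY gains in every iteration (both
        effect hazard-ratio CIs lie below 1)."""
        psa = gm.run_psa(bundle, ("I",), (10,), n_iterations=25, seed=3)
        assert (psa.draws["savings_with_productivity"] > 0).all()
        assert (psa.draws["savings_without_productivity"] > 0).all()
        assert (psa.draws["qaly_gain"] > 0).all()

    def test_probability_curve_is_complement_cdf(self, bundle):
        psa = gm.run_psa(bundle, ("I",), (10,), n_iterations=10, seed=9)
        curve = gm.probability_of_savings(psa.draws)
        probs = curve["probability"].to_numpy()
        assert (np.diff(probs) <= 1e-12).all()  # non-increasing in threshold
        values = psa.draws["savings_with_productivity"].to_numpy()
        s0 = curve.iloc[0]
        assert s0["probability"] == np.mean(values >= s0["threshold"])
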