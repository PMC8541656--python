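"""Markov engine: stepping, conservation, mortality adjustment, calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import grainmod as gm
from grainmod.engine import CohortState, CycleTransitions, step


def _flat_life_table(q_value=1e-15, max_age=120):
    ages = np.arange(30, max_age + 1)
    rows = []
    for sex in gm.SEXES:
        q = np.full(len(ages), q_value)
        q[-1] = 1.0
        rows.append(pd.DataFrame({"age": ages, "sex": sex, "q": q}))
    return gm.LifeTable(pd.concat(rows, ignore_index=True))


def _toy_cohort():
    return pd.DataFrame({
        "age": [40, 60], "sex": ["female", "male"],
        "findrisc_category": [1, 3], "count": [1000.0, 500.0],
    })


def _constant_hazard_fit(scale):
    return gm.WeibullFit(
        shape=1.0, coefficients={"intercept": float(np.log(scale))},
        covariance=np.zeros((2, 2)), param_names=["log_shape", "intercept"],
        loglik=0.0, aic=0.0, bic=0.0, n=100, n_events=100, covariates=[],
    )


def _toy_model(inc_scale=20.0, comp_scale=30.0, life_table=None, hrs=None,
               duration_mode="tunnel"):
    # incidence fit without covariates applies the same hazard to every stratum
    return gm.MarkovModel(_toy_cohort(), _constant_hazard_fit(inc_scale),
                          _constant_hazard_fit(comp_scale),
                          life_table or _flat_life_table(),
                          hrs or gm.MortalityHRs(), duration_mode)


class TestDeathProbability:
    def test_cumulative_hazard_scaling_closed_form(self, life_table):
        table = _flat_life_table(q_value=0.01)
        hrs = gm.MortalityHRs()
        p = gm.state_death_probability(70, "male", "T2Dc", table, hrs)
        assert p == pytest.approx(1.0 - 0.99 ** 2.36, abs=1e-12)

    def test_unit_hazard_ratio_returns_life_table_q(self, life_table):
        hrs = gm.MortalityHRs(hr_t2d_female=1.0, hr_t2d_male=1.0, hr_t2dc=1.0)
        for state in ("NoT2D", "T2D", "T2Dc"):
            assert gm.state_death_probability(50, "female", state, life_table, hrs) \
                == pytest.approx(life_table.q(50, "female"), abs=1e-15)

    def test_certain_death_is_absorbing_cap(self, life_table):
        hrs = gm.MortalityHRs()
        for state in ("NoT2D", "T2D", "T2Dc"):
            assert gm.state_death_probability(110, "male", state, life_table, hrs) == 1.0

    def test_sex_specific_hr_selection(self, life_table):
        hrs = gm.MortalityHRs()
        q = life_table.q(60, "female")
        assert gm.state_death_probability(60, "female", "T2D", life_table, hrs) \
            == pytest.approx(1 - (1 - q) ** 2.47, abs=1e-12)

    def test_missing_age_raises(self, life_table):
        with pytest.raises(gm.LifeTableError):
            gm.state_death_probability(120, "male", "NoT2D", life_table, gm.MortalityHRs())


def _state(no, t2d, t2dc, dead):
    return CohortState(no_t2d=np.asarray(no, float), t2d=np.asarray(t2d, float),
                       t2dc=np.asarray(t2dc, float), dead=np.asarray(dead, float))


class TestStep:
    def test_no_transitions_leaves_occupancy_unchanged(self):
        s = _state([100.0], [[10.0, 5.0]], [3.0], [2.0])
        zeros = np.zeros(1)
        tr = CycleTransitions(zeros, zeros, zeros, zeros, np.zeros((1, 2)))
        out = step(s, tr)
        assert out.no_t2d[0] == 100.0
        assert out.t2d[0].sum() == 15.0
        assert out.t2dc[0] == 3.0 and out.dead[0] == 2.0

    def test_certain_incidence_moves_all_mass(self):
        s = _state([100.0], [[0.0, 0.0]], [0.0], [0.0])
        zeros = np.zeros(1)
        tr = CycleTransitions(zeros, zeros, zeros, np.ones(1), np.zeros((1, 2)))
        out = step(s, tr)
        assert out.no_t2d[0] == 0.0
        assert out.t2d[0, 0] == 100.0

    def test_tunnel_layers_shift_by_one_year(self):
        s = _state([0.0], [[10.0, 4.0]], [0.0], [0.0])
        zeros = np.zeros(1)
        tr = CycleTransitions(zeros, zeros, zeros, zeros, np.zeros((1, 2)))
        out = step(s, tr)
        assert out.t2d[0, 0] == 0.0
        assert out.t2d[0, 1] == 14.0  # terminal layer accumulates

    def test_out_of_range_probability_fails_loudly(self):
        s = _state([1.0], [[0.0]], [0.0], [0.0])
        tr = CycleTransitions(np.array([1.2]), np.zeros(1), np.zeros(1),
                              np.zeros(1), np.zeros((1, 1)))
        with pytest.raises(gm.EngineError):
            step(s, tr)

    @given(
        p=arrays(float, (4,), elements=st.floats(0.0, 1.0)),
        pc=arrays(float, (3,), elements=st.floats(0.0, 1.0)),
        occ=arrays(float, (6,), elements=st.floats(0.0, 1e6)),
    )
    def test_mass_conservation_under_random_probabilities(self, p, pc, occ):
        s = _state([occ[0]], [list(occ[1:4])], [occ[4]], [occ[5]])
        tr = CycleTransitions(p[:1], p[1:2], p[2:3], p[3:4], pc[None, :])
        out = step(s, tr)
        assert out.total()[0] == pytest.approx(s.total()[0], rel=1e-12, abs=1e-9)
        assert out.dead[0] >= s.dead[0]


class TestRun:
    def test_horizon_one_equals_single_step(self, model, mstar):
        trace = model.run(1, mstar)
        assert trace.horizon == 1
        assert trace.occupancy.shape[0] == 2

    def test_cumulative_incidence_closed_form_without_mortality(self):
        """Negligible mortality, constant hazard: cumulative incidence is
        1 - exp(-t / scale)."""
        scale = 20.0
        model = _toy_model(inc_scale=scale)
        trace = model.run(10)
        for t in (1, 5, 10):
            assert trace.cumulative_incidence(t) == pytest.approx(
                1.0 - np.exp(-t / scale), abs=1e-9)

    def test_mass_conservation_on_default_model(self, model, mstar):
        trace = model.run(30, mstar)
        totals = trace.occupancy.sum(axis=(1, 2))
        # at most 1e-6 absolute drift per million persons
        assert np.max(np.abs(totals - totals[0])) <= 1e-6 * totals[0] / 1e6
        assert np.max(np.abs(totals - totals[0])) / totals[0] < 1e-12

    def test_dead_state_is_absorbing(self, model, mstar):
        trace = model.run(30, mstar)
        dead = trace.occupancy[:, :, 3]
        assert (np.diff(dead, axis=0) >= -1e-9).all()

    def test_new_cases_and_deaths_nonnegative(self, model, mstar):
        trace = model.run(20, mstar)
        assert (trace.new_cases >= 0).all()
        assert (trace.deaths >= 0).all()

    def test_fast_incidence_path_matches_full_run(self, model, mstar):
        trace = model.run(10, mstar)
        assert model.cumulative_incidence(mstar) == pytest.approx(
            trace.cumulative_incidence(10), abs=1e-12)

    def test_life_years_match_plain_survivorship_when_hrs_are_one(self, bundle):
        """With unit mortality HRs, being diagnosed changes nothing about
        survival, so alive person-years equal the life-table product."""
        hrs = gm.MortalityHRs(hr_t2d_female=1.0, hr_t2d_male=1.0, hr_t2dc=1.0)
        model = gm.MarkovModel(bundle.cohort, bundle.incidence_fit,
                               bundle.complication_fit, bundle.life_table, hrs)
        trace = model.run(20, 1.0)
        alive = trace.occupancy[:, :, :3].sum(axis=2)
        age0 = bundle.cohort["age"].to_numpy()
        count = bundle.cohort["count"].to_numpy(float)
        for s in (0, 57, 99):
            sex = bundle.cohort["sex"].iloc[s]
            q = bundle.life_table.q_vector(age0[s] + np.arange(20), sex)
            survivorship = count[s] * np.concatenate([[1.0], np.cumprod(1 - q)])
            assert np.allclose(alive[:, s], survivorship, rtol=1e-9)

    def test_life_table_exhaustion_raises(self, bundle):
        with pytest.raises(gm.LifeTableError):
            bundle.model().run(35)  # ages reach 111 > table maximum

    def test_memoryless_mode_conserves_and_differs_from_tunnel(self, bundle, mstar):
        tunnel = bundle.model().run(15, mstar)
        memoryless = gm.MarkovModel(
            bundle.cohort, bundle.incidence_fit, bundle.complication_fit,
            bundle.life_table, duration_mode="memoryless").run(15, mstar)
        totals = memoryless.occupancy.sum(axis=(1, 2))
        assert np.allclose(totals, totals[0], rtol=1e-12)
        # same incident cases, different complication split
        assert memoryless.new_cases.sum() == pytest.approx(
            tunnel.new_cases.sum(), rel=1e-9)
        assert not np.allclose(memoryless.occupancy[-1, :, 2],
                               tunnel.occupancy[-1, :, 2])

    def test_trace_tidy_export(self, model, mstar, tmp_path):
        trace = model.run(2, mstar)
        tidy = trace.to_frame()
        assert set(tidy["state"]) == set(gm.STATES)
        assert len(tidy) == 3 * model.n_strata * 4
        tidy.to_csv(tmp_path / "trace.csv", index=False)
        back = pd.read_csv(tmp_path / "trace.csv")
        assert back["occupancy"].sum() == pytest.approx(tidy["occupancy"].sum())


class TestCalibration:
    def test_fixed_point_when_target_is_own_incidence(self, model):
        target = model.cumulative_incidence(1.0)
        mstar = gm.calibrate_incidence(model, target)
        assert mstar == pytest.approx(1.0, abs=1e-9)

    def test_calibrated_model_reproduces_observed_incidence(self, model, mstar):
        assert model.cumulative_incidence(mstar) == pytest.approx(0.0769, abs=1e-9)

    def test_doubling_target_raises_multiplier(self, model, mstar):
        m2 = gm.calibrate_incidence(model, 2 * 0.0769)
        assert m2 > mstar

    def test_incidence_monotone_in_multiplier(self, model):
        values = [model.cumulative_incidence(m) for m in (0.25, 0.5, 1.0, 2.0)]
        assert values == sorted(values)

    def test_unbracketable_target_raises(self, model):
        with pytest.raises(gm.CalibrationError):
            gm.calibrate_incidence(model, 0.999999, bracket=(1e-3, 1.0))
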