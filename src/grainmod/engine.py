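"""Four-state Markov cohort engine with duration-dependent complication risk.

States: No-T2D, T2D, T2D-with-complications (T2Dc), Dead. The cohort is a
set of (age, sex, FINDRISC category) strata advanced in 1-year cycles.
Within a cycle, death is applied first (life-table probability, scaled on
the cumulative-hazard scale by state-specific hazard ratios) and disease
transitions apply to the survivors; this sequential composition keeps every
per-state outflow at most 1 without renormalization. No half-cycle
correction is applied: state membership is counted at cycle start.

Because a cohort model does not track individual diagnosis dates, T2D
occupancy is held in year-since-entry tunnel layers so that the Weibull
complication hazard is evaluated at the correct time since diagnosis
(``duration_mode="tunnel"``, the default). A duration-free alternative
(``"memoryless"``) evaluates the first-year complication hazard at attained
age every cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .parameters import SEXES, MortalityHRs
from .survival import WeibullFit

STATES = ("NoT2D", "T2D", "T2Dc", "Dead")


class EngineError(RuntimeError):
    pass


class LifeTableError(EngineError):
    """Raised when a death probability is requested outside the table's ages."""


class CalibrationError(EngineError):
    pass


class LifeTable:
    """Annual all-cause death probability q(age, sex) on integer ages."""

    def __init__(self, table: pd.DataFrame):
        required = {"age", "sex", "q"}
        if not required.issubset(table.columns):
            raise ValueError(f"life table needs columns {sorted(required)}")
        self._frame = table.reset_index(drop=True)
        self._q: dict[str, np.ndarray] = {}
        ages = np.sort(table["age"].unique())
        self.min_age = int(ages.min())
        self.max_age = int(ages.max())
        if not np.array_equal(ages, np.arange(self.min_age, self.max_age + 1)):
            raise ValueError("life table ages must be contiguous integers")
        for sex in SEXES:
            sub = table[table["sex"] == sex].sort_values("age")
            if len(sub) != len(ages):
                raise ValueError(f"life table incomplete for sex {sex!r}")
            q = sub["q"].to_numpy(dtype=float)
            if np.any(q <= 0) or np.any(q > 1):
                raise ValueError("q must lie in (0, 1]")
            self._q[sex] = q

    def q(self, age: int, sex: str) -> float:
        return float(self.q_vector(np.asarray([age]), sex)[0])

    def q_vector(self, ages: np.ndarray, sex: str) -> np.ndarray:
        ages = np.asarray(ages, dtype=int)
        if ages.min() < self.min_age or ages.max() > self.max_age:
            raise LifeTableError(
                f"age outside life table range [{self.min_age}, {self.max_age}]")
        return self._q[sex][ages - self.min_age]

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def to_csv(self, path: str | Path) -> None:
        # %.17g guarantees bit-exact float round-trips through the CSV
        self._frame.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        return cls(pd.read_csv(path, float_precision="round_trip"))


def state_death_probability(age: int, sex: str, state: str,
                            life_table: LifeTable, hrs: MortalityHRs) -> float:
    """Annual death probability by health state.

    The disease-state hazard ratios scale the cumulative hazard:
    ``1 - (1 - q)**HR``, capped at 1. The Dead state returns 0.
    """
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}")
    if state == "Dead":
        return 0.0
    q = life_table.q(age, sex)
    if state == "NoT2D":
        return q
    hr = hrs.hr_t2dc if state == "T2Dc" else hrs.hr_t2d(sex)
    return min(1.0, 1.0 - (1.0 - q) ** hr)


@dataclass
class CohortState:
    """Occupancy of one cycle: No-T2D pool, T2D tunnel layers (column d =
    d years since diagnosis), complicated pool and cumulative deaths —
    each per stratum."""

    no_t2d: np.ndarray          # (n_strata,)
    t2d: np.ndarray             # (n_strata, n_layers)
    t2dc: np.ndarray            # (n_strata,)
    dead: np.ndarray            # (n_strata,)

    def total(self) -> np.ndarray:
        return self.no_t2d + self.t2d.sum(axis=1) + self.t2dc + self.dead

    def occupancy(self) -> np.ndarray:
        """(n_strata, 4) array in STATES order, tunnels collapsed."""
        return np.column_stack(
            [self.no_t2d, self.t2d.sum(axis=1), self.t2dc, self.dead])


@dataclass
class CycleTransitions:
    """Per-stratum transition probabilities for one cycle.

    Death probabilities apply first; ``p_incidence`` and ``p_complication``
    are conditional on surviving the cycle. ``p_complication`` has one
    column per tunnel layer (time since T2D entry).
    """

    p_death_no: np.ndarray
    p_death_t2d: np.ndarray
    p_death_t2dc: np.ndarray
    p_incidence: np.ndarray
    p_complication: np.ndarray  # (n_strata, n_layers)

    def validate(self) -> None:
        for name in ("p_death_no", "p_death_t2d", "p_death_t2dc",
                     "p_incidence", "p_complication"):
            p = getattr(self, name)
            if np.any(p < 0) or np.any(p > 1):
                raise EngineError(
                    f"{name} outside [0, 1]: transition probabilities from a "
                    "state must not imply total outflow above 1")


def step(state: CohortState, tr: CycleTransitions) -> CohortState:
    """Advance the cohort one cycle (death first, then disease transitions).

    Mass is conserved exactly; Dead is absorbing; new T2D cases enter tunnel
    layer 0, complication-free survivors shift one layer deeper (the last
    layer accumulates).
    """
    tr.validate()
    n, n_layers = state.t2d.shape

    surv_no = state.no_t2d * (1.0 - tr.p_death_no)
    deaths = state.no_t2d * tr.p_death_no

    incident = surv_no * tr.p_incidence
    no_next = surv_no - incident

    surv_t2d = state.t2d * (1.0 - tr.p_death_t2d[:, None])
    deaths += (state.t2d.sum(axis=1) - surv_t2d.sum(axis=1))
    to_comp = surv_t2d * tr.p_complication
    stay = surv_t2d - to_comp

    t2d_next = np.zeros_like(state.t2d)
    t2d_next[:, 0] = incident
    t2d_next[:, 1:] = stay[:, :-1]
    t2d_next[:, -1] += stay[:, -1]  # terminal layer accumulates

    surv_c = state.t2dc * (1.0 - tr.p_death_t2dc)
    deaths += state.t2dc * tr.p_death_t2dc
    t2dc_next = surv_c + to_comp.sum(axis=1)

    return CohortState(
        no_t2d=no_next,
        t2d=t2d_next,
        t2dc=t2dc_next,
        dead=state.dead + deaths,
    )


@dataclass
class ModelTrace:
    """Cycle-by-cycle occupancy plus incident-case and death counts.

    ``occupancy`` has shape (horizon + 1, n_strata, 4) in STATES order, row 0
    being the initial cohort; ``new_cases`` and ``deaths`` have shape
    (horizon, n_strata) and count events occurring during each cycle.
    """

    strata: pd.DataFrame
    occupancy: np.ndarray
    new_cases: np.ndarray
    deaths: np.ndarray

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def cumulative_incidence(self, horizon: int | None = None) -> float:
        """Cumulative new T2D cases through ``horizon`` as a fraction of the
        initial cohort."""
        h = self.horizon if horizon is None else horizon
        return float(self.new_cases[:h].sum() / self.occupancy[0].sum())

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: one row per cycle x stratum x state."""
        rows = []
        keys = self.strata[["age", "sex", "findrisc_category"]]
        for t in range(self.horizon + 1):
            for j, state in enumerate(STATES):
                df = keys.copy()
                df.insert(0, "cycle", t)
                df["state"] = state
                df["occupancy"] = self.occupancy[t, :, j]
                rows.append(df)
        return pd.concat(rows, ignore_index=True)


class MarkovModel:
    """Cohort model binding strata, fitted hazards, life table and mortality HRs.

    ``cohort`` needs columns ``age`` (integer baseline age), ``sex``,
    ``findrisc_category`` and ``count``. Counts are carried as reals inside
    the engine (expected-value semantics).
    """

    def __init__(self, cohort: pd.DataFrame, incidence_fit: WeibullFit,
                 complication_fit: WeibullFit, life_table: LifeTable,
                 hrs: MortalityHRs | None = None,
                 duration_mode: str = "tunnel"):
        required = {"age", "sex", "findrisc_category", "count"}
        if not required.issubset(cohort.columns):
            raise ValueError(f"cohort needs columns {sorted(required)}")
        if duration_mode not in ("tunnel", "memoryless"):
            raise ValueError("duration_mode must be 'tunnel' or 'memoryless'")
        self.cohort = cohort.reset_index(drop=True)
        self.life_table = life_table
        self.hrs = hrs or MortalityHRs()
        self.duration_mode = duration_mode
        self.incidence_fit = incidence_fit
        self.complication_fit = complication_fit

        self.age0 = self.cohort["age"].to_numpy(dtype=int)
        self.sex = self.cohort["sex"].to_numpy()
        self.count = self.cohort["count"].to_numpy(dtype=float)
        self.n_strata = len(self.cohort)

        # per-stratum incidence scale lambda(x) and its inverse k-th power
        self._lam_inc = incidence_fit.scale(self.cohort)
        self._k_inc = incidence_fit.shape
        self._k_comp = complication_fit.shape
        self._comp_coef = complication_fit.coefficients
        if set(self._comp_coef) - {"intercept", "age", "sex_male"}:
            raise ValueError("complication fit must use age and sex only")

    # -- precomputations -----------------------------------------------------

    def _comp_inv_scale_k(self, entry_cycles: np.ndarray) -> np.ndarray:
        """lambda_comp(x)**(-k) for each stratum (rows) entering T2D at each
        cycle (columns); the age covariate is the attained age at diagnosis."""
        beta0 = self._comp_coef["intercept"]
        b_age = self._comp_coef.get("age", 0.0)
        b_male = self._comp_coef.get("sex_male", 0.0)
        ages = self.age0[:, None] + entry_cycles[None, :]
        lp = beta0 + b_age * ages + b_male * (self.sex == "male").astype(float)[:, None]
        return np.exp(-self._k_comp * lp)

    def _death_probs(self, ages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        q = np.empty(self.n_strata)
        for sex in SEXES:
            mask = self.sex == sex
            if mask.any():
                q[mask] = self.life_table.q_vector(ages[mask], sex)
        hr_t2d = np.where(self.sex == "male", self.hrs.hr_t2d_male, self.hrs.hr_t2d_female)
        q_t2d = np.minimum(1.0, 1.0 - (1.0 - q) ** hr_t2d)
        q_c = np.minimum(1.0, 1.0 - (1.0 - q) ** self.hrs.hr_t2dc)
        return q, q_t2d, q_c

    def _incidence_probs(self, t: int, hazard_multiplier: float) -> np.ndarray:
        dh = ((t + 1.0) ** self._k_inc - float(t) ** self._k_inc) / self._lam_inc ** self._k_inc
        return 1.0 - np.exp(-hazard_multiplier * dh)

    # -- simulation ----------------------------------------------------------

    def run(self, horizon: int, hazard_multiplier: float = 1.0) -> ModelTrace:
        """Advance the whole cohort ``horizon`` one-year cycles.

        ``hazard_multiplier`` scales the No-T2D -> T2D cumulative hazard; it
        is the product of the calibration multiplier and the scenario's
        weighted hazard ratio.
        """
        if horizon < 1:
            raise ValueError("horizon must be at least 1")
        if hazard_multiplier < 0:
            raise ValueError("hazard_multiplier must be non-negative")
        n, h = self.n_strata, int(horizon)
        k_c = self._k_comp
        inv_scale_k = self._comp_inv_scale_k(np.arange(h, dtype=float))
        layer_incr = (np.arange(1, h + 1, dtype=float) ** k_c
                      - np.arange(h, dtype=float) ** k_c)  # (d+1)^k - d^k

        state = CohortState(
            no_t2d=self.count.copy(),
            t2d=np.zeros((n, h)),
            t2dc=np.zeros(n),
            dead=np.zeros(n),
        )
        occupancy = np.empty((h + 1, n, 4))
        new_cases = np.empty((h, n))
        deaths = np.empty((h, n))
        occupancy[0] = state.occupancy()

        for t in range(h):
            ages = self.age0 + t
            q, q_t2d, q_c = self._death_probs(ages)
            p_inc = self._incidence_probs(t, hazard_multiplier)
            if self.duration_mode == "tunnel":
                # layer d was diagnosed during cycle t-1-d; hazard over (d, d+1]
                entry = np.arange(t - 1, t - 1 - h, -1)
                valid = entry >= 0
                p_comp = np.zeros((n, h))
                if valid.any():
                    p_comp[:, valid] = 1.0 - np.exp(
                        -layer_incr[None, valid] * inv_scale_k[:, np.clip(entry, 0, None)[valid]])
            else:
                # duration-free: first-year complication hazard at attained age
                inv_now = self._comp_inv_scale_k(np.array([float(t)]))[:, 0]
                p_comp = np.tile((1.0 - np.exp(-inv_now))[:, None], (1, h))

            tr = CycleTransitions(
                p_death_no=q, p_death_t2d=q_t2d, p_death_t2dc=q_c,
                p_incidence=p_inc, p_complication=p_comp,
            )
            prev_dead = state.dead
            state = step(state, tr)
            occupancy[t + 1] = state.occupancy()
            new_cases[t] = state.t2d[:, 0]
            deaths[t] = state.dead - prev_dead

        return ModelTrace(strata=self.cohort, occupancy=occupancy,
                          new_cases=new_cases, deaths=deaths)

    def cumulative_incidence(self, hazard_multiplier: float, horizon: int = 10) -> float:
        """Population cumulative T2D incidence through ``horizon`` years.

        Exact fast path: new cases arise only from the No-T2D pool, whose
        dynamics involve just background mortality and the incidence hazard,
        so the tunnel machinery is unnecessary here. Agrees with
        ``run(...).cumulative_incidence()`` to machine precision.
        """
        no = self.count.copy()
        cum = 0.0
        for t in range(horizon):
            ages = self.age0 + t
            q, _, _ = self._death_probs(ages)
            p_inc = self._incidence_probs(t, hazard_multiplier)
            surv = no * (1.0 - q)
            inc = surv * p_inc
            cum += inc.sum()
            no = surv - inc
        return cum / self.count.sum()


def calibrate_incidence(model: MarkovModel, target_10y_incidence: float = 0.0769,
                        bracket: tuple[float, float] = (1e-3, 1e3)) -> float:
    """Find the hazard multiplier m* at which the population 10-year
    cumulative T2D incidence (whole cohort treated as non-users, mortality
    active) equals the observed target.

    Solved by Brent root search on the given bracket; raises
    :class:`CalibrationError` when the target is not bracketed.
    """
    if not target_10y_incidence > 0:
        raise CalibrationError("target incidence must be positive")
    f = lambda m: model.cumulative_incidence(m, horizon=10) - target_10y_incidence
    lo, hi = bracket
    f_lo, f_hi = f(lo), f(hi)
    if f_lo * f_hi > 0:
        raise CalibrationError(
            f"target {target_10y_incidence} not bracketed on [{lo}, {hi}] "
            f"(incidence range [{f_lo + target_10y_incidence:.6g}, "
            f"{f_hi + target_10y_incidence:.6g}])")
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-14))
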