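"""Costs, utilities, discounting and scenario-vs-baseline aggregation.

Annual T2D-attributable costs attach to the T2D and complicated states
(nothing accrues in No-T2D or Dead); productivity losses apply below the
retirement age and can be switched off for the health-care-only perspective.
QALYs weight each person-year by an EQ-5D-3L utility: the sex/age-band
baseline minus the relevant disutilities, floored at zero. Both streams are
discounted at a constant annual rate with cycle 0 undiscounted, and state
membership is counted at cycle start (no half-cycle correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .engine import ModelTrace
from .parameters import AGE_BANDS, MALE, EconomicInputs, UtilityInputs, age_band_index


def annual_cost(state: str, age: float, sex: str, inputs: EconomicInputs,
                include_productivity: bool = True) -> float:
    """Annual per-person cost (euros) for one health state.

    T2D: secondary + primary (sex-specific) + medication, plus productivity
    losses below retirement age when requested; the complicated state adds
    the recurring complication cost on top; No-T2D and Dead cost nothing.
    """
    if state in ("NoT2D", "Dead"):
        return 0.0
    cost = (inputs.cost_t2d_secondary + inputs.cost_primary(sex)
            + inputs.cost_medication)
    if include_productivity and age < inputs.retirement_age:
        cost += inputs.cost_productivity
    if state == "T2Dc":
        cost += inputs.cost_complications
    elif state != "T2D":
        raise ValueError(f"unknown state {state!r}")
    return cost


def annual_utility(state: str, age: float, sex: str, inputs: UtilityInputs) -> float:
    """EQ-5D-3L utility weight for one person-year in a health state."""
    if state == "Dead":
        return 0.0
    base = inputs.baseline_utility(age, sex)
    if state == "NoT2D":
        return base
    if state == "T2D":
        return max(0.0, base - inputs.disutility_t2d)
    if state == "T2Dc":
        if inputs.complication_disutility_mode == "additive":
            return max(0.0, base - inputs.disutility_t2d - inputs.disutility_complications)
        return max(0.0, base - inputs.disutility_complications)
    raise ValueError(f"unknown state {state!r}")


def discount_factor(cycle_index: int, rate: float) -> float:
    """(1 + rate)**(-cycle); cycle 0 is undiscounted."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be non-negative")
    if rate <= -1.0:
        raise ValueError("discount rate must exceed -1")
    return float((1.0 + rate) ** (-cycle_index))


def _per_cycle_values(trace: ModelTrace, econ: EconomicInputs, util: UtilityInputs,
                      include_productivity: bool) -> tuple[np.ndarray, np.ndarray]:
    """Undiscounted cost and QALY accrual per (cycle, stratum)."""
    h = trace.horizon
    age0 = trace.strata["age"].to_numpy(dtype=float)
    sexes = trace.strata["sex"].to_numpy()
    n = len(age0)

    cost = np.zeros((h, n))
    qaly = np.zeros((h, n))
    primary = np.where(sexes == MALE, econ.cost_primary_male, econ.cost_primary_female)
    base_cost_t2d = econ.cost_t2d_secondary + primary + econ.cost_medication

    # baseline utility lookup per (stratum, band)
    band_util = np.array([[util.baseline[s][b][0] for b in range(len(AGE_BANDS))]
                          for s in sexes])
    for t in range(h):
        ages = age0 + t
        bands = np.array([age_band_index(a) for a in ages])
        base_u = band_util[np.arange(n), bands]
        u_t2d = np.maximum(0.0, base_u - util.disutility_t2d)
        if util.complication_disutility_mode == "additive":
            u_t2dc = np.maximum(0.0, base_u - util.disutility_t2d
                                - util.disutility_complications)
        else:
            u_t2dc = np.maximum(0.0, base_u - util.disutility_complications)

        c_t2d = base_cost_t2d.copy()
        if include_productivity:
            c_t2d = c_t2d + econ.cost_productivity * (ages < econ.retirement_age)
        c_t2dc = c_t2d + econ.cost_complications

        occ = trace.occupancy[t]  # state membership at cycle start
        cost[t] = occ[:, 1] * c_t2d + occ[:, 2] * c_t2dc
        qaly[t] = occ[:, 0] * base_u + occ[:, 1] * u_t2d + occ[:, 2] * u_t2dc
    return cost, qaly


def discounted_totals(trace: ModelTrace, econ: EconomicInputs, util: UtilityInputs,
                      horizons: Sequence[int], rate: float | None = None,
                      include_productivity: bool = True) -> pd.DataFrame:
    """Discounted total costs and QALYs by sex, cumulated to each horizon.

    Returns a frame indexed by (horizon, sex) with columns ``cost``, ``qaly``.
    """
    rate = econ.discount_rate if rate is None else rate
    horizons = sorted(set(int(x) for x in horizons))
    if horizons[-1] > trace.horizon:
        raise ValueError("trace shorter than the requested horizon")
    cost, qaly = _per_cycle_values(trace, econ, util, include_productivity)
    disc = (1.0 + rate) ** (-np.arange(trace.horizon, dtype=float))
    cost_d = cost * disc[:, None]
    qaly_d = qaly * disc[:, None]

    sexes = trace.strata["sex"].to_numpy()
    rows = []
    for h in horizons:
        for sex in pd.unique(sexes):
            m = sexes == sex
            rows.append({"horizon": h, "sex": sex,
                         "cost": cost_d[:h, m].sum(), "qaly": qaly_d[:h, m].sum()})
        rows.append({"horizon": h, "sex": "total",
                     "cost": cost_d[:h].sum(), "qaly": qaly_d[:h].sum()})
    return pd.DataFrame(rows).set_index(["horizon", "sex"])


@dataclass
class OutcomeSummary:
    """Scenario-vs-baseline differences: savings (baseline minus scenario
    discounted cost), savings percentage of the baseline cost, and QALY
    gains, by sex and in total, with and without productivity losses."""

    table: pd.DataFrame

    def formatted(self) -> pd.DataFrame:
        """Publication-style view: money in millions of euros at one decimal,
        QALYs as whole numbers."""
        out = self.table.copy()
        for col in ("baseline_cost", "scenario_cost", "savings"):
            out[col + "_meur"] = (out[col] / 1e6).round(1)
            del out[col]
        out["savings_pct"] = out["savings_pct"].round(1)
        for col in ("baseline_qaly", "scenario_qaly", "qaly_gain"):
            out[col] = out[col].round(0).astype(np.int64)
        return out


def aggregate(trace_baseline: ModelTrace, trace_scenario: ModelTrace,
              econ: EconomicInputs, util: UtilityInputs,
              horizons: Iterable[int] | None = None,
              rate: float | None = None) -> OutcomeSummary:
    """Compare a scenario trace against the baseline trace.

    Traces must share the stratum layout and horizon. Costs are evaluated
    both with and without productivity losses (``with_productivity`` column);
    QALYs do not depend on that flag.
    """
    if not trace_baseline.strata[["age", "sex", "findrisc_category"]].equals(
            trace_scenario.strata[["age", "sex", "findrisc_category"]]):
        raise ValueError("traces do not share the same strata")
    if trace_baseline.horizon != trace_scenario.horizon:
        raise ValueError("traces do not share the same horizon")
    if not np.allclose(trace_baseline.occupancy[0], trace_scenario.occupancy[0]):
        raise ValueError("traces do not share the initial cohort")
    horizons = list(horizons) if horizons is not None else [trace_baseline.horizon]

    frames = []
    for include_productivity in (True, False):
        base = discounted_totals(trace_baseline, econ, util, horizons, rate,
                                 include_productivity)
        scen = discounted_totals(trace_scenario, econ, util, horizons, rate,
                                 include_productivity)
        df = pd.DataFrame({
            "baseline_cost": base["cost"],
            "scenario_cost": scen["cost"],
            "baseline_qaly": base["qaly"],
            "scenario_qaly": scen["qaly"],
        })
        df["savings"] = df["baseline_cost"] - df["scenario_cost"]
        with np.errstate(invalid="ignore", divide="ignore"):
            df["savings_pct"] = np.where(df["baseline_cost"] > 0,
                                         df["savings"] / df["baseline_cost"] * 100.0, 0.0)
        df["qaly_gain"] = df["scenario_qaly"] - df["baseline_qaly"]
        df["with_productivity"] = include_productivity
        frames.append(df.reset_index())
    table = pd.concat(frames, ignore_index=True).set_index(
        ["horizon", "sex", "with_productivity"])
    return OutcomeSummary(table=table)
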