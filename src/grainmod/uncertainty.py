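"""One-way (tornado) and probabilistic sensitivity analyses.

Parameter distributions follow the usual health-economic conventions:
costs ~ gamma, utilities and disutilities ~ beta, hazard ratios ~ lognormal,
all parameterized from their published (mean, SE) pairs by the method of
moments; survival-regression coefficients are drawn jointly from a
multivariate normal using the fitted (log-shape, coefficients) covariance so
their correlation structure is preserved. Where no interval is published the
SE is derived from a +/-25% variation read as a 95% CI half-width.

Each probabilistic draw is a full deterministic model evaluation: the
incidence multiplier is re-calibrated to the observed 10-year non-user
incidence under the drawn survival coefficients, then baseline and scenario
arms are run and aggregated with the drawn costs and utilities. Out-of-range
draws (e.g. an effect hazard ratio above 1) are rejected and redrawn, with
the rejection count reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .intervention import ConsumptionMix, WGFEffect
from .parameters import AGE_BANDS, FEMALE, MALE, SEXES, EconomicInputs, MortalityHRs, UtilityInputs
from .pipeline import ModelBundle, evaluate_scenarios
from .survival import WeibullFit

logger = logging.getLogger("grainmod")

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class DistributionError(ValueError):
    pass


@dataclass(frozen=True)
class DistributionSpec:
    """A PSA sampling distribution with its moment parameterization."""

    kind: str  # gamma | beta | lognormal
    mean: float
    se: float
    params: dict = field(default_factory=dict)

    def sample(self, rng: np.random.Generator, size=None):
        if self.se == 0.0:
            return self.mean if size is None else np.full(size, self.mean)
        if self.kind == "gamma":
            return rng.gamma(self.params["shape"], self.params["scale"], size=size)
        if self.kind == "beta":
            return rng.beta(self.params["alpha"], self.params["beta"], size=size)
        if self.kind == "lognormal":
            return rng.lognormal(self.params["log_mean"], self.params["log_sd"], size=size)
        raise DistributionError(f"unknown distribution kind {self.kind!r}")


def se_from_pm25(mean: float) -> float:
    """SE implied by a +/-25% variation interpreted as a 95% CI half-width."""
    if mean < 0:
        raise DistributionError("mean must be non-negative")
    return 0.25 * mean / Z95


def gamma_from_moments(mean: float, se: float) -> DistributionSpec:
    """Gamma with the given mean and SE: shape = (mean/se)^2, scale = se^2/mean."""
    if mean <= 0 or se <= 0:
        raise DistributionError("gamma moments must be positive")
    return DistributionSpec("gamma", mean, se,
                            {"shape": (mean / se) ** 2, "scale": se ** 2 / mean})


def beta_from_moments(mean: float, se: float) -> DistributionSpec:
    """Beta with the given mean and SE by the method of moments."""
    if not 0.0 < mean < 1.0:
        raise DistributionError("beta mean must lie in (0, 1)")
    if se <= 0:
        raise DistributionError("beta SE must be positive")
    if se ** 2 >= mean * (1.0 - mean):
        raise DistributionError("variance too large for a beta distribution")
    nu = mean * (1.0 - mean) / se ** 2 - 1.0
    return DistributionSpec("beta", mean, se,
                            {"alpha": mean * nu, "beta": (1.0 - mean) * nu})


def lognormal_from_moments(hr: float, se: float) -> DistributionSpec:
    """Lognormal for a hazard ratio from its natural-scale (mean, SE);
    delta method: log-mean ln(hr), log-sd se/hr."""
    if hr <= 0 or se < 0:
        raise DistributionError("hazard ratio must be positive, SE non-negative")
    return DistributionSpec("lognormal", hr, se,
                            {"log_mean": math.log(hr), "log_sd": se / hr})


def lognormal_from_hr_ci(hr: float, ci_low: float, ci_high: float) -> DistributionSpec:
    """Lognormal for a hazard ratio from its 95% CI: the natural-scale SE is
    the CI width over 2 x 1.96."""
    if not 0.0 < ci_low <= hr <= ci_high:
        raise DistributionError("require 0 < ci_low <= hr <= ci_high")
    se = (ci_high - ci_low) / (2.0 * Z95)
    return lognormal_from_moments(hr, se)


def sample_weibull_coefficients(fit: WeibullFit,
                                rng: np.random.Generator | int) -> tuple[float, dict[str, float]]:
    """One multivariate-normal draw of (shape, coefficients) around the fit.

    Uses a Cholesky factor of the fitted covariance, with an escalating
    diagonal jitter fallback for borderline-PSD matrices; an all-zero
    covariance returns the point estimates. Returns the drawn shape and a
    named coefficient dict in the fit's design order.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    cov = np.asarray(fit.covariance, dtype=float)
    names = fit.param_names
    mean = np.array(([math.log(fit.shape)] if not fit.shape_fixed else [])
                    + list(fit.coefficients.values()))
    if not np.any(cov):
        theta = mean
    else:
        L = None
        scale = np.mean(np.diag(cov)) or 1.0
        for jitter in (0.0, 1e-12, 1e-10, 1e-8, 1e-6):
            try:
                L = np.linalg.cholesky(cov + jitter * scale * np.eye(len(cov)))
                break
            except np.linalg.LinAlgError:
                continue
        if L is None:
            raise DistributionError("fit covariance is not positive semidefinite")
        theta = mean + L @ rng.standard_normal(len(mean))
    if fit.shape_fixed:
        shape = fit.shape
        beta = theta
    else:
        shape = float(np.exp(theta[0]))
        beta = theta[1:]
    coef_names = [n for n in names if n != "log_shape"]
    return shape, dict(zip(coef_names, beta.tolist()))


# -- default PSA specification ------------------------------------------------

def build_psa_specs(econ: EconomicInputs, util: UtilityInputs,
                    hrs: MortalityHRs, effect: WGFEffect) -> dict[str, DistributionSpec]:
    """The default joint PSA parameter set keyed by parameter name."""
    specs: dict[str, DistributionSpec] = {
        "cost_t2d_secondary": gamma_from_moments(
            econ.cost_t2d_secondary, se_from_pm25(econ.cost_t2d_secondary)),
        "cost_complications": gamma_from_moments(
            econ.cost_complications, se_from_pm25(econ.cost_complications)),
        "cost_productivity": gamma_from_moments(
            econ.cost_productivity, se_from_pm25(econ.cost_productivity)),
        "cost_medication": gamma_from_moments(
            econ.cost_medication, se_from_pm25(econ.cost_medication)),
        "cost_primary_male": gamma_from_moments(econ.cost_primary_male,
                                                econ.se_primary_male),
        "cost_primary_female": gamma_from_moments(econ.cost_primary_female,
                                                  econ.se_primary_female),
        "disutility_t2d": beta_from_moments(util.disutility_t2d,
                                            util.se_disutility_t2d),
        "disutility_complications": beta_from_moments(
            util.disutility_complications, se_from_pm25(util.disutility_complications)),
        # published SEs for the sex-specific diabetes mortality HRs
        "hr_mort_t2d_female": lognormal_from_moments(hrs.hr_t2d_female, hrs.se_t2d_female),
        "hr_mort_t2d_male": lognormal_from_moments(hrs.hr_t2d_male, hrs.se_t2d_male),
        "hr_mort_t2dc": lognormal_from_hr_ci(hrs.hr_t2dc, *hrs.ci_t2dc),
        "hr_wgf_one": lognormal_from_hr_ci(effect.hr_one, *effect.ci_one),
        "hr_wgf_two_plus": lognormal_from_hr_ci(effect.hr_two_plus, *effect.ci_two_plus),
    }
    for sex in SEXES:
        for b in range(len(AGE_BANDS)):
            mean, se = util.baseline[sex][b]
            specs[f"utility_{sex}_band{b}"] = beta_from_moments(mean, se)
    return specs


def _draw_is_valid(draw: dict[str, float]) -> bool:
    for name, value in draw.items():
        if name.startswith("cost_") and value < 0:
            return False
        if (name.startswith("utility_") or name.startswith("disutility_")) \
                and not 0.0 <= value <= 1.0:
            return False
        if name.startswith("hr_") and value <= 0:
            return False
        if name.startswith("hr_wgf_") and value >= 1.0:
            return False
    return True


def _bundle_from_draw(bundle: ModelBundle, draw: dict[str, float],
                      inc_draw: tuple[float, dict], comp_draw: tuple[float, dict]) -> ModelBundle:
    econ = replace(
        bundle.econ,
        cost_t2d_secondary=draw["cost_t2d_secondary"],
        cost_complications=draw["cost_complications"],
        cost_productivity=draw["cost_productivity"],
        cost_medication=draw["cost_medication"],
        cost_primary_male=draw["cost_primary_male"],
        cost_primary_female=draw["cost_primary_female"],
    )
    baseline = {
        sex: tuple((draw[f"utility_{sex}_band{b}"], bundle.util.baseline[sex][b][1])
                   for b in range(len(AGE_BANDS)))
        for sex in SEXES
    }
    util = replace(bundle.util, baseline=baseline,
                   disutility_t2d=draw["disutility_t2d"],
                   disutility_complications=draw["disutility_complications"])
    hrs = replace(bundle.hrs,
                  hr_t2d_female=draw["hr_mort_t2d_female"],
                  hr_t2d_male=draw["hr_mort_t2d_male"],
                  hr_t2dc=draw["hr_mort_t2dc"])
    hr1, hr2 = draw["hr_wgf_one"], draw["hr_wgf_two_plus"]
    effect = WGFEffect(hr_one=hr1, hr_two_plus=hr2,
                       ci_one=(hr1, hr1), ci_two_plus=(hr2, hr2))
    inc_fit = replace(bundle.incidence_fit, shape=inc_draw[0], coefficients=inc_draw[1])
    comp_fit = replace(bundle.complication_fit, shape=comp_draw[0], coefficients=comp_draw[1])
    return bundle.with_updates(econ=econ, util=util, hrs=hrs, effect=effect,
                               incidence_fit=inc_fit, complication_fit=comp_fit)


@dataclass
class PSAResult:
    """Per-iteration scenario outcomes and their summaries."""

    draws: pd.DataFrame       # iteration x scenario x horizon outcomes
    parameters: pd.DataFrame  # iteration x sampled parameter values
    summary: pd.DataFrame     # mean and 2.5/97.5 percentiles per cell
    n_rejected: int


def run_psa(bundle: ModelBundle,
            scenario_names: Sequence[str] = ("I", "II", "III"),
            horizons: Sequence[int] = (10, 20, 30),
            n_iterations: int = 1000,
            seed: int = 0,
            specs: dict[str, DistributionSpec] | None = None) -> PSAResult:
    """Probabilistic sensitivity analysis with joint parameter draws.

    Per iteration: draw every PSA parameter, draw correlated survival
    coefficients, re-calibrate, evaluate baseline and scenarios
    deterministically, and record discounted cost differences (with and
    without productivity losses) and QALY gains per scenario and horizon.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be at least 1")
    rng = np.random.default_rng(seed)
    specs = specs if specs is not None else build_psa_specs(
        bundle.econ, bundle.util, bundle.hrs, bundle.effect)

    rows, param_rows = [], []
    n_rejected = 0
    for it in range(n_iterations):
        while True:
            draw = {name: float(spec.sample(rng)) for name, spec in specs.items()}
            if _draw_is_valid(draw):
                break
            n_rejected += 1
        inc_draw = sample_weibull_coefficients(bundle.incidence_fit, rng)
        comp_draw = sample_weibull_coefficients(bundle.complication_fit, rng)
        drawn_bundle = _bundle_from_draw(bundle, draw, inc_draw, comp_draw)
        result = evaluate_scenarios(drawn_bundle, tuple(scenario_names),
                                    tuple(horizons))
        param_rows.append({"iteration": it, **draw})
        for name, summary in result.summaries.items():
            for h in horizons:
                with_p = summary.table.loc[(h, "total", True)]
                without_p = summary.table.loc[(h, "total", False)]
                rows.append({
                    "iteration": it, "scenario": name, "horizon": h,
                    "savings_with_productivity": with_p["savings"],
                    "savings_without_productivity": without_p["savings"],
                    "qaly_gain": with_p["qaly_gain"],
                })
    if n_rejected:
        logger.info("PSA rejected and redrew %d invalid parameter sets", n_rejected)

    draws = pd.DataFrame(rows)
    outcomes = ["savings_with_productivity", "savings_without_productivity", "qaly_gain"]
    summary = (draws.groupby(["scenario", "horizon"])[outcomes]
               .agg(["mean", lambda x: np.percentile(x, 2.5),
                     lambda x: np.percentile(x, 97.5)]))
    summary.columns = [f"{o}_{s}" for o, s in zip(
        [c[0] for c in summary.columns],
        ["mean", "p2.5", "p97.5"] * len(outcomes))]
    return PSAResult(draws=draws, parameters=pd.DataFrame(param_rows),
                     summary=summary.reset_index(), n_rejected=n_rejected)


def probability_of_savings(draws: pd.DataFrame,
                           column: str = "savings_with_productivity",
                           thresholds: np.ndarray | None = None) -> pd.DataFrame:
    """Empirical P(savings >= s) per scenario/horizon over a threshold grid.

    The curve is the complement of the empirical CDF of the PSA draws, hence
    non-increasing in the threshold.
    """
    if thresholds is None:
        top = max(draws[column].max(), 0.0)
        thresholds = np.linspace(0.0, top, 101)
    rows = []
    for (scenario, horizon), group in draws.groupby(["scenario", "horizon"]):
        values = group[column].to_numpy()
        for s in thresholds:
            rows.append({"scenario": scenario, "horizon": horizon,
                         "threshold": float(s),
                         "probability": float(np.mean(values >= s))})
    return pd.DataFrame(rows)


# -- one-way sensitivity analysis ---------------------------------------------

@dataclass(frozen=True)
class OWSAParameter:
    """A tornado bar: low/high values and how they modify the model bundle.

    ``setter(bundle, value)`` returns (modified bundle, discount-rate
    override or None).
    """

    name: str
    low: object
    high: object
    setter: Callable[[ModelBundle, object], tuple[ModelBundle, float | None]]


def _econ_setter(field_name: str):
    def setter(bundle: ModelBundle, value):
        return bundle.with_updates(econ=replace(bundle.econ, **{field_name: value})), None
    return setter


def _util_setter(field_name: str):
    def setter(bundle: ModelBundle, value):
        return bundle.with_updates(util=replace(bundle.util, **{field_name: value})), None
    return setter


def _hr_setter(field_name: str):
    def setter(bundle: ModelBundle, value):
        return bundle.with_updates(hrs=replace(bundle.hrs, **{field_name: value})), None
    return setter


def _effectiveness_setter(bundle: ModelBundle, value):
    # perturb the intervention arm only; the comparator stays at the
    # observed current-situation point estimates
    hr1, hr2 = value
    effect = WGFEffect(hr_one=hr1, hr_two_plus=hr2,
                       ci_one=(hr1, hr1), ci_two_plus=(hr2, hr2))
    return bundle.with_updates(effect=effect,
                               baseline_effect=bundle.baseline_effect or bundle.effect), None


def _discount_setter(bundle: ModelBundle, value):
    return bundle, float(value)


def default_owsa_parameters(econ: EconomicInputs, util: UtilityInputs,
                            hrs: MortalityHRs, effect: WGFEffect) -> list[OWSAParameter]:
    """Base one-way analysis grid: costs at +/-25%, disutilities at their
    95% bounds (or +/-25%), mortality and effect HRs at their CI bounds, and
    the discount rate over 0-5%."""
    pm25 = lambda v: (0.75 * v, 1.25 * v)
    d_lo = max(0.0, util.disutility_t2d - Z95 * util.se_disutility_t2d)
    d_hi = util.disutility_t2d + Z95 * util.se_disutility_t2d
    params = [
        OWSAParameter("effectiveness", (effect.ci_one[0], effect.ci_two_plus[0]),
                      (effect.ci_one[1], effect.ci_two_plus[1]), _effectiveness_setter),
        OWSAParameter("discount_rate", 0.0, 0.05, _discount_setter),
        OWSAParameter("cost_t2d_secondary", *pm25(econ.cost_t2d_secondary),
                      _econ_setter("cost_t2d_secondary")),
        OWSAParameter("cost_complications", *pm25(econ.cost_complications),
                      _econ_setter("cost_complications")),
        OWSAParameter("cost_productivity", *pm25(econ.cost_productivity),
                      _econ_setter("cost_productivity")),
        OWSAParameter("cost_medication", *pm25(econ.cost_medication),
                      _econ_setter("cost_medication")),
        OWSAParameter("cost_primary_male", *pm25(econ.cost_primary_male),
                      _econ_setter("cost_primary_male")),
        OWSAParameter("cost_primary_female", *pm25(econ.cost_primary_female),
                      _econ_setter("cost_primary_female")),
        OWSAParameter("disutility_t2d", d_lo, d_hi, _util_setter("disutility_t2d")),
        OWSAParameter("disutility_complications", *pm25(util.disutility_complications),
                      _util_setter("disutility_complications")),
        OWSAParameter("hr_mort_t2d_female", hrs.ci_t2d_female[0], hrs.ci_t2d_female[1],
                      _hr_setter("hr_t2d_female")),
        OWSAParameter("hr_mort_t2d_male", hrs.ci_t2d_male[0], hrs.ci_t2d_male[1],
                      _hr_setter("hr_t2d_male")),
        OWSAParameter("hr_mort_t2dc", hrs.ci_t2dc[0], hrs.ci_t2dc[1],
                      _hr_setter("hr_t2dc")),
    ]
    return params


def run_owsa(bundle: ModelBundle, scenario: str = "I", horizon: int = 20,
             parameters: Sequence[OWSAParameter] | None = None) -> pd.DataFrame:
    """One-way sensitivity analysis: re-run the model with each parameter at
    its low and high bound (all else at base) and tabulate the induced range
    of total savings (with productivity) and QALY gains, sorted tornado-style
    by savings range."""
    if parameters is None:
        parameters = default_owsa_parameters(bundle.econ, bundle.util,
                                             bundle.hrs, bundle.effect)

    def outcome(b: ModelBundle, rate: float | None) -> tuple[float, float]:
        result = evaluate_scenarios(b, (scenario,), (horizon,), discount_rate=rate)
        row = result.summaries[scenario].table.loc[(horizon, "total", True)]
        return float(row["savings"]), float(row["qaly_gain"])

    base_savings, base_qaly = outcome(bundle, None)
    rows = []
    for p in parameters:
        lo_bundle, lo_rate = p.setter(bundle, p.low)
        hi_bundle, hi_rate = p.setter(bundle, p.high)
        s_lo, q_lo = outcome(lo_bundle, lo_rate)
        s_hi, q_hi = outcome(hi_bundle, hi_rate)
        rows.append({
            "parameter": p.name, "low": p.low, "high": p.high,
            "savings_low": s_lo, "savings_high": s_hi,
            "savings_range": abs(s_hi - s_lo),
            "qaly_low": q_lo, "qaly_high": q_hi,
            "qaly_range": abs(q_hi - q_lo),
            "savings_base": base_savings, "qaly_base": base_qaly,
        })
    return (pd.DataFrame(rows)
            .sort_values("savings_range", ascending=False)
            .reset_index(drop=True))
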