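"""Default model parameters: excess-mortality hazard ratios, unit costs and utilities.

All monetary values are per-person annual euros at the 2019 price level for the
Finnish adult population; utilities are EQ-5D-3L index values by age band and
sex. The standard errors stored alongside the point estimates feed the
probabilistic sensitivity analysis (see :mod:`grainmod.uncertainty`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

MALE = "male"
FEMALE = "female"
SEXES = (MALE, FEMALE)

#: EQ-5D-3L age bands on attained age: 30-44, 45-54, 55-64, 65+.
AGE_BANDS = ((30, 44), (45, 54), (55, 64), (65, 200))


def age_band_index(age: float) -> int:
    """Index of the utility age band containing ``age`` (ages below 30 use the first band)."""
    for i, (lo, hi) in enumerate(AGE_BANDS):
        if age <= hi:
            return i
    return len(AGE_BANDS) - 1


@dataclass(frozen=True)
class MortalityHRs:
    """Excess all-cause mortality in the diabetic states, as hazard ratios on
    the annual death probability of the general population.

    The diabetes HR is sex-specific; the complicated-diabetes HR is common.
    The ``se_*``/``ci_t2dc`` fields carry the published uncertainty used by
    the PSA (lognormal sampling).
    """

    hr_t2d_female: float = 2.47
    hr_t2d_male: float = 1.93
    hr_t2dc: float = 2.36
    se_t2d_female: float = 0.04
    se_t2d_male: float = 0.05
    ci_t2d_female: tuple[float, float] = (2.42, 3.06)
    ci_t2d_male: tuple[float, float] = (1.79, 2.07)
    ci_t2dc: tuple[float, float] = (1.70, 3.29)

    def __post_init__(self) -> None:
        for v in (self.hr_t2d_female, self.hr_t2d_male, self.hr_t2dc):
            if not v > 0:
                raise ValueError("mortality hazard ratios must be positive")

    def hr_t2d(self, sex: str) -> float:
        if sex == FEMALE:
            return self.hr_t2d_female
        if sex == MALE:
            return self.hr_t2d_male
        raise ValueError(f"unknown sex {sex!r}")


@dataclass(frozen=True)
class EconomicInputs:
    """Annual per-person T2D-attributable costs (euros/year) and discounting.

    ``cost_t2d_secondary`` is additional secondary health care, ``cost_complications``
    is an additional recurring annual cost while in the complicated state,
    ``cost_productivity`` covers sick leave / premature retirement / premature
    death and is applied only below ``retirement_age``. Primary-care costs are
    sex-specific; medication is ATC A10.
    """

    cost_t2d_secondary: float = 3315.0
    cost_complications: float = 4401.0
    cost_productivity: float = 7632.0
    cost_primary_male: float = 562.0
    cost_primary_female: float = 542.0
    cost_medication: float = 584.0
    retirement_age: float = 65.0
    discount_rate: float = 0.03
    # PSA standard errors where a registry-based SE is published (primary care);
    # the remaining costs use the +/-25% convention (see uncertainty.se_from_pm25).
    se_primary_male: float = 9.53
    se_primary_female: float = 9.82

    def __post_init__(self) -> None:
        for name in ("cost_t2d_secondary", "cost_complications", "cost_productivity",
                     "cost_primary_male", "cost_primary_female", "cost_medication"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.discount_rate <= 0.2:
            raise ValueError("discount_rate must lie in [0, 0.2]")

    def cost_primary(self, sex: str) -> float:
        return self.cost_primary_male if sex == MALE else self.cost_primary_female


def _default_baseline_utilities() -> dict[str, tuple[tuple[float, float], ...]]:
    # (mean, SE) per age band 30-44, 45-54, 55-64, 65+
    return {
        FEMALE: ((0.906, 0.003), (0.865, 0.005), (0.810, 0.006), (0.770, 0.008)),
        MALE: ((0.917, 0.003), (0.876, 0.005), (0.821, 0.006), (0.781, 0.008)),
    }


@dataclass(frozen=True)
class UtilityInputs:
    """EQ-5D-3L baseline utilities by sex and age band, plus disease disutilities.

    ``complication_disutility_mode`` controls whether the complication
    disutility stacks on top of the plain-T2D disutility (``"additive"``,
    default) or replaces it (``"replace"``). State utilities are floored at 0.
    """

    baseline: Mapping[str, tuple[tuple[float, float], ...]] = field(
        default_factory=_default_baseline_utilities
    )
    disutility_t2d: float = 0.041
    se_disutility_t2d: float = 0.012
    disutility_complications: float = 0.119
    complication_disutility_mode: str = "additive"

    def __post_init__(self) -> None:
        for sex, bands in self.baseline.items():
            if len(bands) != len(AGE_BANDS):
                raise ValueError(f"need {len(AGE_BANDS)} utility bands for {sex}")
            for mean, se in bands:
                if not 0.0 <= mean <= 1.0:
                    raise ValueError("baseline utilities must lie in [0, 1]")
                if se < 0:
                    raise ValueError("utility SEs must be non-negative")
        if self.disutility_t2d < 0 or self.disutility_complications < 0:
            raise ValueError("disutilities must be non-negative")
        if self.complication_disutility_mode not in ("additive", "replace"):
            raise ValueError("complication_disutility_mode must be 'additive' or 'replace'")

    def baseline_utility(self, age: float, sex: str) -> float:
        return self.baseline[sex][age_band_index(age)][0]

    def baseline_se(self, age: float, sex: str) -> float:
        return self.baseline[sex][age_band_index(age)][1]


def save_parameters(path: str | Path, econ: EconomicInputs | None = None,
                    util: UtilityInputs | None = None,
                    hrs: MortalityHRs | None = None,
                    extra: dict | None = None) -> None:
    """Write the economic/utility/mortality parameter set as a YAML file."""
    econ = econ or EconomicInputs()
    util = util or UtilityInputs()
    hrs = hrs or MortalityHRs()
    payload = {
        "economics": asdict(econ),
        "utilities": {
            "baseline": {sex: [list(pair) for pair in bands]
                         for sex, bands in util.baseline.items()},
            "disutility_t2d": util.disutility_t2d,
            "se_disutility_t2d": util.se_disutility_t2d,
            "disutility_complications": util.disutility_complications,
            "complication_disutility_mode": util.complication_disutility_mode,
        },
        "mortality_hrs": {
            "hr_t2d_female": hrs.hr_t2d_female,
            "hr_t2d_male": hrs.hr_t2d_male,
            "hr_t2dc": hrs.hr_t2dc,
            "se_t2d_female": hrs.se_t2d_female,
            "se_t2d_male": hrs.se_t2d_male,
            "ci_t2d_female": list(hrs.ci_t2d_female),
            "ci_t2d_male": list(hrs.ci_t2d_male),
            "ci_t2dc": list(hrs.ci_t2dc),
        },
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")


def load_parameters(path: str | Path) -> tuple[EconomicInputs, UtilityInputs, MortalityHRs, dict]:
    """Read a parameter YAML written by :func:`save_parameters`.

    Returns (economics, utilities, mortality HRs, any extra sections).
    """
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    econ = EconomicInputs(**payload["economics"])
    u = payload["utilities"]
    util = UtilityInputs(
        baseline={sex: tuple(tuple(pair) for pair in bands)
                  for sex, bands in u["baseline"].items()},
        disutility_t2d=u["disutility_t2d"],
        se_disutility_t2d=u["se_disutility_t2d"],
        disutility_complications=u["disutility_complications"],
        complication_disutility_mode=u.get("complication_disutility_mode", "additive"),
    )
    h = payload["mortality_hrs"]
    hrs = MortalityHRs(
        hr_t2d_female=h["hr_t2d_female"], hr_t2d_male=h["hr_t2d_male"],
        hr_t2dc=h["hr_t2dc"], se_t2d_female=h["se_t2d_female"],
        se_t2d_male=h["se_t2d_male"],
        ci_t2d_female=tuple(h.get("ci_t2d_female", (2.42, 3.06))),
        ci_t2d_male=tuple(h.get("ci_t2d_male", (1.79, 2.07))),
        ci_t2dc=tuple(h["ci_t2dc"]),
    )
    extra = {k: v for k, v in payload.items()
             if k not in ("economics", "utilities", "mortality_hrs")}
    return econ, util, hrs, extra
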