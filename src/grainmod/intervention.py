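"""Whole-grain-food (WGF) consumption scenarios and their weighted hazard
ratios on T2D incidence.

The calibrated baseline incidence represents adults with no daily WGF
consumption, so population incidence under any consumption mix is obtained by
a consumption-weighted hazard ratio: non-users contribute HR 1, one-serving
users HR 0.73 and two-plus-serving users HR 0.65 (dose-response estimates
from a meta-analysis of prospective cohorts). In the default baseline mix,
69.5% of adults use at least one WGF serving a day, all assigned to the
one-serving category — the reading under which moving existing users to two
or more servings (Scenario II) changes anything; the split is configurable.

Scenarios:
  I    move 10 percentage points of the population from non-use to daily use;
  II   move all existing one-serving users to two-plus servings;
  III  both (the newly added users also land in the two-plus category).

The full scenario effect is applied immediately and persists over the whole
horizon; the effect touches only the incidence hazard, never complication or
death hazards.
"""

from __future__ import annotations

from dataclasses import dataclass

SCENARIO_NAMES = ("baseline", "I", "II", "III", "custom")


@dataclass(frozen=True)
class ConsumptionMix:
    """Population proportions by daily WGF servings: none, one, two or more."""

    p_nonuser: float
    p_one_serving: float
    p_two_plus: float

    def __post_init__(self) -> None:
        for p in (self.p_nonuser, self.p_one_serving, self.p_two_plus):
            if not 0.0 <= p <= 1.0:
                raise ValueError("mix proportions must lie in [0, 1]")
        if abs(self.p_nonuser + self.p_one_serving + self.p_two_plus - 1.0) > 1e-12:
            raise ValueError("mix proportions must sum to 1")


#: Default baseline: 69.5% daily users, all in the one-serving category.
DEFAULT_BASELINE_MIX = ConsumptionMix(0.305, 0.695, 0.0)


@dataclass(frozen=True)
class WGFEffect:
    """Hazard ratios of daily WGF consumption on T2D incidence (vs non-use)."""

    hr_one: float = 0.73
    hr_two_plus: float = 0.65
    ci_one: tuple[float, float] = (0.72, 0.74)
    ci_two_plus: tuple[float, float] = (0.61, 0.68)

    def __post_init__(self) -> None:
        for hr, ci in ((self.hr_one, self.ci_one), (self.hr_two_plus, self.ci_two_plus)):
            if not 0.0 < hr <= 1.0:
                raise ValueError("WGF hazard ratios must lie in (0, 1]")
            if not ci[0] <= hr <= ci[1]:
                raise ValueError("CI bounds must bracket the point estimate")


@dataclass(frozen=True)
class ScenarioSpec:
    """A named consumption scenario: resulting mix plus the applied effect."""

    name: str
    mix: ConsumptionMix
    effect: WGFEffect

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(f"scenario name must be one of {SCENARIO_NAMES}")

    @property
    def weighted_hr(self) -> float:
        return weighted_hr(self.mix, self.effect)


def weighted_hr(mix: ConsumptionMix, effect: WGFEffect) -> float:
    """Consumption-weighted hazard ratio relative to an all-non-user population."""
    return (mix.p_nonuser
            + mix.p_one_serving * effect.hr_one
            + mix.p_two_plus * effect.hr_two_plus)


def build_scenario(name: str, baseline_mix: ConsumptionMix = DEFAULT_BASELINE_MIX,
                   effect: WGFEffect | None = None,
                   uptake_increase: float = 0.10,
                   new_users_to_two_plus_in_iii: bool = True) -> ScenarioSpec:
    """Derive a scenario's consumption mix from the baseline mix.

    Scenario I moves ``uptake_increase`` mass from non-users into the
    one-serving pool; Scenario II moves all one-serving mass to two-plus;
    Scenario III applies I then II (by default the newly recruited users also
    end up in the two-plus category).
    """
    effect = effect or WGFEffect()
    if name == "baseline":
        return ScenarioSpec("baseline", baseline_mix, effect)
    if name in ("I", "III") and baseline_mix.p_nonuser < uptake_increase:
        raise ValueError(
            f"cannot move {uptake_increase:.0%} of the population out of a "
            f"non-user pool of {baseline_mix.p_nonuser:.1%}")
    if name == "I":
        mix = ConsumptionMix(baseline_mix.p_nonuser - uptake_increase,
                             baseline_mix.p_one_serving + uptake_increase,
                             baseline_mix.p_two_plus)
    elif name == "II":
        mix = ConsumptionMix(baseline_mix.p_nonuser, 0.0,
                             baseline_mix.p_one_serving + baseline_mix.p_two_plus)
    elif name == "III":
        if new_users_to_two_plus_in_iii:
            mix = ConsumptionMix(
                baseline_mix.p_nonuser - uptake_increase, 0.0,
                baseline_mix.p_one_serving + baseline_mix.p_two_plus + uptake_increase)
        else:
            mix = ConsumptionMix(
                baseline_mix.p_nonuser - uptake_increase, uptake_increase,
                baseline_mix.p_one_serving + baseline_mix.p_two_plus)
    else:
        raise ValueError(f"unknown scenario {name!r}; use build_custom_scenario for custom mixes")
    return ScenarioSpec(name, mix, effect)


def build_custom_scenario(mix: ConsumptionMix, effect: WGFEffect | None = None) -> ScenarioSpec:
    return ScenarioSpec("custom", mix, effect or WGFEffect())


def scenario_hazard_multiplier(scenario: ScenarioSpec, calibrated_multiplier: float) -> float:
    """Total multiplier on the No-T2D -> T2D cumulative hazard: the
    calibration multiplier (pinning the non-user baseline) times the
    scenario's consumption-weighted hazard ratio."""
    if not calibrated_multiplier > 0:
        raise ValueError("calibrated_multiplier must be positive")
    return calibrated_multiplier * scenario.weighted_hr
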