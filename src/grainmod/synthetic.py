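"""Synthetic stand-ins for the registry inputs: cohort structure,
right-censored time-to-event datasets and a national-style life table.

Every generator carries known ground-truth parameters so the downstream
fitting, calibration and economic stages are testable end-to-end without any
restricted-access data. Defaults emulate the study conditions: a Finnish
adult cohort aged 30-79 split by sex and five FINDRISC risk categories,
10-year follow-up for T2D incidence (cohort of 9512), 9-year follow-up for
complications after diagnosis (cohort of 1151), and a Gompertz-Makeham life
table. All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import LifeTable
from .parameters import FEMALE, MALE, SEXES


class ConfigurationError(ValueError):
    pass


#: 5-year age bands spanning 30-79 and their integer midpoints.
AGE_BAND_EDGES = tuple((lo, lo + 4) for lo in range(30, 80, 5))
AGE_BAND_MIDPOINTS = tuple(lo + 2 for lo, _ in AGE_BAND_EDGES)


@dataclass(frozen=True)
class WeibullTruth:
    """Ground-truth Weibull AFT process: shape and log-time coefficients."""

    shape: float
    coefficients: dict[str, float]

    def __post_init__(self) -> None:
        if not self.shape > 0:
            raise ConfigurationError("Weibull shape must be positive")
        if "intercept" not in self.coefficients:
            raise ConfigurationError("coefficients must include an intercept")

    def scale(self, age: np.ndarray, male: np.ndarray,
              findrisc: np.ndarray | None = None) -> np.ndarray:
        c = self.coefficients
        lp = c["intercept"] + c.get("age", 0.0) * age + c.get("sex_male", 0.0) * male
        if findrisc is not None:
            for cat in (2, 3, 4, 5):
                lp = lp + c.get(f"findrisc_{cat}", 0.0) * (findrisc == cat)
        return np.exp(lp)


def _default_incidence_truth() -> WeibullTruth:
    # Chosen so the uncalibrated population 10-year incidence sits near 10%,
    # leaving the calibration step a non-trivial downward adjustment.
    return WeibullTruth(shape=1.4, coefficients={
        "intercept": 5.1, "age": -0.012, "sex_male": -0.15,
        "findrisc_2": -0.35, "findrisc_3": -0.70,
        "findrisc_4": -1.05, "findrisc_5": -1.45,
    })


def _default_complication_truth() -> WeibullTruth:
    return WeibullTruth(shape=1.15, coefficients={
        "intercept": 3.6, "age": -0.008, "sex_male": -0.12,
    })


def _default_findrisc_probs() -> dict[str, np.ndarray]:
    """Category probabilities per age band, drifting toward higher risk with age."""
    young = np.array([0.40, 0.30, 0.17, 0.09, 0.04])
    old = np.array([0.20, 0.28, 0.25, 0.17, 0.10])
    n = len(AGE_BAND_EDGES)
    w = np.linspace(0.0, 1.0, n)[:, None]
    bands = (1 - w) * young[None, :] + w * old[None, :]
    return {sex: bands.copy() for sex in SEXES}


def _default_age_band_weights() -> np.ndarray:
    # mild downward slope with age; mean baseline age ~53, matching the
    # population structure the model targets
    w = 1.0 - 0.03 * np.arange(len(AGE_BAND_EDGES))
    return w / w.sum()


@dataclass(frozen=True)
class GompertzMakeham:
    """q(age) = makeham + b * exp(c * (age - 30)), clipped to (0, 1]."""

    makeham: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if min(self.makeham, self.b, self.c) <= 0:
            raise ConfigurationError("life-table baseline parameters must be positive")

    def q(self, ages: np.ndarray) -> np.ndarray:
        return np.minimum(1.0, self.makeham + self.b * np.exp(self.c * (ages - 30.0)))


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground truth and sampling layout for every synthetic input.

    ``population`` and ``t2d_prevalence`` define the cohort totals per sex;
    ``n_incidence``/``n_complication`` size the two individual-level survival
    datasets; ``true_weibull`` holds one :class:`WeibullTruth` per event
    process; ``censoring_year`` is the administrative follow-up cut-off.
    """

    seed: int = 2017
    age_range: tuple[int, int] = (30, 79)
    population: dict[str, float] = field(
        default_factory=lambda: {MALE: 1_673_290, FEMALE: 1_702_260})
    t2d_prevalence: dict[str, float] = field(
        default_factory=lambda: {MALE: 0.146, FEMALE: 0.094})
    sex_split: dict[str, float] = field(
        default_factory=lambda: {MALE: 0.5, FEMALE: 0.5})
    findrisc_probs: dict[str, np.ndarray] = field(default_factory=_default_findrisc_probs)
    age_band_weights: np.ndarray = field(default_factory=_default_age_band_weights)
    n_incidence: int = 9512
    n_complication: int = 1151
    true_weibull: dict[str, WeibullTruth] = field(default_factory=lambda: {
        "incidence": _default_incidence_truth(),
        "complication": _default_complication_truth(),
    })
    censoring_year: dict[str, float] = field(
        default_factory=lambda: {"incidence": 10.0, "complication": 9.0})
    life_table_params: dict[str, GompertzMakeham] = field(default_factory=lambda: {
        MALE: GompertzMakeham(makeham=6e-4, b=4.5e-4, c=0.092),
        FEMALE: GompertzMakeham(makeham=3e-4, b=2.5e-4, c=0.096),
    })
    life_table_max_age: int = 110

    def __post_init__(self) -> None:
        lo, hi = self.age_range
        if not (30 <= lo < hi <= 79):
            raise ConfigurationError("age_range must lie within [30, 79]")
        if abs(sum(self.sex_split.values()) - 1.0) > 1e-12:
            raise ConfigurationError("sex_split must sum to 1")
        for sex, probs in self.findrisc_probs.items():
            probs = np.asarray(probs, dtype=float)
            if probs.ndim == 1:
                probs = np.tile(probs, (len(AGE_BAND_EDGES), 1))
            if probs.shape != (len(AGE_BAND_EDGES), 5):
                raise ConfigurationError("findrisc_probs needs 5 probabilities per age band")
            if np.any(probs < 0) or np.any(probs > 1):
                raise ConfigurationError("findrisc_probs must lie in [0, 1]")
            if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-12):
                raise ConfigurationError("findrisc_probs must sum to 1 per band")
            object.__setattr__(self, "findrisc_probs",
                               {**self.findrisc_probs, sex: probs})
        w = np.asarray(self.age_band_weights, dtype=float)
        if w.shape != (len(AGE_BAND_EDGES),) or np.any(w < 0):
            raise ConfigurationError("age_band_weights must be non-negative, one per band")
        object.__setattr__(self, "age_band_weights", w / w.sum())
        for process, c in self.censoring_year.items():
            if c <= 0:
                raise ConfigurationError("censoring_year must be positive")
        for prev in self.t2d_prevalence.values():
            if not 0.0 <= prev < 1.0:
                raise ConfigurationError("prevalence must lie in [0, 1)")


def largest_remainder_round(values: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative reals to integers summing exactly to ``total``
    (Hamilton / largest-remainder apportionment)."""
    values = np.asarray(values, dtype=float)
    if values.sum() <= 0:
        out = np.zeros(len(values), dtype=int)
        out[0] = total
        return out
    scaled = values / values.sum() * total
    floors = np.floor(scaled).astype(int)
    remainder = total - floors.sum()
    order = np.argsort(-(scaled - floors), kind="stable")
    floors[order[:remainder]] += 1
    return floors


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Build the baseline cohort strata: (age, sex, FINDRISC category, count).

    Per-sex totals are the configured population scaled by (1 - T2D
    prevalence) and rounded; within a sex, counts are apportioned across
    age-band x FINDRISC cells by largest-remainder rounding so the totals are
    conserved exactly. Every stratum starts fully in the No-T2D state.
    """
    rows = []
    for sex in SEXES:
        pop = config.population.get(sex, 0.0)
        if pop <= 0 or config.sex_split.get(sex, 0.0) == 0.0:
            continue
        total = int(round(pop * (1.0 - config.t2d_prevalence.get(sex, 0.0))))
        probs = config.findrisc_probs[sex]
        weights = (config.age_band_weights[:, None] * probs).ravel()
        counts = largest_remainder_round(weights, total)
        i = 0
        for b, mid in enumerate(AGE_BAND_MIDPOINTS):
            for cat in (1, 2, 3, 4, 5):
                rows.append({"age": mid, "sex": sex, "findrisc_category": cat,
                             "count": int(counts[i])})
                i += 1
    frame = pd.DataFrame(rows)
    if frame.empty:
        raise ConfigurationError("cohort is empty: check population counts")
    return frame


def generate_survival_dataset(config: SyntheticConfig, process: str) -> pd.DataFrame:
    """Draw right-censored event records from the configured Weibull truth.

    ``process`` is ``"incidence"`` (covariates: age, sex, FINDRISC) or
    ``"complication"`` (age, sex). Times follow T = lambda(x) * E**(1/k)
    with E ~ Exp(1); administrative censoring applies at the configured
    follow-up cut-off.
    """
    if process not in config.true_weibull:
        raise ConfigurationError(f"no ground-truth Weibull for process {process!r}")
    truth = config.true_weibull[process]
    n = config.n_incidence if process == "incidence" else config.n_complication
    cens = config.censoring_year[process]
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.seed, 1 if process == "incidence" else 2]))

    lo, hi = config.age_range
    age = rng.uniform(lo, hi + 1.0, size=n)
    p_male = config.sex_split.get(MALE, 0.0)
    male = (rng.random(n) < p_male).astype(float)
    sex = np.where(male == 1.0, MALE, FEMALE)

    findrisc = None
    records = {"age": age, "sex": sex}
    if process == "incidence":
        findrisc = np.empty(n, dtype=int)
        band = np.clip(((age - 30.0) // 5).astype(int), 0, len(AGE_BAND_EDGES) - 1)
        u = rng.random(n)
        for s in SEXES:
            probs = config.findrisc_probs[s]
            cum = np.cumsum(probs, axis=1)
            mask = sex == s
            if mask.any():
                findrisc[mask] = 1 + (u[mask, None] > cum[band[mask], :]).sum(axis=1)
        records["findrisc_category"] = findrisc

    lam = truth.scale(age, male, findrisc)
    t_event = lam * rng.exponential(1.0, size=n) ** (1.0 / truth.shape)
    time = np.minimum(t_event, cens)
    event = (t_event <= cens).astype(int)
    # event times of exactly zero cannot occur (continuous draw), but clip
    # against denormal underflow to keep log-likelihoods finite
    records["time"] = np.maximum(time, 1e-12)
    records["event"] = event
    return pd.DataFrame(records)


def generate_life_table(config: SyntheticConfig) -> LifeTable:
    """Synthetic Gompertz-Makeham life table on integer ages 30..max_age.

    q is strictly increasing in age until the cap and the terminal age has
    q = 1 so no cohort member outlives the table.
    """
    ages = np.arange(30, config.life_table_max_age + 1)
    rows = []
    for sex in SEXES:
        q = config.life_table_params[sex].q(ages.astype(float))
        q[-1] = 1.0
        rows.append(pd.DataFrame({"age": ages, "sex": sex, "q": q}))
    return LifeTable(pd.concat(rows, ignore_index=True))


def default_life_table() -> LifeTable:
    """The synthetic life table shipped with the package (identical to
    ``generate_life_table(SyntheticConfig())``); a stand-in for the external
    national table."""
    path = Path(__file__).parent / "data" / "life_table_synthetic.csv"
    return LifeTable.from_csv(path)


# -- file I/O ---------------------------------------------------------------

def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_events(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_config(config: SyntheticConfig, path: str | Path) -> None:
    payload = {
        "seed": config.seed,
        "age_range": list(config.age_range),
        "population": dict(config.population),
        "t2d_prevalence": dict(config.t2d_prevalence),
        "sex_split": dict(config.sex_split),
        "findrisc_probs": {s: np.asarray(p).tolist()
                           for s, p in config.findrisc_probs.items()},
        "age_band_weights": np.asarray(config.age_band_weights).tolist(),
        "n_incidence": config.n_incidence,
        "n_complication": config.n_complication,
        "true_weibull": {k: {"shape": v.shape, "coefficients": v.coefficients}
                         for k, v in config.true_weibull.items()},
        "censoring_year": dict(config.censoring_year),
        "life_table_params": {s: {"makeham": p.makeham, "b": p.b, "c": p.c}
                              for s, p in config.life_table_params.items()},
        "life_table_max_age": config.life_table_max_age,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")


def load_config(path: str | Path) -> SyntheticConfig:
    d = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return SyntheticConfig(
        seed=d["seed"],
        age_range=tuple(d["age_range"]),
        population=d["population"],
        t2d_prevalence=d["t2d_prevalence"],
        sex_split=d["sex_split"],
        findrisc_probs={s: np.asarray(p) for s, p in d["findrisc_probs"].items()},
        age_band_weights=np.asarray(d["age_band_weights"]),
        n_incidence=d["n_incidence"],
        n_complication=d["n_complication"],
        true_weibull={k: WeibullTruth(shape=v["shape"], coefficients=v["coefficients"])
                      for k, v in d["true_weibull"].items()},
        censoring_year=d["censoring_year"],
        life_table_params={s: GompertzMakeham(**p)
                           for s, p in d["life_table_params"].items()},
        life_table_max_age=d["life_table_max_age"],
    )
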