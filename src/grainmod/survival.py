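"""Weibull accelerated-failure-time survival regression and conversion of
fitted curves into annual transition probabilities.

The incidence process (time to T2D diagnosis) is modelled on baseline age,
sex and FINDRISC risk category; the complication process (time from T2D
diagnosis to first complication) on age at diagnosis and sex. Both use the
Weibull AFT parameterization

    S(t | x) = exp(-(t / lambda(x))**k),   lambda(x) = exp(x' beta),

with shape ``k`` shared across covariate profiles. The maximum-likelihood fit
is over theta = (log k, beta); the covariance of theta from the inverse
observed information drives the multivariate-normal coefficient draws in the
probabilistic sensitivity analysis.

Hazard-ratio effects and the calibration multiplier act on the cumulative
hazard, i.e. as a power of the per-cycle survival ratio:

    p_cycle = 1 - (S(t + 1 | x) / S(t | x))**m.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.tools.numdiff import approx_hess

from .parameters import MALE, SEXES

FINDRISC_CATEGORIES = (1, 2, 3, 4, 5)


class FittingError(RuntimeError):
    """Raised when the survival regression cannot be fitted."""


@dataclass(frozen=True)
class CovariateProfile:
    """A single covariate combination at which the fitted model is evaluated."""

    age: float
    sex: str
    findrisc_category: int | None = None

    def __post_init__(self) -> None:
        if not 30.0 <= self.age <= 110.0:
            raise ValueError("age must lie in [30, 110]")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.findrisc_category is not None and self.findrisc_category not in FINDRISC_CATEGORIES:
            raise ValueError("findrisc_category must be in 1..5")

    def to_frame(self) -> pd.DataFrame:
        row = {"age": self.age, "sex": self.sex}
        if self.findrisc_category is not None:
            row["findrisc_category"] = self.findrisc_category
        return pd.DataFrame([row])


def build_design(data: pd.DataFrame, covariates: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Expand a record table into the AFT design matrix.

    ``sex`` becomes an indicator for male; ``findrisc_category`` becomes four
    indicators with category 1 as reference; numeric columns enter as-is.
    An intercept column is always prepended.
    """
    cols: list[np.ndarray] = [np.ones(len(data))]
    names: list[str] = ["intercept"]
    for cov in covariates:
        if cov == "sex":
            cols.append((data["sex"].to_numpy() == MALE).astype(float))
            names.append("sex_male")
        elif cov == "findrisc_category":
            cats = data["findrisc_category"].to_numpy()
            for c in FINDRISC_CATEGORIES[1:]:
                cols.append((cats == c).astype(float))
                names.append(f"findrisc_{c}")
        else:
            cols.append(pd.to_numeric(data[cov]).to_numpy(dtype=float))
            names.append(cov)
    return np.column_stack(cols), names


@dataclass
class WeibullFit:
    """A fitted Weibull AFT model.

    ``coefficients`` are on the log-time scale (named, including
    ``intercept``); ``covariance`` is over ``param_names``
    (``log_shape`` first unless the shape was fixed during fitting).
    """

    shape: float
    coefficients: dict[str, float]
    covariance: np.ndarray
    param_names: list[str]
    loglik: float
    aic: float
    bic: float
    n: int
    n_events: int
    covariates: list[str] = field(default_factory=list)
    shape_fixed: bool = False

    def __post_init__(self) -> None:
        if not self.shape > 0:
            raise ValueError("Weibull shape must be positive")
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (len(self.param_names), len(self.param_names)):
            raise ValueError("covariance dimension must match parameter names")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        self.covariance = cov

    # -- evaluation ---------------------------------------------------------

    def _beta(self) -> np.ndarray:
        return np.array(list(self.coefficients.values()), dtype=float)

    def scale(self, data: pd.DataFrame) -> np.ndarray:
        """lambda(x) = exp(x' beta) for each row of ``data``."""
        X, names = build_design(data, self.covariates)
        if names != list(self.coefficients.keys()):
            raise ValueError("data does not match the fitted design")
        return np.exp(X @ self._beta())

    def standard_errors(self) -> dict[str, float]:
        se = np.sqrt(np.diag(self.covariance))
        return dict(zip(self.param_names, se))

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "shape": self.shape,
            "coefficients": self.coefficients,
            "covariance": self.covariance.tolist(),
            "param_names": self.param_names,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "n": self.n,
            "n_events": self.n_events,
            "covariates": self.covariates,
            "shape_fixed": self.shape_fixed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "WeibullFit":
        text = Path(source).read_text(encoding="utf-8") if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            shape=d["shape"], coefficients=d["coefficients"],
            covariance=np.array(d["covariance"]), param_names=d["param_names"],
            loglik=d["loglik"], aic=d["aic"], bic=d["bic"],
            n=d["n"], n_events=d["n_events"], covariates=d["covariates"],
            shape_fixed=d.get("shape_fixed", False),
        )


def _negloglik(theta: np.ndarray, X: np.ndarray, log_t: np.ndarray,
               event: np.ndarray, fixed_log_shape: float | None) -> float:
    if fixed_log_shape is None:
        log_k, beta = theta[0], theta[1:]
    else:
        log_k, beta = fixed_log_shape, theta
    k = np.exp(log_k)
    z = k * (log_t - X @ beta)
    # guard against overflow in exp(z) far from the optimum
    ll = np.sum(event * (log_k - log_t + z)) - np.sum(np.exp(np.minimum(z, 500.0)))
    return -ll


def fit_weibull(records: pd.DataFrame, covariates: Sequence[str],
                fix_shape: float | None = None) -> WeibullFit:
    """Maximum-likelihood Weibull AFT fit on right-censored records.

    ``records`` needs columns ``time`` (> 0), ``event`` (0/1) and the
    requested covariate columns. ``fix_shape`` pins the Weibull shape (e.g.
    1.0 for the exponential sub-model used in information-criterion
    comparisons); the fixed shape is then excluded from the covariance.
    """
    records = pd.DataFrame(records)
    if len(records) < 30:
        raise FittingError("need at least 30 records to fit")
    event = records["event"].to_numpy(dtype=float)
    if event.sum() < 5:
        raise FittingError("need at least 5 observed events to fit")
    if event.sum() == 0:
        raise FittingError("all records are censored")
    t = records["time"].to_numpy(dtype=float)
    if np.any(t <= 0):
        raise FittingError("all times must be positive")
    if fix_shape is not None and fix_shape <= 0:
        raise FittingError("fixed shape must be positive")

    X, names = build_design(records, covariates)
    for j, name in enumerate(names[1:], start=1):
        if np.ptp(X[:, j]) == 0:
            raise FittingError(f"covariate {name!r} is constant across records")

    log_t = np.log(t)
    fixed_log_shape = None if fix_shape is None else float(np.log(fix_shape))
    beta0 = np.zeros(X.shape[1])
    beta0[0] = np.log(t.mean())
    theta0 = beta0 if fix_shape is not None else np.concatenate([[0.0], beta0])

    obj = lambda th: _negloglik(th, X, log_t, event, fixed_log_shape)
    res = optimize.minimize(obj, theta0, method="BFGS",
                            options={"maxiter": 500, "gtol": 1e-8})
    if not res.success:
        res = optimize.minimize(obj, res.x, method="Nelder-Mead",
                                options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-10})
    if not res.success:
        raise FittingError(f"Weibull fit did not converge: {res.message}")

    theta = res.x
    hess = approx_hess(theta, obj)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate designs
        raise FittingError(f"observed information is singular: {exc}") from exc
    cov = (cov + cov.T) / 2.0

    if fix_shape is None:
        shape = float(np.exp(theta[0]))
        beta = theta[1:]
        param_names = ["log_shape", *names]
        shape_fixed = False
    else:
        shape = float(fix_shape)
        beta = theta
        param_names = list(names)
        shape_fixed = True

    loglik = -res.fun
    p = len(theta)
    n = len(records)
    return WeibullFit(
        shape=shape,
        coefficients=dict(zip(names, beta.tolist())),
        covariance=cov,
        param_names=param_names,
        loglik=float(loglik),
        aic=float(2 * p - 2 * loglik),
        bic=float(np.log(n) * p - 2 * loglik),
        n=n,
        n_events=int(event.sum()),
        covariates=list(covariates),
        shape_fixed=shape_fixed,
    )


def survival_at(fit: WeibullFit, profile: CovariateProfile, t) -> float | np.ndarray:
    """S(t | x) = exp(-(t / lambda(x))**k) at the profile's covariates."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    lam = fit.scale(profile.to_frame())[0]
    s = np.exp(-((t / lam) ** fit.shape))
    return float(s) if s.ndim == 0 else s


def annual_transition_probability(fit: WeibullFit, profile: CovariateProfile,
                                  cycle_start: float, hazard_multiplier: float = 1.0) -> float:
    """Probability of the event within (cycle_start, cycle_start + 1],
    conditional on being event-free at cycle_start.

    ``hazard_multiplier`` scales the cumulative hazard: the conditional
    survival ratio is raised to that power, which is the exact
    proportional-hazards application of calibration factors and hazard
    ratios. ``hazard_multiplier = 0`` gives probability 0.
    """
    if cycle_start < 0:
        raise ValueError("cycle_start must be non-negative")
    if hazard_multiplier < 0:
        raise ValueError("hazard_multiplier must be non-negative")
    lam = fit.scale(profile.to_frame())[0]
    k = fit.shape
    delta_h = ((cycle_start + 1.0) ** k - cycle_start ** k) / lam ** k
    return float(1.0 - np.exp(-hazard_multiplier * delta_h))
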