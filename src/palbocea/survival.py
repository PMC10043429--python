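"""Parametric survival curves, per-cycle transition probabilities and censored MLE.

Time is measured in model cycles (28 days by default elsewhere in the
package). Every family is parameterised with a rate-like ``scale`` λ > 0 and,
where applicable, a ``shape`` γ > 0, chosen so that

* ``S(0) = 1`` exactly,
* ``S`` is non-increasing and proper (``S(t) -> 0`` as ``t -> inf``),
* the Weibull reads ``S(t) = exp(-λ t**γ)``, the form used to extrapolate
  progression-free and overall survival, so γ = 1 collapses to the
  exponential.

Family parameterisations
------------------------
weibull            S(t) = exp(-λ t**γ)
exponential        S(t) = exp(-λ t)
lognormal          S(t) = 1 - Φ((ln t + ln λ) / γ)      (median 1/λ, γ = σ)
loglogistic        S(t) = 1 / (1 + (λ t)**γ)
gompertz           S(t) = exp(-(λ/γ) (e**(γ t) - 1)),   γ > 0
generalized_gamma  S(t) = Q(a, (λ t)**γ)   (Stacy; Q = regularised upper
                   incomplete gamma; ``extra_shape`` a = 1 recovers a Weibull
                   with rate λ**γ)

The conditional probability of leaving a state during cycle ``t`` is the
discrete hazard ``P(t) = 1 - S(t)/S(t-1)``; for the Weibull this equals the
closed form ``1 - exp(λ (t-1)**γ - λ t**γ)``.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

FAMILIES = (
    "weibull",
    "exponential",
    "lognormal",
    "loglogistic",
    "gompertz",
    "generalized_gamma",
)

#: number of free parameters per family (used for AIC/BIC)
N_PARAMS = {
    "exponential": 1,
    "weibull": 2,
    "lognormal": 2,
    "loglogistic": 2,
    "gompertz": 2,
    "generalized_gamma": 3,
}


class SurvivalValidationError(ValueError):
    """Invalid model parameters or inputs."""


class NonIdentifiableError(ValueError):
    """Likelihood has no interior maximum (e.g. no observed events)."""


class FitConvergenceError(RuntimeError):
    """The optimiser failed to converge; no estimates are reported."""


@dataclass(frozen=True)
class ParametricSurvivalModel:
    """A parametric survival curve S(t) on the model-cycle time axis."""

    family: str
    scale: float
    shape: float = 1.0
    extra_shape: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise SurvivalValidationError(f"unknown family {self.family!r}")
        if not (self.scale > 0):
            raise SurvivalValidationError("scale (lambda) must be positive")
        if not (self.shape > 0):
            raise SurvivalValidationError("shape (gamma) must be positive")
        if self.family == "generalized_gamma":
            if self.extra_shape is None or not (self.extra_shape > 0):
                raise SurvivalValidationError(
                    "generalized_gamma requires positive extra_shape"
                )
        elif self.extra_shape is not None:
            raise SurvivalValidationError(
                f"extra_shape only applies to generalized_gamma, not {self.family}"
            )

    # -- convenience wrappers -------------------------------------------------
    def survival(self, t):
        return survival_at(self, t)

    def transition(self, t):
        return transition_prob(self, t)


@dataclass(frozen=True)
class CensoredSample:
    """A right-censored event-time record (time in cycles, > 0)."""

    time: float
    event: bool

    def __post_init__(self) -> None:
        if not (self.time > 0):
            raise SurvivalValidationError("time must be positive")


@dataclass(frozen=True)
class FitReport:
    """Maximum-likelihood fit of one family to censored data."""

    model: ParametricSurvivalModel
    log_likelihood: float
    aic: float
    bic: float
    n: int

    @property
    def k(self) -> int:
        return N_PARAMS[self.model.family]


def _log_survival(model: ParametricSurvivalModel, t: np.ndarray) -> np.ndarray:
    lam, gam = model.scale, model.shape
    fam = model.family
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        if fam == "weibull":
            return -lam * t**gam
        if fam == "exponential":
            return -lam * t
        if fam == "lognormal":
            # S(t) = Phi_bar((ln t + ln lam) / gam); S(0)=1
            out = np.full_like(t, 0.0)
            pos = t > 0
            z = (np.log(t[pos]) + math.log(lam)) / gam
            out[pos] = stats.norm.logsf(z)
            return out
        if fam == "loglogistic":
            return -np.log1p((lam * t) ** gam)
        if fam == "gompertz":
            return -(lam / gam) * np.expm1(gam * t)
        if fam == "generalized_gamma":
            a = model.extra_shape
            s = special.gammaincc(a, (lam * t) ** gam)
            return np.log(np.clip(s, 1e-320, 1.0))
    raise AssertionError(fam)


def _log_density(model: ParametricSurvivalModel, t: np.ndarray) -> np.ndarray:
    lam, gam = model.scale, model.shape
    fam = model.family
    t = np.asarray(t, dtype=float)
    logt = np.log(t)
    if fam == "weibull":
        return math.log(lam) + math.log(gam) + (gam - 1) * logt - lam * t**gam
    if fam == "exponential":
        return math.log(lam) - lam * t
    if fam == "lognormal":
        z = (logt + math.log(lam)) / gam
        return stats.norm.logpdf(z) - math.log(gam) - logt
    if fam == "loglogistic":
        z = (lam * t) ** gam
        return (
            math.log(gam)
            + gam * math.log(lam)
            + (gam - 1) * logt
            - 2 * np.log1p(z)
        )
    if fam == "gompertz":
        return math.log(lam) + gam * t - (lam / gam) * np.expm1(gam * t)
    if fam == "generalized_gamma":
        a = model.extra_shape
        z = (lam * t) ** gam
        return (
            math.log(gam)
            + a * gam * math.log(lam)
            + (a * gam - 1) * logt
            - z
            - special.gammaln(a)
        )
    raise AssertionError(fam)


def survival_at(model: ParametricSurvivalModel, t) -> float | np.ndarray:
    """S(t): probability of remaining event-free through time ``t`` (cycles).

    ``t`` may be a scalar or array; values must be non-negative.
    """
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise SurvivalValidationError("t must be non-negative")
    out = np.exp(_log_survival(model, arr))
    out = np.clip(out, 0.0, 1.0)
    # exact boundary
    out = np.where(arr == 0, 1.0, out)
    return float(out) if np.isscalar(t) or arr.ndim == 0 else out


def transition_prob(model: ParametricSurvivalModel, t) -> float | np.ndarray:
    """Conditional probability of the event during cycle ``t`` (t >= 1).

    Equals ``1 - S(t)/S(t-1)``; the Weibull uses the closed form
    ``1 - exp(λ (t-1)**γ - λ t**γ)`` directly.
    """
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 1):
        raise SurvivalValidationError("cycle index t must be >= 1")
    lam, gam = model.scale, model.shape
    if model.family == "weibull":
        p = 1.0 - np.exp(lam * (arr - 1) ** gam - lam * arr**gam)
    elif model.family == "exponential":
        p = np.full_like(arr, 1.0 - math.exp(-lam))
    else:
        ls1 = _log_survival(model, arr - 1)
        ls2 = _log_survival(model, arr)
        p = -np.expm1(ls2 - ls1)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if np.isscalar(t) or arr.ndim == 0 else p


def _as_arrays(data: Iterable[CensoredSample]) -> tuple[np.ndarray, np.ndarray]:
    recs = list(data)
    times = np.array([r.time for r in recs], dtype=float)
    events = np.array([bool(r.event) for r in recs])
    return times, events


def log_likelihood(
    model: ParametricSurvivalModel, times: np.ndarray, events: np.ndarray
) -> float:
    """Right-censoring log-likelihood: sum log f over events + log S over censored."""
    ll = 0.0
    if events.any():
        ll += float(np.sum(_log_density(model, times[events])))
    if (~events).any():
        ll += float(np.sum(_log_survival(model, times[~events])))
    return ll


def _build(family: str, theta: np.ndarray) -> ParametricSurvivalModel:
    p = np.exp(theta)
    if family == "exponential":
        return ParametricSurvivalModel(family, float(p[0]), 1.0)
    if family == "generalized_gamma":
        return ParametricSurvivalModel(family, float(p[0]), float(p[1]), float(p[2]))
    return ParametricSurvivalModel(family, float(p[0]), float(p[1]))


def fit_parametric(
    data: Iterable[CensoredSample], family: str
) -> FitReport:
    """Maximum-likelihood fit of one family to right-censored samples.

    Optimisation runs on log-parameters (positivity for free) with L-BFGS-B
    from fixed starting values (λ0 = crude event rate, γ0 = 1, a0 = 1), so the
    report is deterministic given the data.
    """
    if family not in FAMILIES:
        raise SurvivalValidationError(f"unknown family {family!r}")
    times, events = _as_arrays(data)
    n = times.size
    if n < 10:
        raise SurvivalValidationError("need at least 10 records")
    if not events.any():
        raise NonIdentifiableError("all records censored: no interior maximum")

    rate0 = events.sum() / times.sum()
    k = N_PARAMS[family]
    theta0 = np.log([rate0] + [1.0] * (k - 1))

    def nll(theta: np.ndarray) -> float:
        try:
            m = _build(family, theta)
        except SurvivalValidationError:
            return 1e300
        v = -log_likelihood(m, times, events)
        return v if np.isfinite(v) else 1e300

    res = optimize.minimize(nll, theta0, method="L-BFGS-B")
    if not res.success and not np.isfinite(res.fun):
        raise FitConvergenceError(f"{family}: {res.message}")
    model = _build(family, res.x)
    ll = log_likelihood(model, times, events)
    if not np.isfinite(ll):
        raise FitConvergenceError(f"{family}: non-finite log-likelihood")
    aic = 2 * k - 2 * ll
    bic = k * math.log(n) - 2 * ll
    return FitReport(model=model, log_likelihood=ll, aic=aic, bic=bic, n=n)


def select_model(reports: Sequence[FitReport]) -> FitReport:
    """Pick the best fit: smallest AIC, ties by BIC, then fewest parameters.

    Deterministic and invariant to the input order (final tie-break on the
    family name).
    """
    reports = list(reports)
    if not reports:
        raise SurvivalValidationError("empty report collection")
    return min(reports, key=lambda r: (r.aic, r.bic, r.k, r.model.family))


# -- external interfaces ------------------------------------------------------

def read_censored_csv(path: str | Path | io.IOBase) -> list[CensoredSample]:
    """Read samples from a two-column CSV ``time,event`` (event in {0,1})."""
    df = pd.read_csv(path)
    if not {"time", "event"}.issubset(df.columns):
        raise SurvivalValidationError("CSV must have columns time,event")
    return [
        CensoredSample(time=float(t), event=bool(int(e)))
        for t, e in zip(df["time"], df["event"])
    ]


def write_censored_csv(data: Iterable[CensoredSample], path: str | Path) -> None:
    recs = list(data)
    df = pd.DataFrame(
        {"time": [r.time for r in recs], "event": [int(r.event) for r in recs]}
    )
    df.to_csv(path, index=False)


def fit_report_to_text(report: FitReport) -> str:
    """Flat key-value serialisation of a fit report."""
    m = report.model
    lines = [
        f"family={m.family}",
        f"scale={m.scale!r}",
        f"shape={m.shape!r}",
    ]
    if m.extra_shape is not None:
        lines.append(f"extra_shape={m.extra_shape!r}")
    lines += [
        f"loglik={report.log_likelihood!r}",
        f"aic={report.aic!r}",
        f"bic={report.bic!r}",
        f"n={report.n}",
    ]
    return "\n".join(lines) + "\n"


def fit_report_from_text(text: str) -> FitReport:
    kv = dict(line.split("=", 1) for line in text.strip().splitlines())
    model = ParametricSurvivalModel(
        family=kv["family"],
        scale=float(kv["scale"]),
        shape=float(kv["shape"]),
        extra_shape=float(kv["extra_shape"]) if "extra_shape" in kv else None,
    )
    return FitReport(
        model=model,
        log_likelihood=float(kv["loglik"]),
        aic=float(kv["aic"]),
        bic=float(kv["bic"]),
        n=int(kv["n"]),
    )


def weibull_median(model: ParametricSurvivalModel) -> float:
    """Closed-form median of the Weibull ``(ln 2 / λ)**(1/γ)`` (cycles)."""
    if model.family != "weibull":
        raise SurvivalValidationError("median closed form is for the Weibull")
    return (math.log(2.0) / model.scale) ** (1.0 / model.shape)
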