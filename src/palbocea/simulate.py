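"""Synthetic pseudo-IPD: event times from known curves, KM tables, perturbed inputs.

The survival fitting stage normally consumes patient-level times reconstructed
from digitised Kaplan-Meier figures, which are not redistributable. This
module generates equivalent inputs from first principles: event times drawn by
inverse-transform sampling from any supported parametric curve, optional
right-censoring, product-limit survival tables on a time grid, and randomly
perturbed economic-input sets for stress tests.

The default administrative censoring horizon (79.6 cycles, about 73.3 months)
mirrors the median follow-up maturity of the trial read-out the curve
parameters were derived from.

All randomness flows from an explicit seed per call; no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import special, stats

from .economics import EconInputs
from .sensitivity import ParameterSpec, parameterize_distribution
from .survival import CensoredSample, ParametricSurvivalModel, SurvivalValidationError

#: trial-like administrative follow-up in 28-day cycles (73.3 months)
DEFAULT_FOLLOWUP_CYCLES = 73.3 * (365.25 / 12.0) / 28.0


@dataclass(frozen=True)
class SimulationSpec:
    """Recipe for one synthetic censored sample."""

    true_model: ParametricSurvivalModel
    n: int
    censoring: str = "none"  # none | uniform | administrative
    t_max: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SurvivalValidationError("n must be >= 1")
        if self.censoring not in ("none", "uniform", "administrative"):
            raise SurvivalValidationError("unknown censoring scheme")
        if self.censoring != "none" and not (self.t_max and self.t_max > 0):
            raise SurvivalValidationError("censoring requires positive t_max")


def inverse_survival(model: ParametricSurvivalModel, u) -> np.ndarray:
    """Solve S(t) = u for t (closed form per family); u in (0, 1)."""
    u = np.asarray(u, dtype=float)
    lam, gam = model.scale, model.shape
    fam = model.family
    if fam == "weibull":
        return (-np.log(u) / lam) ** (1.0 / gam)
    if fam == "exponential":
        return -np.log(u) / lam
    if fam == "lognormal":
        # S(t) = Phi_bar((ln t + ln lam)/gam)
        return np.exp(gam * stats.norm.isf(u) - math.log(lam))
    if fam == "loglogistic":
        return ((1.0 - u) / u) ** (1.0 / gam) / lam
    if fam == "gompertz":
        return np.log1p(-(gam / lam) * np.log(u)) / gam
    if fam == "generalized_gamma":
        z = special.gammainccinv(model.extra_shape, u)
        return z ** (1.0 / gam) / lam
    raise AssertionError(fam)


def simulate_ipd(spec: SimulationSpec) -> list[CensoredSample]:
    """Draw censored event times from the spec's true curve.

    Event times come from inverse-transform sampling of S; censoring times are
    uniform on (0, t_max) or administrative at t_max. Observed time is the
    minimum; ties favour the event. Zero times are nudged to the smallest
    positive float to honour the time > 0 contract.
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(size=spec.n)
    t_event = inverse_survival(spec.true_model, u)
    if spec.censoring == "none":
        t_obs, event = t_event, np.ones(spec.n, dtype=bool)
    else:
        if spec.censoring == "uniform":
            t_cens = rng.uniform(0.0, spec.t_max, size=spec.n)
        else:
            t_cens = np.full(spec.n, float(spec.t_max))
        event = t_event <= t_cens
        t_obs = np.where(event, t_event, t_cens)
    t_obs = np.maximum(t_obs, np.finfo(float).tiny)
    return [CensoredSample(float(t), bool(e)) for t, e in zip(t_obs, event)]


def km_coordinates(samples: list[CensoredSample], grid) -> np.ndarray:
    """Product-limit (Kaplan-Meier) survival estimates at the grid points."""
    if not samples:
        raise SurvivalValidationError("no samples")
    kmf = KaplanMeierFitter()
    kmf.fit(
        durations=[s.time for s in samples],
        event_observed=[int(s.event) for s in samples],
    )
    grid = np.asarray(list(grid), dtype=float)
    return kmf.survival_function_at_times(grid).to_numpy()


def perturb_econ_inputs(
    base: EconInputs, specs: list[ParameterSpec], seed: int
) -> EconInputs:
    """Redraw every economic parameter from its PSA distribution.

    Uses the same parameter names as the sensitivity module (see
    :func:`palbocea.workbench.apply_overrides`); draws that violate the
    EconInputs invariants (e.g. inverted utilities) are resampled.
    """
    from .workbench import apply_overrides  # circular at import time otherwise

    rng = np.random.default_rng(seed)
    dists = {s.name: parameterize_distribution(s) for s in specs}
    for _ in range(1000):
        params = {name: float(d.rvs(random_state=rng)) for name, d in dists.items()}
        try:
            inputs, _settings = apply_overrides(base, None, params)
            return inputs
        except Exception:
            continue
    raise SurvivalValidationError("could not draw a valid economic-input set")
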