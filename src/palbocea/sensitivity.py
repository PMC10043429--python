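"""Deterministic (tornado) and probabilistic sensitivity analysis.

Both analyses treat the model as a black box: a callable that maps a dict of
parameter overrides (by name) to an incremental :class:`~palbocea.economics.Comparison`.

One-way DSA re-evaluates the full two-arm pipeline at each parameter's lower
and upper bound with everything else at base. PSA samples all parameters
jointly and independently from moment-matched distributions — Gamma for
costs, Beta for utilities and probabilities, Normal for the discount rate —
with the standard deviation recovered from the (lower, upper) bounds read as
a 95% interval: sd = (upper - lower) / (2 * 1.96).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .economics import Comparison

Z95_WIDTH = 2 * 1.959963984540054  # width of a 95% normal interval in sd units

EvaluateFn = Callable[[dict[str, float]], Comparison]


class SensitivityError(ValueError):
    pass


@dataclass(frozen=True)
class ParameterSpec:
    """One uncertain parameter: base value, DSA bounds, PSA distribution."""

    name: str
    base: float
    lower: float
    upper: float
    distribution: str  # gamma | beta | normal | fixed

    def __post_init__(self) -> None:
        if not (self.lower <= self.base <= self.upper):
            raise SensitivityError(
                f"{self.name}: bounds must satisfy lower <= base <= upper"
            )
        if self.distribution not in ("gamma", "beta", "normal", "fixed"):
            raise SensitivityError(f"{self.name}: unknown distribution")
        if self.distribution == "beta" and not (
            0 <= self.lower and self.upper <= 1 and 0 <= self.base <= 1
        ):
            raise SensitivityError(f"{self.name}: beta requires values in [0,1]")

    @property
    def sd(self) -> float:
        return (self.upper - self.lower) / Z95_WIDTH


class _PointMass:
    """Degenerate distribution at a single value."""

    def __init__(self, value: float):
        self.value = float(value)

    def rvs(self, size=None, random_state=None):
        if size is None:
            return self.value
        return np.full(size, self.value)

    def mean(self) -> float:
        return self.value

    def std(self) -> float:
        return 0.0


def parameterize_distribution(spec: ParameterSpec):
    """Moment-matched sampling distribution for one parameter.

    Gamma: shape = (m/sd)^2, rate = m/sd^2. Beta: alpha+beta = m(1-m)/sd^2 - 1.
    Normal: (m, sd). A zero sd (or ``fixed``) collapses to a point mass.
    """
    m, sd = spec.base, spec.sd
    if spec.distribution == "fixed" or sd == 0:
        return _PointMass(m)
    if spec.distribution == "gamma":
        if m <= 0:
            raise SensitivityError(f"{spec.name}: gamma requires positive mean")
        shape = (m / sd) ** 2
        return stats.gamma(a=shape, scale=sd**2 / m)
    if spec.distribution == "beta":
        if not (0 < m < 1):
            raise SensitivityError(f"{spec.name}: beta mean must lie in (0,1)")
        ab = m * (1 - m) / sd**2 - 1
        if ab <= 0:
            raise SensitivityError(f"{spec.name}: beta sd too large for mean")
        return stats.beta(a=m * ab, b=(1 - m) * ab)
    return stats.norm(loc=m, scale=sd)


def one_way_dsa(
    specs: Sequence[ParameterSpec], evaluate: EvaluateFn
) -> pd.DataFrame:
    """One-way DSA: ICER at each parameter's lower and upper bound.

    Returns a frame with columns (parameter, base, lower, upper, icer_at_lower,
    icer_at_upper, range_width, error). A bound that makes the model invalid
    is recorded in ``error`` with NaN ICERs rather than raising.
    """
    if not specs:
        raise SensitivityError("no parameters to vary")
    rows = []
    for spec in specs:
        row = {
            "parameter": spec.name,
            "base": spec.base,
            "lower": spec.lower,
            "upper": spec.upper,
            "icer_at_lower": np.nan,
            "icer_at_upper": np.nan,
            "error": "",
        }
        for bound, col in ((spec.lower, "icer_at_lower"), (spec.upper, "icer_at_upper")):
            try:
                cmp_ = evaluate({spec.name: bound})
                row[col] = np.nan if cmp_.icer is None else cmp_.icer
            except Exception as exc:  # failed bound, not a crash
                row["error"] = f"{col}: {exc}"
        row["range_width"] = abs(row["icer_at_upper"] - row["icer_at_lower"])
        rows.append(row)
    return pd.DataFrame(rows)


def tornado_rank(result: pd.DataFrame) -> pd.DataFrame:
    """Sort DSA rows by descending ICER range; ties broken by parameter name."""
    if result.empty:
        raise SensitivityError("empty DSA result")
    out = result.sort_values(
        ["range_width", "parameter"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out


def run_psa(
    specs: Sequence[ParameterSpec],
    evaluate: EvaluateFn,
    n_draws: int,
    seed: int,
    constraint: Callable[[dict[str, float]], bool] | None = None,
) -> pd.DataFrame:
    """Monte-Carlo PSA: joint independent draws, full pipeline per draw.

    Draws violating ``constraint`` (e.g. a PD utility exceeding the PFS
    utility) are redrawn; the number of rejections is reported in
    ``frame.attrs['n_resampled']``. Reproducible given ``seed``.
    """
    if n_draws < 1:
        raise SensitivityError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    dists = {s.name: parameterize_distribution(s) for s in specs}
    records = []
    n_resampled = 0
    for i in range(n_draws):
        for _attempt in range(1000):
            params = {
                name: float(d.rvs(random_state=rng)) for name, d in dists.items()
            }
            if constraint is None or constraint(params):
                break
            n_resampled += 1
        else:
            raise SensitivityError("could not satisfy draw constraints")
        cmp_ = evaluate(params)
        records.append(
            {"draw": i, **params, "delta_cost": cmp_.delta_cost, "delta_qaly": cmp_.delta_qaly}
        )
    frame = pd.DataFrame(records)
    frame.attrs["n_resampled"] = n_resampled
    frame.attrs["seed"] = seed
    return frame


@dataclass(frozen=True)
class CEACCurve:
    """Probability of positive net monetary benefit per WTP grid point."""

    wtp: np.ndarray
    probability: np.ndarray

    def __post_init__(self) -> None:
        if self.wtp.shape != self.probability.shape:
            raise SensitivityError("wtp and probability must align")
        if np.any(self.probability < 0) or np.any(self.probability > 1):
            raise SensitivityError("probabilities must lie in [0,1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "probability": self.probability})

    def crossing(self, level: float) -> float | None:
        """Smallest grid WTP at which the curve reaches ``level`` (or None)."""
        idx = np.nonzero(self.probability >= level)[0]
        return float(self.wtp[idx[0]]) if idx.size else None


def ceac(samples: pd.DataFrame, wtp_grid: Iterable[float]) -> CEACCurve:
    """Cost-effectiveness acceptability curve from PSA (dC, dE) draws."""
    if samples.empty:
        raise SensitivityError("no PSA samples")
    wtp = np.asarray(list(wtp_grid), dtype=float)
    dc = samples["delta_cost"].to_numpy()
    de = samples["delta_qaly"].to_numpy()
    nmb = de[None, :] * wtp[:, None] - dc[None, :]
    prob = (nmb > 0).mean(axis=1)
    return CEACCurve(wtp=wtp, probability=prob)
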