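"""Three-state Markov cohort engine: transitions, trace, half-cycle credits.

States are (PFS, PD, Death) in that column order. The whole cohort starts in
PFS; death is absorbing. Per cycle ``t`` (1-based):

* PFS -> Death uses the background (all-cause) mortality of the general
  population. Two conventions are supported: ``per_cycle`` plugs the 7.18 per
  mille annual figure in directly as the per-cycle probability (the reading
  used by the study configuration), ``annual_compound`` converts it properly
  via ``1 - (1 - r)**(cycle_days/365.25)``.
* the total probability of leaving PFS is the PFS curve's discrete hazard,
  so PFS -> PD is that hazard minus background mortality (clamped at 0 with a
  warning if background exceeds it);
* PD -> Death is the discrete hazard of the overall-survival curve at model
  time ``t`` (a simplification: time since progression is not tracked).

State membership is credited per cycle as the average of start- and
end-of-cycle occupancy (trapezoidal half-cycle correction).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .survival import ParametricSurvivalModel, transition_prob

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
STATES = ("pfs", "pd", "death")


class CohortValidationError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSettings:
    """Global simulation settings (defaults = the study configuration)."""

    cycle_length_days: float = 28.0
    horizon_years: float = 10.0
    discount_rate_annual: float = 0.05
    background_mortality_annual: float = 0.00718
    background_mode: str = "per_cycle"  # or "annual_compound"

    def __post_init__(self) -> None:
        if not (self.cycle_length_days > 0 and self.horizon_years > 0):
            raise CohortValidationError("cycle length and horizon must be positive")
        if not (0 <= self.discount_rate_annual < 1):
            raise CohortValidationError("discount rate must be in [0, 1)")
        if not (0 <= self.background_mortality_annual < 1):
            raise CohortValidationError("background mortality must be in [0, 1)")
        if self.background_mode not in ("per_cycle", "annual_compound"):
            raise CohortValidationError(
                "background_mode must be per_cycle or annual_compound"
            )
        if self.n_cycles < 1:
            raise CohortValidationError("horizon shorter than one cycle")

    @property
    def n_cycles(self) -> int:
        return int(self.horizon_years * DAYS_PER_YEAR // self.cycle_length_days)

    @property
    def cycle_fraction_of_year(self) -> float:
        return self.cycle_length_days / DAYS_PER_YEAR

    @property
    def discount_rate_cycle(self) -> float:
        """Per-cycle rate compounded from the annual rate."""
        return (1.0 + self.discount_rate_annual) ** self.cycle_fraction_of_year - 1.0

    def background_mortality_cycle(self) -> float:
        """Per-cycle PFS->Death probability under the configured convention."""
        r = self.background_mortality_annual
        if self.background_mode == "per_cycle":
            return r
        return 1.0 - (1.0 - r) ** self.cycle_fraction_of_year

    def with_discount(self, rate: float) -> "ModelSettings":
        return replace(self, discount_rate_annual=rate)


@dataclass(frozen=True)
class TransitionMatrixSequence:
    """Per-cycle 3x3 row-stochastic matrices, index 0 = cycle 1."""

    matrices: np.ndarray  # (n_cycles, 3, 3)

    def __post_init__(self) -> None:
        m = self.matrices
        if m.ndim != 3 or m.shape[1:] != (3, 3):
            raise CohortValidationError("matrices must have shape (n, 3, 3)")
        if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
            raise CohortValidationError("entries must be probabilities")
        if not np.allclose(m.sum(axis=2), 1.0, atol=1e-12):
            raise CohortValidationError("rows must sum to 1")

    @property
    def n_cycles(self) -> int:
        return self.matrices.shape[0]


@dataclass(frozen=True)
class CohortTrace:
    """Occupancy rows for cycles 0..n; columns (pfs, pd, death)."""

    occupancy: np.ndarray  # (n_cycles + 1, 3)
    arm_label: str = ""

    def __post_init__(self) -> None:
        occ = self.occupancy
        if occ.ndim != 2 or occ.shape[1] != 3:
            raise CohortValidationError("occupancy must have 3 columns")
        if not np.allclose(occ.sum(axis=1), 1.0, atol=1e-10):
            raise CohortValidationError("occupancy rows must sum to 1")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def new_deaths(self) -> np.ndarray:
        """Incident deaths per cycle (length n_cycles)."""
        return np.diff(self.occupancy[:, 2])

    def to_frame(self, settings: ModelSettings | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        if settings is not None:
            df["discount_factor"] = discount_factor(settings, df["cycle"].to_numpy())
        return df


def build_transitions(
    pfs_model: ParametricSurvivalModel,
    os_model: ParametricSurvivalModel,
    settings: ModelSettings,
) -> TransitionMatrixSequence:
    """Per-cycle transition matrices for one arm.

    PFS exit = discrete hazard of the PFS curve; of that, background mortality
    goes to Death and the remainder to PD. PD -> Death = discrete hazard of
    the OS curve at model time.
    """
    n = settings.n_cycles
    bg = settings.background_mortality_cycle()
    t = np.arange(1, n + 1, dtype=float)
    exit_pfs = np.asarray(transition_prob(pfs_model, t))
    p_pd_death = np.asarray(transition_prob(os_model, t))
    pfs_to_pd = exit_pfs - bg
    if np.any(pfs_to_pd < 0):
        logger.warning(
            "background mortality exceeds total PFS exit in %d cycle(s); "
            "clamping PFS->PD to 0",
            int(np.sum(pfs_to_pd < 0)),
        )
        pfs_to_pd = np.maximum(pfs_to_pd, 0.0)
    mats = np.zeros((n, 3, 3))
    mats[:, 0, 0] = 1.0 - pfs_to_pd - bg
    mats[:, 0, 1] = pfs_to_pd
    mats[:, 0, 2] = bg
    mats[:, 1, 1] = 1.0 - p_pd_death
    mats[:, 1, 2] = p_pd_death
    mats[:, 2, 2] = 1.0
    return TransitionMatrixSequence(mats)


def run_cohort(
    transitions: TransitionMatrixSequence,
    settings: ModelSettings,
    arm_label: str = "",
) -> CohortTrace:
    """Propagate the cohort: occupancy(t) = occupancy(t-1) @ M(t)."""
    if transitions.n_cycles != settings.n_cycles:
        raise CohortValidationError(
            f"transition sequence covers {transitions.n_cycles} cycles, "
            f"settings require {settings.n_cycles}"
        )
    n = settings.n_cycles
    occ = np.zeros((n + 1, 3))
    occ[0] = (1.0, 0.0, 0.0)
    for t in range(1, n + 1):
        occ[t] = occ[t - 1] @ transitions.matrices[t - 1]
    return CohortTrace(occupancy=occ, arm_label=arm_label)


def half_cycle_correct(trace: CohortTrace) -> np.ndarray:
    """Per-cycle credited state membership (trapezoidal half-cycle correction).

    Row ``i`` is the average of the cycle-``i`` start and end occupancy, i.e.
    the membership credited for cycle ``i + 1``; shape ``(n_cycles, 3)``.
    """
    occ = trace.occupancy
    return 0.5 * (occ[:-1] + occ[1:])


def discount_factor(settings: ModelSettings, t) -> float | np.ndarray:
    """Discount factor ``(1 + r_cycle)**(-t)`` for cycle index ``t`` (>= 0)."""
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise CohortValidationError("t must be non-negative")
    out = (1.0 + settings.discount_rate_cycle) ** (-arr)
    return float(out) if np.isscalar(t) or arr.ndim == 0 else out
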