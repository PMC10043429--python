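"""Costs and QALYs per arm from a cohort trace, and the incremental comparison.

Only direct medical costs enter: drug acquisition, drug administration,
follow-up, supportive care, terminal care, and management of grade >= 3
adverse events (AEs). Accrual conventions are explicit policy fields on
:class:`EconInputs` because the sources for such models rarely pin them down:

* drugs and administration accrue while on treatment, i.e. in PFS
  (treat-to-progression);
* follow-up accrues in a configurable state set (default: all alive states);
* supportive care accrues in a configurable state set (default: PFS only,
  i.e. supportive co-medication alongside active therapy);
* the incidence-weighted AE management cost is applied either once at model
  entry or per treated (PFS) cycle (default: per treated cycle);
* terminal care is a one-off cost attached to each incident death, discounted
  at the cycle of death and never half-cycle corrected (it attaches to a
  transition, not to state membership).

All costs are in USD; QALYs use utility weights in [0, 1] and
365.25-day years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .cohort import CohortTrace, ModelSettings, discount_factor, half_cycle_correct

ARMS = ("palbociclib", "placebo")
AE_NAMES = ("neutropenia", "leukopenia", "infections", "fatigue", "nausea")
ACCRUAL_STATES = ("pfs", "pd", "alive")
AE_MODES = ("per_treated_cycle", "entry_once")


class EconValidationError(ValueError):
    pass


@dataclass(frozen=True)
class DosingSchedule:
    """Trial dosing: palbociclib 125 mg/day, 21 of 28 days; fulvestrant 500 mg
    IM per administration (2 x 250 mg), twice in cycle 1 (days 1 and 15) and
    once per cycle thereafter. Treatment is given in PFS only."""

    palbociclib_mg_per_day: float = 125.0
    palbociclib_days_on: int = 21
    fulvestrant_mg_per_admin: float = 500.0
    fulvestrant_vial_mg: float = 250.0

    @property
    def fulvestrant_vials_per_admin(self) -> float:
        return self.fulvestrant_mg_per_admin / self.fulvestrant_vial_mg

    def fulvestrant_administrations(self, cycle: int) -> int:
        """Administrations falling in 28-day cycle ``cycle`` (1-based)."""
        if cycle < 1:
            raise EconValidationError("cycle must be >= 1")
        return 2 if cycle == 1 else 1


@dataclass(frozen=True)
class EconInputs:
    """Unit costs (USD), AE incidences, utilities and accrual policy."""

    cost_palbociclib_cycle: float = 640.39
    cost_fulvestrant_250mg: float = 287.90
    cost_followup_cycle: float = 166.0
    cost_administration_cycle: float = 33.56
    cost_supportive_cycle: float = 807.0
    cost_terminal_once: float = 1893.0
    ae_costs: Mapping[str, float] = field(
        default_factory=lambda: {
            "neutropenia": 412.0,
            "leukopenia": 435.58,
            "infections": 395.82,
            "fatigue": 110.0,
            "nausea": 323.0,
        }
    )
    ae_incidence: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "palbociclib": {
                "neutropenia": 0.577,
                "leukopenia": 0.377,
                "infections": 0.046,
                "fatigue": 0.029,
                "nausea": 0.006,
            },
            "placebo": {
                "leukopenia": 0.006,
                "infections": 0.035,
                "fatigue": 0.012,
                "nausea": 0.006,
            },
        }
    )
    utility_pfs: float = 0.87
    utility_pd: float = 0.71
    follow_up_state: str = "alive"
    supportive_care_state: str = "pfs"
    ae_mode: str = "per_treated_cycle"

    def __post_init__(self) -> None:
        costs = (
            self.cost_palbociclib_cycle,
            self.cost_fulvestrant_250mg,
            self.cost_followup_cycle,
            self.cost_administration_cycle,
            self.cost_supportive_cycle,
            self.cost_terminal_once,
            *self.ae_costs.values(),
        )
        if any(c < 0 for c in costs):
            raise EconValidationError("costs must be non-negative")
        for arm, inc in self.ae_incidence.items():
            for ae, p in inc.items():
                if ae not in AE_NAMES:
                    raise EconValidationError(f"unknown adverse event {ae!r}")
                if not (0 <= p <= 1):
                    raise EconValidationError(f"incidence {arm}/{ae} outside [0,1]")
        for u in (self.utility_pfs, self.utility_pd):
            if not (0 <= u <= 1):
                raise EconValidationError("utilities must lie in [0,1]")
        if self.follow_up_state not in ACCRUAL_STATES:
            raise EconValidationError("follow_up_state must be pfs, pd or alive")
        if self.supportive_care_state not in ACCRUAL_STATES:
            raise EconValidationError("supportive_care_state must be pfs, pd or alive")
        if self.ae_mode not in AE_MODES:
            raise EconValidationError("ae_mode must be per_treated_cycle or entry_once")

    def replace(self, **kw) -> "EconInputs":
        return replace(self, **kw)


@dataclass(frozen=True)
class ArmOutcome:
    """Discounted totals for one arm, with an additive cost breakdown."""

    arm: str
    total_cost: float
    total_qaly: float
    cost_breakdown: Mapping[str, float]

    def __post_init__(self) -> None:
        if abs(sum(self.cost_breakdown.values()) - self.total_cost) > 1e-6:
            raise EconValidationError("cost breakdown does not sum to total")
        if self.total_qaly < 0:
            raise EconValidationError("total QALYs must be non-negative")


@dataclass(frozen=True)
class Comparison:
    """Incremental cost, incremental QALYs and the ICER (or a dominance flag)."""

    delta_cost: float
    delta_qaly: float
    icer: float | None
    dominance: str | None = None

    def cost_effective_at(self, wtp: float) -> bool:
        """Positive net monetary benefit at the given WTP threshold."""
        return self.delta_qaly * wtp - self.delta_cost > 0


def ae_expected_cost(inputs: EconInputs, arm: str) -> float:
    """Incidence-weighted AE management cost for one arm (USD per patient).

    The dot product of the arm's grade >= 3 incidences with the per-event
    management costs; events absent from an arm's incidence table cost 0.
    """
    if arm not in inputs.ae_incidence:
        raise EconValidationError(f"unknown arm {arm!r}")
    inc = inputs.ae_incidence[arm]
    return float(sum(inc[ae] * inputs.ae_costs[ae] for ae in inc))


def _state_credit(credits: np.ndarray, state: str) -> np.ndarray:
    if state == "pfs":
        return credits[:, 0]
    if state == "pd":
        return credits[:, 1]
    return credits[:, 0] + credits[:, 1]


def cycle_costs(
    trace: CohortTrace,
    inputs: EconInputs,
    schedule: DosingSchedule,
    settings: ModelSettings,
) -> ArmOutcome:
    """Discounted total cost for one arm with a per-category breakdown.

    Per-cycle costs are weighted by half-cycle-corrected state membership and
    discounted at the end of each cycle; terminal care attaches to incident
    deaths without half-cycle correction.
    """
    arm = trace.arm_label
    if arm not in inputs.ae_incidence:
        raise EconValidationError(f"trace arm {arm!r} has no AE incidence row")
    credits = half_cycle_correct(trace)
    if np.any(credits < -1e-12):
        raise EconValidationError("negative state membership")
    n = credits.shape[0]
    cycles = np.arange(1, n + 1)
    df = np.asarray(discount_factor(settings, cycles))
    pfs = credits[:, 0]

    breakdown: dict[str, float] = {}
    if arm == "palbociclib":
        breakdown["palbociclib"] = float(
            np.sum(df * inputs.cost_palbociclib_cycle * pfs)
        )
    else:
        breakdown["palbociclib"] = 0.0
    admins = np.array(
        [schedule.fulvestrant_administrations(int(t)) for t in cycles], dtype=float
    )
    fulv_per_cycle = (
        admins * schedule.fulvestrant_vials_per_admin * inputs.cost_fulvestrant_250mg
    )
    breakdown["fulvestrant"] = float(np.sum(df * fulv_per_cycle * pfs))
    breakdown["administration"] = float(
        np.sum(df * inputs.cost_administration_cycle * pfs)
    )
    breakdown["follow_up"] = float(
        np.sum(df * inputs.cost_followup_cycle * _state_credit(credits, inputs.follow_up_state))
    )
    breakdown["supportive_care"] = float(
        np.sum(
            df
            * inputs.cost_supportive_cycle
            * _state_credit(credits, inputs.supportive_care_state)
        )
    )
    ae = ae_expected_cost(inputs, arm)
    if inputs.ae_mode == "per_treated_cycle":
        breakdown["adverse_events"] = float(np.sum(df * ae * pfs))
    else:
        breakdown["adverse_events"] = float(ae * df[0])
    breakdown["terminal_care"] = float(
        np.sum(df * inputs.cost_terminal_once * trace.new_deaths())
    )
    total = float(sum(breakdown.values()))
    qaly = cycle_qalys(trace, inputs, settings)
    return ArmOutcome(arm=arm, total_cost=total, total_qaly=qaly, cost_breakdown=breakdown)


def cycle_qalys(
    trace: CohortTrace, inputs: EconInputs, settings: ModelSettings
) -> float:
    """Discounted QALYs: per-cycle utility-weighted membership in year units."""
    credits = half_cycle_correct(trace)
    n = credits.shape[0]
    df = np.asarray(discount_factor(settings, np.arange(1, n + 1)))
    per_cycle = inputs.utility_pfs * credits[:, 0] + inputs.utility_pd * credits[:, 1]
    return float(np.sum(df * per_cycle) * settings.cycle_fraction_of_year)


def compare(a: ArmOutcome, b: ArmOutcome) -> Comparison:
    """Incremental comparison of arm ``a`` against reference arm ``b``."""
    dc = a.total_cost - b.total_cost
    dq = a.total_qaly - b.total_qaly
    if dq == 0:
        return Comparison(dc, dq, None, dominance="undefined")
    if dq > 0 and dc <= 0:
        return Comparison(dc, dq, dc / dq, dominance="dominant")
    if dq < 0 and dc >= 0:
        return Comparison(dc, dq, dc / dq, dominance="dominated")
    return Comparison(dc, dq, dc / dq, dominance=None)
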