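"""Configuration, the end-to-end two-arm pipeline, and report assembly.

A single YAML configuration holds everything the analysis needs: global model
settings, per-arm parametric survival curves for PFS and OS, the economic
parameter table (base value, DSA bounds and PSA distribution per parameter),
cost-accrual policy, WTP thresholds and PSA settings. The shipped default
(:func:`default_config`) encodes the published model inputs for palbociclib +
fulvestrant versus placebo + fulvestrant.

The pipeline per arm is: build per-cycle transition matrices -> run the cohort
trace -> half-cycle-corrected discounted costs and QALYs -> incremental
comparison. Because survival parameters carry no sampling distributions, the
cohort traces are fixed across DSA/PSA re-evaluations and are computed once.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    CohortTrace,
    ModelSettings,
    build_transitions,
    run_cohort,
)
from .economics import (
    AE_NAMES,
    ARMS,
    ArmOutcome,
    Comparison,
    DosingSchedule,
    EconInputs,
    EconValidationError,
    compare,
    cycle_costs,
)
from .sensitivity import (
    CEACCurve,
    ParameterSpec,
    ceac,
    one_way_dsa,
    run_psa,
    tornado_rank,
)
from .survival import ParametricSurvivalModel

logger = logging.getLogger(__name__)

INTERVENTION, REFERENCE = ARMS  # palbociclib, placebo

_COST_FIELDS = {
    "cost_palbociclib_cycle",
    "cost_fulvestrant_250mg",
    "cost_followup_cycle",
    "cost_administration_cycle",
    "cost_supportive_cycle",
    "cost_terminal_once",
}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class AnalysisConfig:
    settings: ModelSettings
    arms: Mapping[str, Mapping[str, ParametricSurvivalModel]]  # arm -> {pfs, os}
    econ: EconInputs
    schedule: DosingSchedule
    parameters: tuple[ParameterSpec, ...]
    wtp_thresholds: tuple[float, ...]
    ceac_max: float
    ceac_step: float
    psa_n_draws: int
    psa_seed: int
    rmb_per_usd: float

    def parameter(self, name: str) -> ParameterSpec:
        for p in self.parameters:
            if p.name == name:
                return p
        raise ConfigError(f"unknown parameter {name!r}")

    @property
    def ceac_grid(self) -> np.ndarray:
        return np.arange(0.0, self.ceac_max + self.ceac_step / 2, self.ceac_step)


def apply_overrides(
    inputs: EconInputs,
    settings: ModelSettings | None,
    params: Mapping[str, float],
) -> tuple[EconInputs, ModelSettings | None]:
    """Build (EconInputs, ModelSettings) with named parameters replaced.

    Names: the EconInputs cost fields verbatim; ``cost_ae_<event>``;
    ``inc_<arm>_<event>``; ``utility_pfs``/``utility_pd``; ``discount_rate``.
    """
    kw: dict = {}
    ae_costs = dict(inputs.ae_costs)
    ae_inc = {arm: dict(v) for arm, v in inputs.ae_incidence.items()}
    for name, value in params.items():
        if name in _COST_FIELDS or name in ("utility_pfs", "utility_pd"):
            kw[name] = value
        elif name.startswith("cost_ae_"):
            ae = name.removeprefix("cost_ae_")
            if ae not in AE_NAMES:
                raise ConfigError(f"unknown adverse event in {name!r}")
            ae_costs[ae] = value
        elif name.startswith("inc_"):
            arm, _, ae = name.removeprefix("inc_").partition("_")
            if arm not in ae_inc or ae not in ae_inc[arm]:
                raise ConfigError(f"unknown incidence parameter {name!r}")
            ae_inc[arm][ae] = value
        elif name == "discount_rate":
            if settings is not None:
                settings = settings.with_discount(value)
        else:
            raise ConfigError(f"unknown parameter {name!r}")
    new_inputs = inputs.replace(ae_costs=ae_costs, ae_incidence=ae_inc, **kw)
    if new_inputs.utility_pd > new_inputs.utility_pfs:
        raise EconValidationError("utilities: PD utility exceeds PFS utility")
    return new_inputs, settings


def psa_constraint(params: Mapping[str, float]) -> bool:
    """Joint-draw validity: utility ordering preserved, discount non-negative."""
    ok = True
    if "utility_pfs" in params and "utility_pd" in params:
        ok &= params["utility_pd"] < params["utility_pfs"]
    if "discount_rate" in params:
        ok &= params["discount_rate"] >= 0
    return bool(ok)


class Pipeline:
    """Two-arm model with traces precomputed (survival parameters are fixed)."""

    def __init__(self, config: AnalysisConfig):
        self.config = config
        self.traces: dict[str, CohortTrace] = {}
        for arm, curves in config.arms.items():
            tm = build_transitions(curves["pfs"], curves["os"], config.settings)
            self.traces[arm] = run_cohort(tm, config.settings, arm_label=arm)

    def outcomes(
        self, overrides: Mapping[str, float] | None = None
    ) -> tuple[dict[str, ArmOutcome], Comparison]:
        inputs, settings = self.config.econ, self.config.settings
        if overrides:
            inputs, settings = apply_overrides(inputs, settings, overrides)
        out = {
            arm: cycle_costs(trace, inputs, self.config.schedule, settings)
            for arm, trace in self.traces.items()
        }
        return out, compare(out[INTERVENTION], out[REFERENCE])

    def evaluate(self, overrides: Mapping[str, float] | None = None) -> Comparison:
        return self.outcomes(overrides)[1]


# -- configuration I/O --------------------------------------------------------

_TOP_KEYS = {"settings", "arms", "accrual", "parameters", "wtp", "psa", "currency"}


def _require(mapping: Mapping, keys: set[str], where: str) -> None:
    unknown = set(mapping) - keys
    if unknown:
        raise ConfigError(f"{where}: unknown key(s) {sorted(unknown)}")
    missing = keys - set(mapping)
    if missing:
        raise ConfigError(f"{where}: missing key(s) {sorted(missing)}")


def config_from_dict(raw: Mapping) -> AnalysisConfig:
    _require(raw, _TOP_KEYS, "config")
    s = raw["settings"]
    _require(
        s,
        {"cycle_length_days", "horizon_years", "background_mortality_annual", "background_mode"},
        "settings",
    )
    params = []
    for p in raw["parameters"]:
        _require(p, {"name", "base", "lower", "upper", "distribution"}, "parameters")
        try:
            params.append(ParameterSpec(**p))
        except ValueError as exc:
            raise ConfigError(f"parameters: {exc}") from exc
    names = [p.name for p in params]
    if len(set(names)) != len(names):
        raise ConfigError("parameters: duplicate names")
    by_name = {p.name: p for p in params}
    if "discount_rate" not in by_name:
        raise ConfigError("parameters: discount_rate is required")
    try:
        settings = ModelSettings(
            cycle_length_days=float(s["cycle_length_days"]),
            horizon_years=float(s["horizon_years"]),
            discount_rate_annual=float(by_name["discount_rate"].base),
            background_mortality_annual=float(s["background_mortality_annual"]),
            background_mode=str(s["background_mode"]),
        )
    except ValueError as exc:
        raise ConfigError(f"settings: {exc}") from exc

    arms = {}
    _require(raw["arms"], set(ARMS), "arms")
    for arm, curves in raw["arms"].items():
        _require(curves, {"pfs", "os"}, f"arms.{arm}")
        arms[arm] = {}
        for endpoint, c in curves.items():
            keys = {"family", "scale", "shape"} | (
                {"extra_shape"} if "extra_shape" in c else set()
            )
            _require(c, keys, f"arms.{arm}.{endpoint}")
            try:
                arms[arm][endpoint] = ParametricSurvivalModel(**c)
            except ValueError as exc:
                raise ConfigError(f"arms.{arm}.{endpoint}: {exc}") from exc

    accrual = raw["accrual"]
    _require(accrual, {"follow_up_state", "supportive_care_state", "ae_mode"}, "accrual")

    def base(name: str) -> float:
        return by_name[name].base

    try:
        econ = EconInputs(
            cost_palbociclib_cycle=base("cost_palbociclib_cycle"),
            cost_fulvestrant_250mg=base("cost_fulvestrant_250mg"),
            cost_followup_cycle=base("cost_followup_cycle"),
            cost_administration_cycle=base("cost_administration_cycle"),
            cost_supportive_cycle=base("cost_supportive_cycle"),
            cost_terminal_once=base("cost_terminal_once"),
            ae_costs={ae: base(f"cost_ae_{ae}") for ae in AE_NAMES},
            ae_incidence={
                arm: {
                    ae: base(f"inc_{arm}_{ae}")
                    for ae in AE_NAMES
                    if f"inc_{arm}_{ae}" in by_name
                }
                for arm in ARMS
            },
            utility_pfs=base("utility_pfs"),
            utility_pd=base("utility_pd"),
            **accrual,
        )
    except KeyError as exc:
        raise ConfigError(f"parameters: missing {exc}") from exc
    except ValueError as exc:
        raise ConfigError(f"economic inputs: {exc}") from exc

    wtp = raw["wtp"]
    _require(wtp, {"thresholds", "ceac_max", "ceac_step"}, "wtp")
    psa = raw["psa"]
    _require(psa, {"n_draws", "seed"}, "psa")
    cur = raw["currency"]
    _require(cur, {"unit", "rmb_per_usd"}, "currency")

    return AnalysisConfig(
        settings=settings,
        arms=arms,
        econ=econ,
        schedule=DosingSchedule(),
        parameters=tuple(params),
        wtp_thresholds=tuple(float(w) for w in wtp["thresholds"]),
        ceac_max=float(wtp["ceac_max"]),
        ceac_step=float(wtp["ceac_step"]),
        psa_n_draws=int(psa["n_draws"]),
        psa_seed=int(psa["seed"]),
        rmb_per_usd=float(cur["rmb_per_usd"]),
    )


def config_to_dict(config: AnalysisConfig) -> dict:
    s = config.settings
    arms = {}
    for arm, curves in config.arms.items():
        arms[arm] = {}
        for endpoint, m in curves.items():
            d = {"family": m.family, "scale": m.scale, "shape": m.shape}
            if m.extra_shape is not None:
                d["extra_shape"] = m.extra_shape
            arms[arm][endpoint] = d
    return {
        "settings": {
            "cycle_length_days": s.cycle_length_days,
            "horizon_years": s.horizon_years,
            "background_mortality_annual": s.background_mortality_annual,
            "background_mode": s.background_mode,
        },
        "arms": arms,
        "accrual": {
            "follow_up_state": config.econ.follow_up_state,
            "supportive_care_state": config.econ.supportive_care_state,
            "ae_mode": config.econ.ae_mode,
        },
        "parameters": [
            {
                "name": p.name,
                "base": p.base,
                "lower": p.lower,
                "upper": p.upper,
                "distribution": p.distribution,
            }
            for p in config.parameters
        ],
        "wtp": {
            "thresholds": list(config.wtp_thresholds),
            "ceac_max": config.ceac_max,
            "ceac_step": config.ceac_step,
        },
        "psa": {"n_draws": config.psa_n_draws, "seed": config.psa_seed},
        "currency": {"unit": "USD", "rmb_per_usd": config.rmb_per_usd},
    }


def load_config(path: str | Path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return config_from_dict(raw)


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def default_config() -> AnalysisConfig:
    """The shipped configuration with the published model inputs."""
    text = resources.files("palbocea.data").joinpath("default.yaml").read_text()
    return config_from_dict(yaml.safe_load(text))


def config_hash(config: AnalysisConfig) -> str:
    blob = json.dumps(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# -- report assembly ----------------------------------------------------------

def base_case_frame(
    outcomes: Mapping[str, ArmOutcome], comparison: Comparison
) -> pd.DataFrame:
    rows = []
    for arm in (INTERVENTION, REFERENCE):
        o = outcomes[arm]
        rows.append(
            {
                "arm": arm,
                "cost_usd": o.total_cost,
                "qalys": o.total_qaly,
                **{f"cost_{k}": v for k, v in o.cost_breakdown.items()},
            }
        )
    df = pd.DataFrame(rows)
    df["delta_cost"] = [comparison.delta_cost, np.nan]
    df["delta_qaly"] = [comparison.delta_qaly, np.nan]
    df["icer"] = [comparison.icer, np.nan]
    return df


def run_base_case(
    config: AnalysisConfig, outdir: str | Path | None = None
) -> tuple[Comparison, dict[str, ArmOutcome], dict[str, CohortTrace]]:
    """Base-case pipeline; optionally write the trace/summary artifacts."""
    pipe = Pipeline(config)
    outcomes, comparison = pipe.outcomes()
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        base_case_frame(outcomes, comparison).to_csv(
            outdir / "base_case.csv", index=False
        )
        for arm, trace in pipe.traces.items():
            trace.to_frame(config.settings).to_csv(
                outdir / f"trace_{arm}.csv", index=False
            )
        (outdir / "base_case_summary.txt").write_text(
            _summary_text(config, outcomes, comparison)
        )
    return comparison, outcomes, pipe.traces


def _summary_text(config, outcomes, comparison) -> str:
    lines = [
        "Base-case results (discounted)",
        f"# config {config_hash(config)}  cycles {config.settings.n_cycles}  "
        f"cycle {config.settings.cycle_length_days:g} d  "
        f"discount {config.settings.discount_rate_annual:.2%}/y",
        "",
    ]
    for arm in (INTERVENTION, REFERENCE):
        o = outcomes[arm]
        lines.append(f"{arm:>12s}: cost ${o.total_cost:,.2f}  QALYs {o.total_qaly:.4f}")
    lines += [
        "",
        f"incremental cost  ${comparison.delta_cost:,.2f}",
        f"incremental QALYs {comparison.delta_qaly:.4f}",
        f"ICER              "
        + (f"${comparison.icer:,.2f}/QALY" if comparison.icer is not None else "undefined"),
    ]
    for wtp in config.wtp_thresholds:
        verdict = "cost-effective" if comparison.cost_effective_at(wtp) else "not cost-effective"
        lines.append(f"at WTP ${wtp:,.2f}/QALY: {verdict}")
    return "\n".join(lines) + "\n"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_analysis(
    config: AnalysisConfig,
    outdir: str | Path,
    seed: int | None = None,
    make_plots: bool = True,
) -> dict:
    """Base case + one-way DSA + PSA + CEAC, with a checksummed results index.

    Artifacts: base_case.csv, per-arm traces, dsa_tornado.csv, psa_scatter.csv,
    ceac.csv, plots (optional), summary text, run log with the seed and config
    hash. A stage failure is recorded in error_manifest.json; completed
    artifacts are kept.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.psa_seed if seed is None else int(seed)
    t0 = time.time()
    errors: dict[str, str] = {}
    timings: dict[str, float] = {}
    pipe = Pipeline(config)

    def stage(name, fn):
        t = time.time()
        try:
            return fn()
        except Exception as exc:
            logger.exception("stage %s failed", name)
            errors[name] = f"{type(exc).__name__}: {exc}"
            return None
        finally:
            timings[name] = round(time.time() - t, 3)

    comparison = outcomes = None

    def _base():
        nonlocal comparison, outcomes
        comparison, outcomes, _ = run_base_case(config, outdir)

    stage("base_case", _base)

    def _dsa():
        dsa = one_way_dsa(config.parameters, pipe.evaluate)
        ranked = tornado_rank(dsa)
        ranked.to_csv(outdir / "dsa_tornado.csv", index=False)
        if make_plots:
            from .plots import tornado_plot

            base_icer = comparison.icer if comparison else None
            tornado_plot(ranked, base_icer, outdir / "tornado.png")
        return ranked

    ranked = stage("dsa", _dsa)

    def _psa():
        samples = run_psa(
            config.parameters, pipe.evaluate, config.psa_n_draws, seed, psa_constraint
        )
        samples.to_csv(outdir / "psa_scatter.csv", index=False)
        curve = ceac(samples, config.ceac_grid)
        curve.to_frame().to_csv(outdir / "ceac.csv", index=False)
        if make_plots:
            from .plots import ceac_plot, scatter_plot

            scatter_plot(samples, config.wtp_thresholds, outdir / "psa_scatter.png")
            ceac_plot(curve, config.wtp_thresholds, outdir / "ceac.png")
        return samples, curve

    psa_out = stage("psa", _psa)

    index = {
        "seed": seed,
        "config_hash": config_hash(config),
        "n_cycles": config.settings.n_cycles,
        "timings_s": timings,
        "files": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name not in ("results_index.json", "error_manifest.json")
        },
    }
    (outdir / "results_index.json").write_text(json.dumps(index, indent=1))
    if errors:
        (outdir / "error_manifest.json").write_text(json.dumps(errors, indent=1))
    logger.info("full analysis done in %.1fs (errors: %s)", time.time() - t0, errors or "none")
    return {
        "comparison": comparison,
        "outcomes": outcomes,
        "dsa": ranked,
        "psa": psa_out[0] if psa_out else None,
        "ceac": psa_out[1] if psa_out else None,
        "index": index,
        "errors": errors,
    }
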