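"""Matplotlib figures: tornado diagram, PSA scatter, CEAC."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .sensitivity import CEACCurve


def tornado_plot(ranked: pd.DataFrame, base_icer: float | None, path: str | Path, top: int = 15) -> None:
    df = ranked.head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(df) + 1.5))
    lo = df[["icer_at_lower", "icer_at_upper"]].min(axis=1)
    hi = df[["icer_at_lower", "icer_at_upper"]].max(axis=1)
    ax.barh(df["parameter"], hi - lo, left=lo, color="#4878cf", alpha=0.85)
    if base_icer is not None:
        ax.axvline(base_icer, color="k", lw=1, ls="--", label="base-case ICER")
        ax.legend(loc="lower right", fontsize=8)
    ax.set_xlabel("ICER ($/QALY)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def scatter_plot(samples: pd.DataFrame, wtp_thresholds, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(samples["delta_qaly"], samples["delta_cost"], s=6, alpha=0.4)
    xs = [0, samples["delta_qaly"].max() * 1.05]
    for wtp in wtp_thresholds:
        ax.plot(xs, [wtp * x for x in xs], lw=1, ls="--", label=f"WTP ${wtp:,.0f}/QALY")
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental cost ($)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ceac_plot(curve: CEACCurve, wtp_thresholds, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.wtp, curve.probability, lw=1.5)
    for wtp in wtp_thresholds:
        ax.axvline(wtp, color="grey", lw=1, ls="--")
    ax.set_xlabel("willingness-to-pay threshold ($/QALY)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
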