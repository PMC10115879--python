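"""Figure-style panels: summary trajectories and trials-required curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .reliability import ReliabilityCurve, ReliabilitySummary


def plot_summaries(summaries: list[ReliabilitySummary], path: str | Path) -> None:
    """Conflict effect, trait SD, noise SD and trait precision against
    cumulative trial count, with 95% credible bands."""
    summaries = sorted(summaries, key=lambda s: s.aggregation_level)
    x = np.array([s.aggregation_level for s in summaries])
    panels = [
        ("conflict_effect_log", "conflict effect (log)"),
        ("sigma_T", "trait SD (log)"),
        ("sigma_N", "noise SD (log)"),
        ("eta", "trait precision"),
    ]
    fig, axes = plt.subplots(1, len(panels), figsize=(4 * len(panels), 3.2), sharex=True)
    for ax, (attr, label) in zip(axes, panels):
        med = [getattr(s, attr).median for s in summaries]
        lo = [getattr(s, attr).lower for s in summaries]
        hi = [getattr(s, attr).upper for s in summaries]
        ax.fill_between(x, lo, hi, color="0.8")
        ax.plot(x, med, color="k")
        ax.set_xlabel("trials aggregated")
        ax.set_title(label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_reliability_curve(curve: ReliabilityCurve, path: str | Path) -> None:
    """Trials required vs. trials available with the identity line and
    dropped verticals at the interpolated crossings."""
    fig, ax = plt.subplots(figsize=(5, 4))
    x = curve.levels.astype(float)
    shades = {0.8: "0.85", 0.9: "0.7"}
    for r in curve.targets:
        ax.fill_between(x, curve.required_lower[r], curve.required_upper[r],
                        color=shades.get(r, "0.8"))
        ax.plot(x, curve.required_median[r], color="k")
        cross = curve.crossings[r]
        if cross is not None:
            ax.plot([cross, cross], [0, cross], linestyle=":", color="k")
            ax.annotate(f"{cross:.0f}", (cross, 0), textcoords="offset points",
                        xytext=(2, 4), fontsize=8)
    lim = max(x.max(), max(np.max(curve.required_median[r]) for r in curve.targets))
    ax.plot([0, lim], [0, lim], linestyle="--", color="k", linewidth=0.8)
    ax.set_xlim(0, x.max() * 1.05)
    ax.set_ylim(0, lim * 1.05)
    ax.set_xlabel("trials available")
    ax.set_ylabel("trials required")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
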