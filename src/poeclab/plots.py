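"""Figure exports: session box-whisker plots, stacked proportions, median trends."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["box_whisker_by_condition", "stacked_proportions", "median_trend"]

_CONDITION_COLORS = {"free": "#e6b422", "on": "#3b6fb6", "off": "#c0392b", "fixed": "#2e8b57"}
_LABEL_COLORS = {"increased": "#c0392b", "decreased": "#3b6fb6", "other": "#9e9e9e"}


def box_whisker_by_condition(
    sessions: pd.DataFrame,
    metric: str,
    path: str | Path,
    ylabel: str = "",
    conditions: tuple[str, ...] = ("free", "on", "off"),
) -> None:
    """Box-and-whisker per condition: median line, 25/75% box, min/max whiskers."""
    present = [c for c in conditions if c in set(sessions["condition"])]
    data = [sessions.loc[sessions["condition"] == c, metric].to_numpy() for c in present]
    fig, ax = plt.subplots(figsize=(4, 3))
    bp = ax.boxplot(data, tick_labels=present, whis=(0, 100), patch_artist=True)
    for patch, cond in zip(bp["boxes"], present):
        patch.set_facecolor(_CONDITION_COLORS.get(cond, "#cccccc"))
        patch.set_alpha(0.6)
    ax.set_ylabel(ylabel or metric)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def stacked_proportions(proportions: pd.DataFrame, path: str | Path) -> None:
    """Stacked percentage bars of increased/decreased/other per comparison."""
    fig, ax = plt.subplots(figsize=(4, 3))
    x = np.arange(len(proportions))
    bottom = np.zeros(len(proportions))
    for label in ("increased", "decreased", "other"):
        vals = proportions[f"pct_{label}"].to_numpy()
        ax.bar(x, vals, bottom=bottom, color=_LABEL_COLORS[label], label=label, width=0.6)
        bottom += vals
    ax.set_xticks(x)
    ax.set_xticklabels(proportions["comparison"])
    ax.set_ylabel("% of neurons")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def median_trend(trends: pd.DataFrame, path: str | Path) -> None:
    """Per-neuron median fluorescence rate across on -> off -> fixed.

    Consistent-trend neurons are coloured (up red, down blue); others grey.
    """
    fig, ax = plt.subplots(figsize=(4, 3))
    colors = {"consistent_up": "#c0392b", "consistent_down": "#3b6fb6", "none": "#d0d0d0"}
    for _, row in trends.iterrows():
        ax.plot(
            [0, 1, 2],
            [row["median_on"], row["median_off"], row["median_fixed"]],
            color=colors.get(row["trend"], "#d0d0d0"),
            alpha=0.8 if row["trend"] != "none" else 0.3,
            lw=1.2 if row["trend"] != "none" else 0.6,
        )
    ax.set_xticks([0, 1, 2])
    ax.set_xticklabels(["on", "off", "fixed"])
    ax.set_ylabel("median fluorescence rate (ΔF/F)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
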