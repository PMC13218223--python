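"""Diagnostic plots: coefficient-interval (forest) plot and binned
empirical-logit scatterplots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .simulate import empirical_logit_groups

__all__ = ["plot_coefficient_intervals", "plot_empirical_logits"]


def plot_coefficient_intervals(intervals, path) -> None:
    """Horizontal error-bar plot of the Wald intervals, zero line dashed."""
    rows = intervals.rows
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(rows) + 1.5))
    ypos = np.arange(len(rows))[::-1]
    ax.errorbar(
        rows["estimate"], ypos,
        xerr=[rows["estimate"] - rows["lower"], rows["upper"] - rows["estimate"]],
        fmt="o", capsize=3,
    )
    ax.axvline(0.0, linestyle="--", linewidth=1)
    ax.set_yticks(ypos, rows["parameter"])
    ax.set_xlabel("coefficient")
    ax.set_title(f"{intervals.level:.0%} Wald confidence intervals")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_empirical_logits(data: pd.DataFrame, y, path, n_groups: int = 15) -> None:
    """Grid of binned empirical-logit scatterplots, one panel per predictor."""
    cols = list(data.columns)
    fig, axes = plt.subplots(1, len(cols), figsize=(4 * len(cols), 3.2), squeeze=False)
    for ax, col in zip(axes[0], cols):
        tab = empirical_logit_groups(data[col], y, n_groups)
        ax.scatter(tab["midpoint"], tab["empirical_logit"])
        ax.set_xlabel(col)
        ax.set_ylabel("empirical logit")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
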