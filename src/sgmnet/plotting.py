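"""Plots for age trajectories and network properties."""

from __future__ import annotations

import numpy as np

from .stats import TrajectoryFit

__all__ = ["plot_age_trajectory"]

_GROUP_COLORS = {"F": "#c0392b", "M": "#2980b9", "all": "#333333"}


def plot_age_trajectory(
    fit: TrajectoryFit,
    table=None,
    response: str | None = None,
    ax=None,
    z: float = 1.96,
):
    """Fitted age-trajectory curves with confidence bands per group.

    When ``table`` and ``response`` are given, the per-subject values are
    overlaid as a scatter.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for g in fit.groups:
        color = _GROUP_COLORS.get(g, None)
        lo, hi = fit.band(g, z=z)
        ax.fill_between(fit.age_grid, lo, hi, alpha=0.2, color=color, lw=0)
        ax.plot(fit.age_grid, fit.fitted[g], color=color, label=g)
        if table is not None and response is not None:
            sub = table if g == "all" else table.loc[table["sex"] == g]
            ax.scatter(sub["age"], sub[response], s=8, alpha=0.4, color=color)
    ax.set_xlabel("age (years)")
    if response:
        ax.set_ylabel(response)
    ax.legend(title="sex" if "F" in fit.groups else None, frameon=False)
    return ax
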