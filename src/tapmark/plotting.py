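"""Group-mean bar charts with SEM error bars for tapping parameters and
striatal uptake — the figures a three-group comparison is usually shown as."""

from __future__ import annotations

import numpy as np
import pandas as pd

GROUP_ORDER = ("RBD-MMI", "RBD-N", "HC")


def _grouped_bars(ax, stats: pd.DataFrame, title: str, ylabel: str) -> None:
    groups = [g for g in GROUP_ORDER if g in set(stats["group"])]
    xs = np.arange(len(groups))
    means = [stats.loc[stats.group == g, "mean"].iloc[0] for g in groups]
    sems = [stats.loc[stats.group == g, "sem"].iloc[0] for g in groups]
    ax.bar(xs, means, yerr=sems, capsize=4, color=["#c44e52", "#dd8452", "#4c72b0"][: len(groups)])
    ax.set_xticks(xs)
    ax.set_xticklabels(groups)
    ax.set_title(title)
    ax.set_ylabel(ylabel)


def plot_tapping_group_means(tap_summaries: pd.DataFrame, groups: pd.Series, axes=None):
    """3x2 panel (parameter x side) of group means of the tapping summaries.

    ``groups`` maps subject_id -> analysis group (see
    ``report.assigned_groups``).  Returns the matplotlib figure.
    """
    import matplotlib.pyplot as plt

    from .classify import SIDES, VALUE_COLUMNS

    df = tap_summaries.merge(groups.rename("group"), left_on="subject_id", right_index=True)
    if axes is None:
        fig, axes = plt.subplots(3, 2, figsize=(8, 10), constrained_layout=True)
    else:
        fig = axes.flat[0].figure
    units = {"amplitude": "mm", "open_speed": "m/s", "close_speed": "m/s"}
    for row, (param, col) in enumerate(VALUE_COLUMNS.items()):
        for ci, side in enumerate(SIDES):
            sub = df[df["hand"] == side]
            stats = (
                sub.groupby("group")[col].agg(["mean", "sem"]).reset_index()
            )
            _grouped_bars(axes[row][ci], stats, f"{param} ({side})", units[param])
    return fig


def plot_uptake_group_means(group_means: pd.DataFrame, axes=None):
    """Bar panel per (region, side) from ``summarize_uptake``'s
    ``group_means`` table.  Returns the matplotlib figure."""
    import matplotlib.pyplot as plt

    combos = group_means[["region", "side"]].drop_duplicates().itertuples(index=False)
    combos = list(combos)
    if axes is None:
        fig, axes = plt.subplots(
            len(combos) // 2 or 1, 2, figsize=(8, 2.6 * (len(combos) // 2 or 1)),
            constrained_layout=True, squeeze=False,
        )
    else:
        fig = axes.flat[0].figure
    for ax, (region, side) in zip(np.ravel(axes), combos):
        stats = group_means[
            (group_means.region == region) & (group_means.side == side)
        ].rename(columns={"mean_sbr": "mean"})
        _grouped_bars(ax, stats, f"{region} ({side})", "SBR")
    return fig
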