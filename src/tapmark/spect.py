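"""Dopamine-transporter SPECT quantification.

Specific binding ratio (SBR) from volume-of-interest (VOI) mean counts,
with the cerebellum as the non-specific reference region::

    SBR = (striatal_counts - cerebellar_counts) / cerebellar_counts

and the left-right asymmetry index of a bilateral measure::

    AI = |R - L| / (R + L)

Striatal VOIs: caudate, anterior putamen and posterior putamen, each side.
Group summaries report means with SEM, the percent reduction of each
patient group relative to the healthy-control mean, and one-way ANOVA with
Tukey post-hoc comparisons per region/side and per asymmetry index.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import stats as _stats

STRIATAL_REGIONS = ("caudate", "ant_putamen", "post_putamen")
SIDES = ("R", "L")
CEREBELLUM = "cerebellum"


def compute_sbr(striatal_count, cerebellar_count):
    """Specific binding ratio; accepts scalars or arrays."""
    cereb = np.asarray(cerebellar_count, dtype=float)
    if np.any(cereb <= 0):
        raise ValueError("cerebellar count must be positive")
    out = (np.asarray(striatal_count, dtype=float) - cereb) / cereb
    return float(out) if out.ndim == 0 else out


def compute_asymmetry_index(right: float, left: float) -> float:
    """|R - L| / (R + L); NaN when R + L == 0.

    Negative inputs (possible for noisy SBR values) are clipped to zero
    with a warning so the index stays in [0, 1].
    """
    r, l = float(right), float(left)
    if r < 0 or l < 0:
        warnings.warn("negative uptake clipped to 0 before asymmetry index", RuntimeWarning)
        r, l = max(r, 0.0), max(l, 0.0)
    if r + l == 0:
        return float("nan")
    return abs(r - l) / (r + l)


def uptake_from_counts(voi_counts: pd.DataFrame) -> pd.DataFrame:
    """Per-subject SBR and asymmetry-index table from a long VOI-count table.

    ``voi_counts`` columns: subject_id, region, side, mean_count — six
    striatal rows plus one cerebellum row (side NA) per subject.

    Returns a long table with rows per (subject, region, side) carrying
    ``sbr``, plus per-(subject, region) rows with side ``AI`` carrying the
    asymmetry index in the same ``value`` layout: columns
    subject_id, region, side, sbr, asymmetry_index.
    """
    required = {"subject_id", "region", "side", "mean_count"}
    if not required <= set(voi_counts.columns):
        raise ValueError(f"VOI count table needs columns {sorted(required)}")
    rows = []
    for sid, grp in voi_counts.groupby("subject_id", sort=True):
        counts = grp.set_index(["region", "side"])["mean_count"]
        if counts.index.duplicated().any():
            raise ValueError(f"subject {sid!r}: duplicated VOI rows")
        cereb_key = [k for k in counts.index if k[0] == CEREBELLUM]
        if len(cereb_key) != 1:
            raise ValueError(f"subject {sid!r}: expected exactly one cerebellum row")
        cereb = float(counts[cereb_key[0]])
        sbr = {}
        for region in STRIATAL_REGIONS:
            for side in SIDES:
                if (region, side) not in counts.index:
                    raise ValueError(f"subject {sid!r}: expected one row for {region}/{side}")
                sbr[(region, side)] = compute_sbr(float(counts[(region, side)]), cereb)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ai = {
                region: compute_asymmetry_index(sbr[(region, "R")], sbr[(region, "L")])
                for region in STRIATAL_REGIONS
            }
        for region in STRIATAL_REGIONS:
            for side in SIDES:
                rows.append(
                    {
                        "subject_id": sid,
                        "region": region,
                        "side": side,
                        "sbr": sbr[(region, side)],
                        "asymmetry_index": ai[region],
                    }
                )
    return pd.DataFrame(rows)


def summarize_uptake(uptake: pd.DataFrame, subjects: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Group-level uptake summary.

    Returns dict of tables:

    - ``group_means``: per (region, side, group) mean SBR, SEM, n;
    - ``percent_diff``: per (region, side, patient group) percent reduction
      vs the HC mean, ``100 * (HC_mean - group_mean) / HC_mean``;
    - ``anova``: per (region, side) one-way ANOVA plus Tukey rows;
    - ``ai_anova``: same for the per-region asymmetry index.

    Groups with fewer than 2 subjects are excluded from testing, and their
    comparisons are absent from the tables.
    """
    df = uptake.merge(subjects[["subject_id", "group"]], on="subject_id", how="inner")
    counts = df.groupby("group")["subject_id"].nunique()
    usable = [g for g in counts.index if counts[g] >= 2]
    dropped = sorted(set(counts.index) - set(usable))
    if dropped:
        warnings.warn(f"groups with < 2 subjects excluded from comparison: {dropped}", RuntimeWarning)
    df = df[df["group"].isin(usable)]

    means_rows, pct_rows, anova_rows = [], [], []
    for (region, side), sub in df.groupby(["region", "side"], sort=True):
        stats = sub.groupby("group")["sbr"].agg(["mean", "sem", "count"])
        for g, r in stats.iterrows():
            means_rows.append(
                {
                    "region": region,
                    "side": side,
                    "group": g,
                    "mean_sbr": r["mean"],
                    "sem": r["sem"],
                    "n": int(r["count"]),
                }
            )
        if "HC" in stats.index:
            hc_mean = stats.loc["HC", "mean"]
            for g in stats.index:
                if g == "HC" or hc_mean == 0:
                    continue
                pct_rows.append(
                    {
                        "region": region,
                        "side": side,
                        "group": g,
                        "percent_lower_than_hc": 100.0 * (hc_mean - stats.loc[g, "mean"]) / hc_mean,
                    }
                )
        if len(stats) >= 2:
            res = _stats.anova_tukey(sub["sbr"].to_numpy(), sub["group"].to_numpy())
            anova_rows.extend(
                {"region": region, "side": side, **row} for row in _stats.comparison_rows(res)
            )

    ai = df[df["side"] == "R"][["subject_id", "region", "asymmetry_index", "group"]]
    ai_rows = []
    for region, sub in ai.groupby("region", sort=True):
        sub = sub.dropna(subset=["asymmetry_index"])
        if sub["group"].nunique() >= 2:
            res = _stats.anova_tukey(sub["asymmetry_index"].to_numpy(), sub["group"].to_numpy())
            ai_rows.extend({"region": region, **row} for row in _stats.comparison_rows(res))

    return {
        "group_means": pd.DataFrame(means_rows),
        "percent_diff": pd.DataFrame(pct_rows),
        "anova": pd.DataFrame(anova_rows),
        "ai_anova": pd.DataFrame(ai_rows),
    }
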