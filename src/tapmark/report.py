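"""Assembly of the study's result tables.

Given the stage outputs (subjects, tapping summaries, MMI classification,
uptake, FC contrasts, per-subject z-matrices), emits tidy tables:

- demographics / clinical-score group comparisons (ANOVA + Tukey, sex
  chi-square, disease-duration t-test, head-motion ANOVA);
- per-item UPDRS-III comparisons;
- polysomnography t-tests (RBD-MMI vs RBD-N);
- finger-tapping parameter comparisons by assigned group;
- uptake group means, percent differences vs HC, ANOVA/Tukey and
  asymmetry-index comparisons;
- FC group-contrast table;
- correlations of tapping parameters / UPDRS-III scores with contralateral
  striatal uptake (Pearson) and with significant FC pairs (partial
  correlation controlling age and sex).

No multiple-testing correction is applied across the correlation tables
(each entry is tested at two-tailed p < 0.05); this per-test convention is
deliberately minimal and is flagged in the docs as a caveat.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import stats as _stats
from .classify import SIDES, VALUE_COLUMNS
from .spect import STRIATAL_REGIONS, summarize_uptake

DEMOGRAPHIC_CONTINUOUS = [
    "age",
    "edinburgh_handedness",
    "updrs3_total",
    "mmse",
    "hads",
    "hads_anxiety",
    "hads_depression",
    "odor_identification",
    "rbdsq_j",
    "epworth",
    "pittsburgh",
    "head_motion_fd",
]

HAND_TO_ITEM = {"R": "updrs3_rt_finger_tapping", "L": "updrs3_lt_finger_tapping"}


def _anova_rows(values, group_labels, variable: str) -> list[dict]:
    """ANOVA+Tukey rows; groups with < 2 observations are dropped and the
    comparison is skipped (returned empty) when fewer than 2 groups remain
    or the variable is constant."""
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    keep = pd.Series(group_labels).groupby(pd.Series(group_labels)).transform("size") >= 2
    values, group_labels = values[keep.to_numpy()], group_labels[keep.to_numpy()]
    if len(values) == 0 or pd.unique(group_labels).size < 2:
        return []
    return _stats.comparison_rows(_stats.anova_tukey(values, group_labels, variable=variable))


def assigned_groups(subjects: pd.DataFrame, classification: pd.DataFrame | None) -> pd.Series:
    """Per-subject analysis group: HC stays HC; patients take the
    classifier's assignment (RBD-MMI / RBD-N) when available."""
    groups = subjects.set_index("subject_id")["group"].copy()
    if classification is not None and "assigned_group" in classification.columns:
        assigned = classification.set_index("subject_id")["assigned_group"]
        groups.loc[assigned.index] = assigned
    return groups


def demographics_table(subjects: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    df = subjects.set_index("subject_id").assign(analysis_group=groups)
    rows: list[dict] = []
    for var in DEMOGRAPHIC_CONTINUOUS:
        if var not in df.columns:
            continue
        sub = df.dropna(subset=[var])
        rows.extend(_anova_rows(sub[var], sub["analysis_group"], var))
    # sex distribution across the three groups
    counts = pd.crosstab(df["analysis_group"], df["sex"])
    if counts.shape[0] >= 2 and counts.shape[1] >= 2 and (counts.sum(axis=0) > 0).all():
        res = _stats.chi_square(counts.to_numpy(), variable="sex")
        res.groups = tuple(counts.index)
        rows.extend(_stats.comparison_rows([res]))
    # disease duration: patients only, two-sample t
    if "disease_duration" in df.columns:
        mmi = df[(df["analysis_group"] == "RBD-MMI")]["disease_duration"].dropna()
        rbdn = df[(df["analysis_group"] == "RBD-N")]["disease_duration"].dropna()
        if len(mmi) >= 2 and len(rbdn) >= 2:
            res = _stats.two_sample_t(mmi, rbdn, variable="disease_duration")
            res.groups = ("RBD-MMI", "RBD-N")
            rows.extend(_stats.comparison_rows([res]))
    return pd.DataFrame(rows)


def updrs_items_table(subjects: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    df = subjects.set_index("subject_id").assign(analysis_group=groups)
    items = [c for c in df.columns if c.startswith("updrs3_") and c != "updrs3_total"]
    rows: list[dict] = []
    for item in items:
        vals = df[item].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            rows.append(
                {"variable": item, "test": "anova", "groups": "", "statistic": 0.0,
                 "df": "", "p": 1.0, "note": "constant"}
            )
            continue
        rows.extend(_anova_rows(vals, df["analysis_group"], item))
    return pd.DataFrame(rows)


def psg_table(subjects: pd.DataFrame, groups: pd.Series, psg_columns: list[str]) -> pd.DataFrame:
    df = subjects.set_index("subject_id").assign(analysis_group=groups)
    rows: list[dict] = []
    for var in psg_columns:
        if var not in df.columns:
            continue
        mmi = df[df["analysis_group"] == "RBD-MMI"][var].dropna()
        rbdn = df[df["analysis_group"] == "RBD-N"][var].dropna()
        if len(mmi) < 2 or len(rbdn) < 2:
            continue
        res = _stats.two_sample_t(mmi, rbdn, variable=var)
        res.groups = ("RBD-MMI", "RBD-N")
        rows.extend(_stats.comparison_rows([res]))
    return pd.DataFrame(rows)


def tapping_table(tap_summaries: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    df = tap_summaries.merge(
        groups.rename("analysis_group"), left_on="subject_id", right_index=True
    )
    rows: list[dict] = []
    for param, col in VALUE_COLUMNS.items():
        for side in SIDES:
            sub = df[df["hand"] == side]
            rows.extend(_anova_rows(sub[col], sub["analysis_group"], f"{param}_{side}"))
    return pd.DataFrame(rows)


def uptake_correlations_table(
    tap_summaries: pd.DataFrame, subjects: pd.DataFrame, uptake: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlations of tapping parameters and UPDRS-III scores with
    contralateral striatal uptake, over all subjects with both measures."""
    subj = subjects.set_index("subject_id")
    wide_sbr = uptake.pivot_table(
        index="subject_id", columns=["region", "side"], values="sbr", aggfunc="first"
    )
    rows: list[dict] = []
    for hand in SIDES:
        striatal_side = _stats.contralateral_map(hand)
        hand_summ = tap_summaries[tap_summaries["hand"] == hand].set_index("subject_id")
        predictors: dict[str, pd.Series] = {
            f"{hand}_{param}": hand_summ[col] for param, col in VALUE_COLUMNS.items()
        }
        predictors["updrs3_total"] = subj["updrs3_total"]
        item = HAND_TO_ITEM[hand]
        if item in subj.columns:
            predictors[f"{hand}_finger_tapping_score"] = subj[item]
        for region in STRIATAL_REGIONS:
            if (region, striatal_side) not in wide_sbr.columns:
                continue
            sbr = wide_sbr[(region, striatal_side)]
            for name, series in predictors.items():
                pair = pd.concat([series, sbr], axis=1, keys=["x", "y"]).dropna()
                if len(pair) < 3 or pair["x"].nunique() < 2 or pair["y"].nunique() < 2:
                    continue
                res = _stats.pearson_correlation(
                    pair["x"], pair["y"], x_name=name, y_name=f"{striatal_side}_{region}"
                )
                rows.append(
                    {"x": res.x_name, "y": res.y_name, "r": res.r, "n": res.n, "p": res.p}
                )
    return pd.DataFrame(rows)


def fc_correlations_table(
    tap_summaries: pd.DataFrame,
    subjects: pd.DataFrame,
    fc_results: dict,
    contrast_table: pd.DataFrame,
    q: float = 0.05,
) -> pd.DataFrame:
    """Partial correlations (controlling age and sex) of tapping parameters
    and UPDRS-III finger-tapping scores with the Fisher-z values of FC
    pairs showing a significant group difference."""
    sig = contrast_table[contrast_table["p_fdr"] < q][["roi_1", "roi_2"]].drop_duplicates()
    if sig.empty:
        return pd.DataFrame(columns=["x", "roi_1", "roi_2", "r", "n", "p"])
    subj = subjects.set_index("subject_id")
    first = next(iter(fc_results.values()))
    label_idx = {lab: i for i, lab in enumerate(first.roi_labels)}
    rows: list[dict] = []
    predictors: dict[str, pd.Series] = {}
    for hand in SIDES:
        hand_summ = tap_summaries[tap_summaries["hand"] == hand].set_index("subject_id")
        for param, col in VALUE_COLUMNS.items():
            predictors[f"{hand}_{param}"] = hand_summ[col]
        item = HAND_TO_ITEM[hand]
        if item in subj.columns:
            predictors[f"{hand}_finger_tapping_score"] = subj[item]
    predictors["updrs3_total"] = subj["updrs3_total"]
    for _, pair_row in sig.iterrows():
        a, b = pair_row["roi_1"], pair_row["roi_2"]
        i, j = label_idx[a], label_idx[b]
        z = pd.Series(
            {sid: res.z_matrix[i, j] for sid, res in fc_results.items()}, name="z"
        )
        for name, series in predictors.items():
            data = pd.concat(
                [series.rename("x"), z, subj["age"], subj["sex"].map(_stats.SEX_CODES)],
                axis=1,
            ).dropna()
            if len(data) < 5 or data["x"].nunique() < 2 or data["z"].nunique() < 2:
                continue
            try:
                res = _stats.partial_correlation(
                    data["x"], data["z"], data[["age", "sex"]],
                    x_name=name, y_name=f"{a}~{b}", covariate_names=("age", "sex"),
                )
            except ValueError:
                continue
            rows.append(
                {"x": name, "roi_1": a, "roi_2": b, "r": res.r, "n": res.n, "p": res.p}
            )
    return pd.DataFrame(rows)


def build_report(
    subjects: pd.DataFrame,
    tap_summaries: pd.DataFrame | None = None,
    classification: pd.DataFrame | None = None,
    uptake: pd.DataFrame | None = None,
    fc_contrasts: pd.DataFrame | None = None,
    fc_results: dict | None = None,
    psg_columns: list[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Assemble every table the available stage outputs support.

    Missing stages skip their tables with a warning.  Returns a dict of
    table name -> DataFrame.
    """
    if psg_columns is None:
        psg_columns = [
            c for c in subjects.columns
            if c.endswith(("_min", "_pct", "_index")) or c in ("arousal_index",)
        ]
    groups = assigned_groups(subjects, classification)
    tables: dict[str, pd.DataFrame] = {
        "demographics": demographics_table(subjects, groups),
        "updrs_items": updrs_items_table(subjects, groups),
        "psg": psg_table(subjects, groups, psg_columns),
    }
    if tap_summaries is not None:
        tables["tapping"] = tapping_table(tap_summaries, groups)
    else:
        warnings.warn("tapping summaries missing; tapping table skipped", RuntimeWarning)
    if classification is not None:
        tables["classification"] = classification
    if uptake is not None:
        subj_groups = subjects[["subject_id"]].assign(group=groups.loc[subjects["subject_id"]].values)
        for name, tbl in summarize_uptake(uptake, subj_groups).items():
            tables[f"uptake_{name}"] = tbl
        if tap_summaries is not None:
            tables["correlations_uptake"] = uptake_correlations_table(
                tap_summaries, subjects, uptake
            )
    else:
        warnings.warn("uptake table missing; SPECT tables skipped", RuntimeWarning)
    if fc_contrasts is not None:
        tables["fc_contrasts"] = fc_contrasts
        if fc_results is not None and tap_summaries is not None:
            tables["correlations_fc"] = fc_correlations_table(
                tap_summaries, subjects, fc_results, fc_contrasts
            )
    else:
        warnings.warn("FC contrasts missing; FC tables skipped", RuntimeWarning)
    return tables
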