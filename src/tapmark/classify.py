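"""Normative 2-SD classification of mild motor impairment (MMI).

A normative model is fitted on healthy-control (HC) tapping summaries:
per parameter (amplitude, peak open speed, peak close speed) and per side
(R, L — sides are fitted independently because of hand dominance), the HC
mean and sample SD define a cutoff ``mean - 2*SD``.  A subject is MMI when
at least one of the six parameter values falls strictly below its cutoff.

The same construction applied to the per-cycle decrement slopes defines the
"progressive decrement" criterion: a slope strictly below the HC slope mean
minus 2 SD (slopes are negative; "below" means more steeply negative).
The two criteria are independent — a subject can be flagged on either.

Exposed statsmodels-style: ``NormativeTappingModel(hc_summaries).fit()``
returns :class:`NormativeTappingResults` which carries the normative table
and classifies new subjects.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

PARAMETERS = ("amplitude", "open_speed", "close_speed")
SIDES = ("R", "L")

VALUE_COLUMNS = {
    "amplitude": "mean_amplitude",
    "open_speed": "mean_peak_open_speed",
    "close_speed": "mean_peak_close_speed",
}
SLOPE_COLUMNS = {
    "amplitude": "slope_amplitude",
    "open_speed": "slope_open_speed",
    "close_speed": "slope_close_speed",
}


def _wide_summaries(summaries: pd.DataFrame) -> pd.DataFrame:
    """Pivot a per-recording summary table to one row per subject with
    ``<column>_<side>`` columns; subjects missing a hand get NaN there."""
    req = {"subject_id", "hand"} | set(VALUE_COLUMNS.values()) | set(SLOPE_COLUMNS.values())
    missing = req - set(summaries.columns)
    if missing:
        raise ValueError(f"summary table missing columns: {sorted(missing)}")
    cols = list(VALUE_COLUMNS.values()) + list(SLOPE_COLUMNS.values())
    wide = summaries.pivot_table(index="subject_id", columns="hand", values=cols, aggfunc="first")
    wide.columns = [f"{col}_{side}" for col, side in wide.columns]
    for col in cols:
        for side in SIDES:
            if f"{col}_{side}" not in wide.columns:
                wide[f"{col}_{side}"] = np.nan
    return wide


@dataclass
class NormativeTappingResults:
    """Fitted normative model: per-parameter, per-side HC statistics.

    ``params`` is indexed by (parameter, side) with columns
    ``value_mean, value_sd, value_cutoff, slope_mean, slope_sd, slope_cutoff``.
    """

    params: pd.DataFrame
    n_hc: int

    def __post_init__(self) -> None:
        if (self.params["value_sd"] <= 0).any():
            raise ValueError("degenerate normative model: a parameter has zero variance")

    # -- classification -------------------------------------------------
    def classify(self, summaries: pd.DataFrame) -> pd.DataFrame:
        """Classify subjects from a per-recording summary table.

        Returns one row per subject with six value flags
        (``flag_<parameter>_<side>``), ``n_flags``, ``is_mmi``, six slope
        flags (``decrement_<parameter>_<side>``) and
        ``has_progressive_decrement``.  Flags use strict inequality: a
        value exactly at the cutoff is not flagged.
        """
        wide = _wide_summaries(summaries)
        out = pd.DataFrame({"subject_id": wide.index})
        flag_cols, dec_cols = [], []
        for p in PARAMETERS:
            for side in SIDES:
                vals = wide[f"{VALUE_COLUMNS[p]}_{side}"]
                if vals.isna().any():
                    bad = wide.index[vals.isna()][0]
                    raise ValueError(
                        f"subject {bad!r}: missing {p} on side {side}; "
                        "classification requires all six parameters"
                    )
                slopes = wide[f"{SLOPE_COLUMNS[p]}_{side}"]
                stats = self.params.loc[(p, side)]
                out[f"flag_{p}_{side}"] = (vals < stats["value_cutoff"]).to_numpy()
                out[f"decrement_{p}_{side}"] = (
                    slopes.notna() & (slopes < stats["slope_cutoff"])
                ).to_numpy()
                flag_cols.append(f"flag_{p}_{side}")
                dec_cols.append(f"decrement_{p}_{side}")
        out["n_flags"] = out[flag_cols].sum(axis=1)
        out["is_mmi"] = out["n_flags"] >= 1
        out["has_progressive_decrement"] = out[dec_cols].any(axis=1)
        return out.reset_index(drop=True)

    def classify_values(self, subject_id: str, row: pd.Series) -> dict:
        """Classify one subject given its wide summary row; both hands required."""
        rec: dict = {"subject_id": subject_id}
        n_flags = 0
        any_decrement = False
        for p in PARAMETERS:
            for side in SIDES:
                val = row[f"{VALUE_COLUMNS[p]}_{side}"]
                slope = row[f"{SLOPE_COLUMNS[p]}_{side}"]
                if not np.isfinite(val):
                    raise ValueError(
                        f"subject {subject_id!r}: missing {p} on side {side}; "
                        "classification requires all six parameters"
                    )
                stats = self.params.loc[(p, side)]
                flag = bool(val < stats["value_cutoff"])
                dec = bool(np.isfinite(slope) and slope < stats["slope_cutoff"])
                rec[f"flag_{p}_{side}"] = flag
                rec[f"decrement_{p}_{side}"] = dec
                n_flags += flag
                any_decrement |= dec
        rec["n_flags"] = n_flags
        rec["is_mmi"] = n_flags >= 1
        rec["has_progressive_decrement"] = any_decrement
        return rec

    # -- presentation & serialization -----------------------------------
    def summary(self) -> str:
        """Human-readable normative table."""
        lines = [
            "Normative tapping model (HC reference)",
            f"n_hc = {self.n_hc}",
            f"{'parameter':<14}{'side':<6}{'mean':>10}{'sd':>10}{'cutoff':>10}"
            f"{'slope mean':>12}{'slope sd':>10}{'slope cutoff':>14}",
        ]
        for (p, side), r in self.params.iterrows():
            lines.append(
                f"{p:<14}{side:<6}{r['value_mean']:>10.3f}{r['value_sd']:>10.3f}"
                f"{r['value_cutoff']:>10.3f}{r['slope_mean']:>12.4f}"
                f"{r['slope_sd']:>10.4f}{r['slope_cutoff']:>14.4f}"
            )
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = {
            "n_hc": self.n_hc,
            "params": [
                {"parameter": p, "side": s, **{k: float(v) for k, v in row.items()}}
                for (p, s), row in self.params.iterrows()
            ],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "NormativeTappingResults":
        payload = json.loads(source)
        df = pd.DataFrame(payload["params"]).set_index(["parameter", "side"])
        return cls(params=df, n_hc=int(payload["n_hc"]))


class NormativeTappingModel:
    """Normative model of HC finger-tapping summaries.

    Parameters
    ----------
    hc_summaries : DataFrame
        Per-recording summary table (see ``kinematics.SUMMARY_COLUMNS``)
        restricted to healthy controls; both hands per subject.  Subjects
        missing a hand are excluded with a warning.
    """

    def __init__(self, hc_summaries: pd.DataFrame):
        self.hc_summaries = hc_summaries

    def fit(self) -> NormativeTappingResults:
        wide = _wide_summaries(self.hc_summaries)
        value_cols = [f"{c}_{s}" for c in VALUE_COLUMNS.values() for s in SIDES]
        complete = wide[value_cols].notna().all(axis=1)
        if (~complete).any():
            warnings.warn(
                f"excluding {int((~complete).sum())} HC subject(s) with a missing hand",
                RuntimeWarning,
            )
        wide = wide[complete]
        if len(wide) < 3:
            raise ValueError("normative fit requires >= 3 complete HC subjects")
        rows = {}
        for p in PARAMETERS:
            for side in SIDES:
                vals = wide[f"{VALUE_COLUMNS[p]}_{side}"].to_numpy(dtype=float)
                slopes = wide[f"{SLOPE_COLUMNS[p]}_{side}"].to_numpy(dtype=float)
                v_mean, v_sd = float(vals.mean()), float(vals.std(ddof=1))
                if v_sd == 0:
                    raise ValueError(f"degenerate normative model: zero variance in {p} ({side})")
                s_mean = float(np.nanmean(slopes))
                s_sd = float(np.nanstd(slopes, ddof=1))
                rows[(p, side)] = {
                    "value_mean": v_mean,
                    "value_sd": v_sd,
                    "value_cutoff": v_mean - 2.0 * v_sd,
                    "slope_mean": s_mean,
                    "slope_sd": s_sd,
                    "slope_cutoff": s_mean - 2.0 * s_sd,
                }
        params = pd.DataFrame.from_dict(rows, orient="index")
        params.index = pd.MultiIndex.from_tuples(params.index, names=["parameter", "side"])
        return NormativeTappingResults(params=params, n_hc=len(wide))


# -- spec-level functional surface --------------------------------------


def fit_normative_model(hc_summaries: pd.DataFrame) -> NormativeTappingResults:
    """Fit the HC normative model (functional wrapper)."""
    return NormativeTappingModel(hc_summaries).fit()


def classify_subject(
    summary_left: dict, summary_right: dict, model: NormativeTappingResults
) -> dict:
    """Classify one subject from its left- and right-hand summaries."""
    df = pd.DataFrame([summary_left, summary_right])
    if set(df["hand"]) != {"L", "R"}:
        raise ValueError("classification requires one summary per hand (L and R)")
    wide = _wide_summaries(df)
    sid = wide.index[0]
    return model.classify_values(sid, wide.loc[sid])


def classify_cohort(
    summaries: pd.DataFrame, subjects: pd.DataFrame
) -> tuple[pd.DataFrame, NormativeTappingResults]:
    """Fit on HC and classify all non-HC subjects.

    ``subjects`` must have ``subject_id`` and ``group`` columns; the
    normative model is fitted on group ``HC`` only and HC subjects are
    never reassigned.  Returns the classification table (with an
    ``assigned_group`` column: ``RBD-MMI`` / ``RBD-N``) and the fitted model.
    """
    groups = subjects.set_index("subject_id")["group"]
    hc_ids = groups[groups == "HC"].index
    if len(hc_ids) == 0:
        raise ValueError("no HC subjects: cannot fit normative model")
    results = fit_normative_model(summaries[summaries["subject_id"].isin(hc_ids)])
    patient_summaries = summaries[~summaries["subject_id"].isin(hc_ids)]
    if patient_summaries.empty:
        table = pd.DataFrame(columns=["subject_id", "n_flags", "is_mmi"])
    else:
        table = results.classify(patient_summaries)
        table["assigned_group"] = np.where(table["is_mmi"], "RBD-MMI", "RBD-N")
    return table, results
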