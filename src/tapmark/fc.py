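"""ROI-to-ROI resting-state functional connectivity.

Per subject: band-pass filter each ROI's BOLD time series (default
0.008–0.09 Hz, zero phase), compute the bivariate Pearson correlation for
every ROI pair and Fisher-z transform it.  Group inference: for each
unordered ROI pair, an ordinary least-squares model of z on a group
indicator plus age (centered) and sex (M = 0, F = 1); pairwise two-group
contrasts; Benjamini–Hochberg FDR across the pairs within each contrast.

Shape convention: time-series matrices are volumes x ROIs.  With 30 ROIs
the analysis covers the 435 unique pairs of the strict upper triangle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .stats import SEX_CODES

#: atanh cap keeping degenerate |r| = 1 pairs finite.
Z_CAP = float(np.arctanh(1.0 - 1e-7))

#: Default sensorimotor ROI set: 15 regions per hemisphere.
ROI_BASENAMES = (
    "M1",
    "PM",
    "SMA",
    "S1",
    "SPL",
    "IPL",
    "caudate",
    "ant_putamen",
    "post_putamen",
    "cereb_II",
    "cereb_III",
    "cereb_IV_V",
    "cereb_VI",
    "cereb_VII",
    "cereb_VIII",
)
DEFAULT_ROI_LABELS = tuple(f"{side}_{name}" for side in ("R", "L") for name in ROI_BASENAMES)

DEFAULT_CONTRASTS = (("RBD-MMI", "HC"), ("RBD-MMI", "RBD-N"), ("RBD-N", "HC"))


@dataclass
class RoiTimeSeries:
    """One subject's ROI time-series matrix (volumes x ROIs)."""

    subject_id: str
    roi_labels: tuple
    tr: float
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.roi_labels = tuple(self.roi_labels)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.roi_labels):
            raise ValueError("data must be volumes x ROIs matching roi_labels")
        if self.data.shape[0] < 10:
            raise ValueError("need >= 10 volumes")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")


@dataclass
class FCResult:
    """Per-subject connectivity: correlation and Fisher-z matrices."""

    subject_id: str
    roi_labels: tuple
    r_matrix: np.ndarray
    z_matrix: np.ndarray

    def upper_triangle(self) -> pd.DataFrame:
        """Long table of the strict upper triangle: roi_1, roi_2, r, z."""
        iu = np.triu_indices(len(self.roi_labels), k=1)
        return pd.DataFrame(
            {
                "roi_1": [self.roi_labels[i] for i in iu[0]],
                "roi_2": [self.roi_labels[j] for j in iu[1]],
                "r": self.r_matrix[iu],
                "z": self.z_matrix[iu],
            }
        )


def bandpass_filter(series: RoiTimeSeries, band: tuple = (0.008, 0.09)) -> RoiTimeSeries:
    """Zero-phase band-pass (second-order recursive design) per ROI column."""
    f_lo, f_hi = band
    fs = 1.0 / series.tr
    if not (0 < f_lo < f_hi < fs / 2.0):
        raise ValueError(
            f"band {band} infeasible for tr={series.tr}s (Nyquist {fs / 2.0:.4g} Hz)"
        )
    sos = signal.butter(2, (f_lo, f_hi), btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, series.data, axis=0)
    return replace(series, data=filtered)


def fisher_z(r):
    """Fisher z = atanh(r), capped near |r| = 1; accepts scalars or arrays."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr[np.isfinite(arr)]) > 1):
        raise ValueError("|r| > 1")
    z = np.arctanh(np.clip(arr, -np.tanh(Z_CAP), np.tanh(Z_CAP)))
    return float(z) if z.ndim == 0 else z


def compute_fc_matrix(series: RoiTimeSeries) -> FCResult:
    """Pearson correlation and Fisher z for every ROI pair.

    Zero-variance columns yield NaN rows/columns with a warning.
    """
    data = series.data
    sd = data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        warnings.warn(
            f"zero-variance ROI column(s) {[series.roi_labels[i] for i in dead]}; "
            "their pairs set to NaN",
            RuntimeWarning,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data, rowvar=False)
    r = (r + r.T) / 2.0  # enforce exact symmetry against rounding
    r[dead, :] = np.nan
    r[:, dead] = np.nan
    np.fill_diagonal(r, 1.0)
    r_sym = np.where(np.isnan(r), np.nan, np.clip(r, -1.0, 1.0))
    z = np.full_like(r_sym, np.nan)
    finite = np.isfinite(r_sym)
    z[finite] = fisher_z(r_sym[finite])
    return FCResult(series.subject_id, series.roi_labels, r_sym, z)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving).

    NaNs propagate; the adjustment runs over the finite entries.
    """
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.any():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def _subjects_design(sub: pd.DataFrame, target_group: str) -> np.ndarray:
    age = sub["age"].to_numpy(dtype=float)
    sex = sub["sex"].map(SEX_CODES).to_numpy(dtype=float)
    ind = (sub["group"] == target_group).to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(sub)), ind, age - age.mean(), sex])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        cols = ["intercept", "group", "age", "sex"]
        raise ValueError(f"rank-deficient design (columns {cols}); check group/sex composition")
    return X


def test_group_differences(
    fc_results: dict,
    subjects: pd.DataFrame,
    contrasts: tuple = DEFAULT_CONTRASTS,
    fdr_scope: str = "analysis",
) -> pd.DataFrame:
    """Covariate-adjusted two-group contrasts for every ROI pair.

    Parameters
    ----------
    fc_results : dict
        subject_id -> :class:`FCResult` (or a Fisher-z matrix).
    subjects : DataFrame
        Columns subject_id, group, age, sex.
    contrasts : sequence of (group_a, group_b)
        Each fitted as a separate two-group model restricted to those
        groups; T > 0 means higher z in ``group_a``.
    fdr_scope : "analysis" | "seed"
        "analysis" adjusts across all pairs within a contrast; "seed"
        adjusts within each seed ROI's family of pairs (a pair belongs to
        both of its seeds and receives the smaller adjusted value).

    Returns a long table: roi_1, roi_2, contrast, n, T, p, p_fdr.
    """
    if fdr_scope not in ("analysis", "seed"):
        raise ValueError("fdr_scope must be 'analysis' or 'seed'")
    ids = list(fc_results)
    first = fc_results[ids[0]]
    labels = tuple(first.roi_labels) if isinstance(first, FCResult) else None
    if labels is None:
        raise TypeError("fc_results values must be FCResult instances")
    n_roi = len(labels)
    iu = np.triu_indices(n_roi, k=1)
    z_rows = {}
    for sid, res in fc_results.items():
        if tuple(res.roi_labels) != labels:
            raise ValueError(f"subject {sid!r}: inconsistent ROI labels")
        z_rows[sid] = res.z_matrix[iu]

    meta = subjects.set_index("subject_id")
    tables = []
    for ga, gb in contrasts:
        sel = meta[meta["group"].isin([ga, gb])]
        sel = sel[sel.index.isin(z_rows)]
        if sel["group"].nunique() < 2:
            warnings.warn(f"contrast {ga}>{gb}: missing a group; skipped", RuntimeWarning)
            continue
        X = _subjects_design(sel.reset_index(), ga)
        Z = np.vstack([z_rows[sid] for sid in sel.index])  # subjects x pairs
        n, p_cols = X.shape
        dof = n - p_cols
        if dof <= 0:
            raise ValueError(f"contrast {ga}>{gb}: non-positive residual df")
        XtX_inv = np.linalg.inv(X.T @ X)
        ok = np.all(np.isfinite(Z), axis=0)
        T = np.full(Z.shape[1], np.nan)
        praw = np.full(Z.shape[1], np.nan)
        if ok.any():
            Zok = Z[:, ok]
            beta = XtX_inv @ X.T @ Zok
            resid = Zok - X @ beta
            sigma2 = (resid**2).sum(axis=0) / dof
            se = np.sqrt(sigma2 * XtX_inv[1, 1])
            with np.errstate(invalid="ignore", divide="ignore"):
                t = np.where(se > 0, beta[1] / se, np.nan)
            T[ok] = t
            praw[ok] = 2.0 * sps.t.sf(np.abs(t), dof)
        table = pd.DataFrame(
            {
                "roi_1": [labels[i] for i in iu[0]],
                "roi_2": [labels[j] for j in iu[1]],
                "contrast": f"{ga}>{gb}",
                "n": n,
                "T": T,
                "p": praw,
            }
        )
        if fdr_scope == "analysis":
            table["p_fdr"] = bh_fdr(table["p"].to_numpy())
        else:
            adj = np.full(len(table), np.nan)
            for seed in labels:
                fam = ((table["roi_1"] == seed) | (table["roi_2"] == seed)).to_numpy()
                fam_adj = bh_fdr(table.loc[fam, "p"].to_numpy())
                adj[fam] = np.fmin(adj[fam], fam_adj)
            table["p_fdr"] = adj
        tables.append(table)
    if not tables:
        raise ValueError("no testable contrasts")
    return pd.concat(tables, ignore_index=True)


test_group_differences.__test__ = False  # not a pytest case despite the name


class GroupContrastModel:
    """statsmodels-style wrapper around :func:`test_group_differences`."""

    def __init__(self, fc_results: dict, subjects: pd.DataFrame):
        self.fc_results = fc_results
        self.subjects = subjects

    def fit(
        self, contrasts: tuple = DEFAULT_CONTRASTS, fdr_scope: str = "analysis"
    ) -> "GroupContrastResults":
        table = test_group_differences(self.fc_results, self.subjects, contrasts, fdr_scope)
        return GroupContrastResults(table=table, fdr_scope=fdr_scope)


@dataclass
class GroupContrastResults:
    table: pd.DataFrame
    fdr_scope: str

    def significant(self, q: float = 0.05) -> pd.DataFrame:
        """Pairs with FDR-adjusted p below ``q``."""
        return self.table[self.table["p_fdr"] < q].reset_index(drop=True)

    def summary(self, q: float = 0.05) -> str:
        sig = self.significant(q)
        lines = [
            f"ROI-to-ROI group contrasts ({self.fdr_scope}-level FDR)",
            f"{len(self.table)} pair-contrast tests, {len(sig)} significant at q={q}",
            f"{'contrast':<18}{'ROI 1':<18}{'ROI 2':<18}{'T':>8}{'p-FDR':>10}",
        ]
        for _, r in sig.iterrows():
            lines.append(
                f"{r['contrast']:<18}{r['roi_1']:<18}{r['roi_2']:<18}{r['T']:>8.2f}{r['p_fdr']:>10.4f}"
            )
        return "\n".join(lines)
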