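"""Group-comparison and correlation statistics.

Conventions (fixed and documented rather than options scattered through
the code):

- one-way ANOVA with Tukey–Kramer post-hoc comparisons (handles unequal
  group sizes) for three-group continuous variables;
- pooled-variance (Student) two-sample t-test by default, Welch optional;
- Pearson chi-square without continuity correction by default;
- Pearson correlation with the t-approximation p-value;
- partial correlation by least-squares residualization on an intercept
  plus covariates, with df = n - 2 - k;
- sex is coded M = 0, F = 1 wherever a numeric coding is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

SEX_CODES = {"M": 0.0, "F": 1.0}


@dataclass
class ComparisonResult:
    variable: str
    test: str  # anova | tukey_pair | t_test | chi_square
    statistic: float
    df: tuple | float
    p: float
    groups: tuple = ()
    note: str = ""


@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    kind: str  # pearson | partial
    r: float
    n: int
    p: float
    covariates: tuple = field(default_factory=tuple)


def comparison_rows(results: list[ComparisonResult]) -> list[dict]:
    """Flatten comparison results to plain dict rows for tabulation."""
    rows = []
    for r in results:
        rows.append(
            {
                "variable": r.variable,
                "test": r.test,
                "groups": "|".join(map(str, r.groups)),
                "statistic": r.statistic,
                "df": "|".join(map(str, r.df)) if isinstance(r.df, tuple) else r.df,
                "p": r.p,
                "note": r.note,
            }
        )
    return rows


def anova_tukey(values, group_labels, variable: str = "") -> list[ComparisonResult]:
    """One-way ANOVA plus Tukey–Kramer pairwise comparisons.

    Returns a list whose first element is the ANOVA result followed by one
    ``tukey_pair`` row per group pair.  An overall-constant input yields
    F = 0, p = 1 and trivial post-hoc rows.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(group_labels)
    labels = sorted(pd.unique(g).tolist())
    if len(labels) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    samples = [y[g == lab] for lab in labels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs >= 2 observations")
    k, n = len(labels), len(y)
    df_pair = (k - 1, n - k)

    if np.ptp(y) == 0:  # all observations identical
        results = [ComparisonResult(variable, "anova", 0.0, df_pair, 1.0, tuple(labels))]
        results += [
            ComparisonResult(variable, "tukey_pair", 0.0, n - k, 1.0, (a, b))
            for i, a in enumerate(labels)
            for b in labels[i + 1 :]
        ]
        return results

    F, p = sps.f_oneway(*samples)
    if not np.isfinite(F):  # identical group means with zero within-group variance
        F, p = 0.0, 1.0
    results = [ComparisonResult(variable, "anova", float(F), df_pair, float(p), tuple(labels))]

    tk = pairwise_tukeyhsd(y, g)
    uniq = [str(u) for u in tk.groupsunique]
    pairs = [(uniq[i], uniq[j]) for i in range(len(uniq)) for j in range(i + 1, len(uniq))]
    for (a, b), diff, padj in zip(pairs, tk.meandiffs, tk.pvalues):
        results.append(
            ComparisonResult(variable, "tukey_pair", float(diff), n - k, float(padj), (a, b))
        )
    return results


def two_sample_t(values_a, values_b, variable: str = "", welch: bool = False) -> ComparisonResult:
    """Two-sample t-test (pooled variance by default)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 observations")
    df = len(a) + len(b) - 2
    if not welch and a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return ComparisonResult(variable, "t_test", 0.0, df, 1.0, note="zero variance")
        t = np.inf if a.mean() > b.mean() else -np.inf
        return ComparisonResult(variable, "t_test", float(t), df, 0.0, note="zero variance, unequal means")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return ComparisonResult(variable, "t_test", float(res.statistic), float(res.df), float(res.pvalue))


def chi_square(contingency, variable: str = "", correction: bool = False) -> ComparisonResult:
    """Pearson chi-square on a 2-way count table (no continuity correction
    by default)."""
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero marginal")
    res = sps.chi2_contingency(table, correction=correction)
    return ComparisonResult(variable, "chi_square", float(res.statistic), float(res.dof), float(res.pvalue))


def pearson_correlation(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Pearson r with the two-tailed t-approximation p-value."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    n = len(xa)
    if n < 3 or len(ya) != n:
        raise ValueError("need matched samples with n >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("constant variable in correlation")
    r, p = sps.pearsonr(xa, ya)
    return CorrelationResult(x_name, y_name, "pearson", float(r), n, float(p))


def partial_correlation(
    x, y, covariates, x_name: str = "x", y_name: str = "y", covariate_names: tuple = ()
) -> CorrelationResult:
    """Partial correlation of x and y controlling for covariates.

    Both variables are residualized on an intercept plus the covariate
    columns by least squares; the Pearson r of the residuals is tested with
    df = n - 2 - k.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    Z = np.atleast_2d(np.asarray(covariates, dtype=float))
    if Z.shape[0] != len(xa):
        Z = Z.T
    n, k = Z.shape
    if len(xa) != n or len(ya) != n:
        raise ValueError("x, y and covariates must have matching length")
    if n < k + 3:
        raise ValueError(f"partial correlation needs n >= k + 3 (n={n}, k={k})")
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear covariates")
    coef_x, *_ = np.linalg.lstsq(design, xa, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, ya, rcond=None)
    rx = xa - design @ coef_x
    ry = ya - design @ coef_y
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("a variable is fully explained by the covariates")
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    df = n - 2 - k
    r_clip = min(max(r, -1.0), 1.0)
    if abs(r_clip) == 1.0:
        p = 0.0
    else:
        t = r_clip * np.sqrt(df / (1.0 - r_clip**2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    names = tuple(covariate_names) if covariate_names else tuple(f"z{i+1}" for i in range(k))
    return CorrelationResult(x_name, y_name, "partial", r, n, p, covariates=names)


def contralateral_map(side: str) -> str:
    """Map a tapping hand to the opposite (contralateral) striatal side."""
    mapping = {"L": "R", "R": "L"}
    if side not in mapping:
        raise ValueError(f"side must be 'L' or 'R', got {side!r}")
    return mapping[side]
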