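"""Group comparisons, covariate-adjusted regressions, multiplicity control.

Group means are compared with pooled-variance (Student) two-sample
t-tests — df = n_a + n_b - 2, so a 38 + 38 cohort reports df = 74 —
and paired t-tests on within-subject contrasts (df = n - 1). Symptom
relationships use ordinary least squares of the outcome on the clinical
score with sex, age and medication as covariates,

    Q = b0 + b_cx * cx + b_s * s + b_a * a + b_m * m + e,

fit per group or pooled with a group interaction. P-values are adjusted
by Benjamini-Hochberg FDR or Bonferroni over a declared comparison
family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ClinicalTable, ValidationError


@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    mean_difference: float
    method: str
    adjusted_p: float | None = None


@dataclass
class RegressionResult:
    coefficients: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    n: int


def independent_ttest(group_a: np.ndarray, group_b: np.ndarray) -> TestResult:
    """Pooled-variance two-sample t-test (two-sided).

    The reported mean difference is mean(a) - mean(b).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 finite values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValidationError("zero pooled variance: t statistic undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TestResult(
        statistic=float(t), df=float(a.size + b.size - 2), p_value=float(p),
        mean_difference=float(a.mean() - b.mean()), method="independent t-test",
    )


def paired_ttest(values_a: np.ndarray, values_b: np.ndarray) -> TestResult:
    """Paired t-test on within-subject differences (two-sided)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValidationError("paired samples must share length >= 2")
    d = a - b
    if np.var(d, ddof=1) == 0:
        raise ValidationError("zero difference variance: paired t undefined")
    t, p = stats.ttest_rel(a, b)
    return TestResult(
        statistic=float(t), df=float(a.size - 1), p_value=float(p),
        mean_difference=float(d.mean()), method="paired t-test",
    )


def ols_with_covariates(
    outcome: np.ndarray,
    clinical_score: np.ndarray,
    clinical_table: ClinicalTable | pd.DataFrame,
    interaction_group: np.ndarray | None = None,
) -> RegressionResult:
    """OLS of an outcome on a clinical score plus sex, age, medication.

    Sex and medication enter as 0/1 indicators, age in years uncentered.
    ``interaction_group`` (0/1 per subject) adds group and group x score
    terms for the pooled-with-interaction variant. Raises on a
    rank-deficient design, naming the collinear columns.
    """
    table = clinical_table.table if isinstance(clinical_table, ClinicalTable) else clinical_table
    y = np.asarray(outcome, dtype=float)
    cx = np.asarray(clinical_score, dtype=float)
    if y.size != len(table) or cx.size != len(table):
        raise ValidationError("outcome/score length does not match clinical table")
    design = pd.DataFrame({
        "cx": cx,
        "sex": table["sex"].to_numpy(dtype=float),
        "age": table["age"].to_numpy(dtype=float),
        "medication": table["medication"].to_numpy(dtype=float),
    })
    if interaction_group is not None:
        g = np.asarray(interaction_group, dtype=float)
        design["group"] = g
        design["cx_x_group"] = cx * g
    keep = np.isfinite(y) & np.all(np.isfinite(design.to_numpy()), axis=1)
    y, design = y[keep], design.loc[keep]
    if y.size <= design.shape[1] + 1:
        raise ValidationError(
            f"need more rows ({y.size}) than parameters ({design.shape[1] + 1})"
        )
    x = sm.add_constant(design, has_constant="add")
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        corr = np.corrcoef(design.to_numpy().T)
        pairs = [
            (design.columns[i], design.columns[j])
            for i in range(corr.shape[0]) for j in range(i + 1, corr.shape[0])
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValidationError(f"rank-deficient design; collinear columns: {pairs}")
    fit = sm.OLS(y, x).fit()
    return RegressionResult(
        coefficients=dict(fit.params),
        t_values=dict(fit.tvalues),
        p_values=dict(fit.pvalues),
        r_squared=float(fit.rsquared),
        n=int(y.size),
    )


def adjust_pvalues(p_list, method: str = "bh") -> np.ndarray:
    """Multiple-comparison adjustment over one family of p-values.

    ``bh`` is Benjamini-Hochberg step-up (monotone adjusted p-values);
    ``bonferroni`` is min(m * p, 1). Adjusted values never fall below
    the raw p-values.
    """
    p = np.asarray(p_list, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    raise ValidationError(f"unknown adjustment method {method!r}")


def group_metric_tests(
    metric_table: pd.DataFrame,
    clinical: ClinicalTable,
    value_column: str,
    adjust: str = "bh",
) -> pd.DataFrame:
    """HC-vs-MDD t-tests of one per-subject, per-state metric.

    ``metric_table`` is long-format with columns subject, state and
    ``value_column``; subjects with a missing value for a state (e.g. a
    never-visited state's dwell time) are excluded from that state's
    test. Adjusted p-values span the family of states.
    """
    merged = metric_table.merge(
        clinical.table[["subject", "group"]], on="subject", how="left"
    )
    rows = []
    for state, chunk in merged.groupby("state"):
        vals = chunk.dropna(subset=[value_column])
        a = vals.loc[vals["group"] == "HC", value_column].to_numpy()
        b = vals.loc[vals["group"] == "MDD", value_column].to_numpy()
        res = independent_ttest(a, b)
        rows.append({
            "state": state, "metric": value_column,
            "mean_difference_hc_minus_mdd": res.mean_difference,
            "t": res.statistic, "df": res.df, "p": res.p_value,
        })
    out = pd.DataFrame(rows)
    out["adjusted_p"] = adjust_pvalues(out["p"].to_numpy(), method=adjust)
    return out
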