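"""Group comparisons: Student t-tests, two-way factorial ANOVA, mean +- SE.

The factorial model is ``response ~ age * volume`` with Type II sums of
squares, the conventional choice for the unbalanced 4-vs-8 animal design when
main effects are of interest; for balanced designs Type II reduces to the
classical orthogonal decomposition.  Significance threshold is alpha = 0.05
throughout.  No multiple-testing correction is applied by default; a Holm
adjustment is available behind a flag.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .types import GroupSummary, TTestResult

ALPHA = 0.05


def two_sample_t(x, y, two_sided: bool = True, welch: bool = False) -> TTestResult:
    """Two-sample t-test, pooled variance by default (Student), Welch by flag.

    Degenerate zero-variance inputs are resolved deterministically: equal
    means give t = 0, p = 1; unequal means give p = 0 flagged degenerate.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    df = x.size + y.size - 2
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return TTestResult(t=0.0, df=df, p=1.0, significant=False)
        t = math.inf if x.mean() > y.mean() else -math.inf
        return TTestResult(t=t, df=df, p=0.0, significant=True, degenerate=True)
    alternative = "two-sided" if two_sided else "greater"
    res = sps.ttest_ind(x, y, equal_var=not welch, alternative=alternative)
    p = float(res.pvalue)
    return TTestResult(t=float(res.statistic), df=float(res.df), p=p,
                       significant=p < ALPHA)


_TERMS = {"C(age)": "age", "C(volume)": "volume",
          "C(age):C(volume)": "age:volume", "Residual": "residual"}


def two_way_anova(data: pd.DataFrame, response: str = "value",
                  factor_a: str = "age", factor_b: str = "volume") -> pd.DataFrame:
    """Two-factor ANOVA with interaction, Type II sums of squares.

    Returns a table indexed by term (age, volume, age:volume, residual) with
    columns sum_sq, df, mean_sq, F, p.  Requires both factors at two levels,
    no empty design cell, and at least two observations in three of the four
    cells (otherwise the interaction or error term is not estimable).
    """
    df = data[[response, factor_a, factor_b]].dropna().copy()
    df.columns = ["value", "age", "volume"]
    for fac in ("age", "volume"):
        levels = df[fac].unique()
        if len(levels) != 2:
            raise ValueError(f"factor {fac!r} must have exactly 2 levels, got {list(levels)}")
    counts = df.groupby(["age", "volume"]).size()
    for a in df["age"].unique():
        for v in df["volume"].unique():
            if (a, v) not in counts.index:
                raise ValueError(f"empty design cell: age={a!r}, volume={v!r}")
    if (counts >= 2).sum() < 3:
        raise ValueError("need >= 2 observations in at least 3 of the 4 cells")

    fit = smf.ols("value ~ C(age) * C(volume)", data=df).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError("rank-deficient design matrix")
    table = sm.stats.anova_lm(fit, typ=2)
    table = table.rename(index=_TERMS)
    table = table.rename(columns={"sum_sq": "sum_sq", "PR(>F)": "p"})
    table["mean_sq"] = table["sum_sq"] / table["df"]
    return table[["sum_sq", "df", "mean_sq", "F", "p"]]


def summarize_groups(data: pd.DataFrame, value: str, by) -> list[GroupSummary]:
    """Per-group n, mean and standard error (SD with n-1 denominator over sqrt n)."""
    out: list[GroupSummary] = []
    for key, g in data.groupby(by, sort=True):
        vals = g[value].dropna().to_numpy(float)
        if vals.size == 0:
            continue
        se = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else None
        out.append(GroupSummary(group=key, n=int(vals.size),
                                mean=float(vals.mean()), se=se))
    return out


def holm_correction(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values (off by default in all pipelines)."""
    p = np.asarray(pvals, float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
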