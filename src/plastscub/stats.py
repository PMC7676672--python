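"""Statistical procedures used throughout the pipeline.

Thin, precondition-checked wrappers around scipy.stats plus the two scalar
descriptive statistics (Cronbach's alpha, coefficient of variation). All
p-values are two-sided, variances are the sample (n-1) form, and no
multiple-testing correction is applied — raw p-values are reported. The 2x2
chi-square uses no continuity correction by default since the codon counts at
stake are in the thousands; a flag restores it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: float | tuple[int, int]
    method: str


def chi2_contingency(table, correction: bool = False) -> TestResult:
    """Pearson chi-square test of independence on an R x C count table."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    row_sums, col_sums = arr.sum(axis=1), arr.sum(axis=0)
    if (row_sums == 0).any() or (col_sums == 0).any():
        zero = ("row", int(np.argmax(row_sums == 0))) if (row_sums == 0).any() \
            else ("column", int(np.argmax(col_sums == 0)))
        raise ValueError(f"{zero[0]} {zero[1]} of the contingency table is all zero")
    expected = np.outer(row_sums, col_sums) / arr.sum()
    if (expected < 1).any():
        raise ValueError("expected cell counts below 1; chi-square invalid")
    stat, p, df, _ = sps.chi2_contingency(arr, correction=correction)
    return TestResult(float(stat), float(p), int(df), "chi2_contingency")


def chi2_gof(observed, expected_prop) -> TestResult:
    """Chi-square goodness of fit of observed counts to expected proportions."""
    obs = np.asarray(observed, dtype=float)
    prop = np.asarray(expected_prop, dtype=float)
    if obs.shape != prop.shape:
        raise ValueError("observed and expected must have equal length")
    if not np.isclose(prop.sum(), 1.0):
        raise ValueError("expected proportions must sum to 1")
    stat, p = sps.chisquare(obs, f_exp=prop * obs.sum())
    return TestResult(float(stat), float(p), len(obs) - 1, "chi2_gof")


def t_one_sample(values, mu: float) -> TestResult:
    """Two-sided one-sample Student t-test against a reference mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("one-sample t-test needs n >= 2")
    if np.all(x == x[0]):  # degenerate: variance is exactly zero
        if x[0] == mu:
            return TestResult(0.0, 1.0, x.size - 1, "t_one_sample")
        raise ValueError("zero-variance input: t statistic undefined")
    stat, p = sps.ttest_1samp(x, mu)
    return TestResult(float(stat), float(p), x.size - 1, "t_one_sample")


def t_two_sample(a, b, equal_var: bool = True) -> TestResult:
    """Two-sided two-sample t-test, pooled variance by default (Welch optional)."""
    x, y = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("two-sample t-test needs n >= 2 in each sample")
    stat, p = sps.ttest_ind(x, y, equal_var=equal_var)
    df = x.size + y.size - 2 if equal_var else None
    if df is None:
        sx, sy = np.var(x, ddof=1) / x.size, np.var(y, ddof=1) / y.size
        df = (sx + sy) ** 2 / (sx ** 2 / (x.size - 1) + sy ** 2 / (y.size - 1))
    return TestResult(float(stat), float(p), float(df), "t_two_sample")


def pearson_r(x, y) -> TestResult:
    """Pearson correlation coefficient with two-sided p-value."""
    xv, yv = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if xv.size != yv.size or xv.size < 3:
        raise ValueError("pearson_r needs equal-length vectors with n >= 3")
    if np.var(xv) == 0 or np.var(yv) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    r, p = sps.pearsonr(xv, yv)
    return TestResult(float(r), float(p), xv.size - 2, "pearson")


def cronbach_alpha(items) -> float:
    """Cronbach's alpha over a cases x items matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of case totals),
    with sample (n-1) variances.
    """
    arr = np.asarray(items, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("cronbach_alpha needs >= 2 cases and >= 2 items")
    k = arr.shape[1]
    item_vars = arr.var(axis=0, ddof=1)
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("case totals have zero variance")
    return k / (k - 1) * (1 - item_vars.sum() / total_var)


def coefficient_of_variation(values) -> float:
    """Sample standard deviation divided by the mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("CV needs n >= 2")
    mean = x.mean()
    if mean == 0:
        raise ValueError("CV undefined for mean-zero input")
    return float(x.std(ddof=1) / mean)
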