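"""Prediction-error metrics and the study's statistical tests.

The prediction error of an eye is the predicted spectacle refraction minus
the achieved postoperative MRSE, in diopters; a positive error means the
eye ended more myopic than predicted (a hyperopic prediction error).
Summaries report mean, sample SD, the median absolute error (MedAE), the
median signed error, and the proportions of eyes within ±0.25/±0.50/±1.00 D.

Test wrappers (one-way ANOVA, Holm step-down, Pearson chi-squared on a 2x2
table, variance-ratio F, Welch t, Tukey HSD) delegate to scipy/statsmodels
and return a uniform :class:`TestResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import InvalidInputError

__all__ = [
    "ErrorSummary",
    "TestResult",
    "prediction_error",
    "summarize",
    "anova_oneway",
    "holm_adjust",
    "chisq_2x2",
    "f_test_sd",
    "t_test",
    "tukey_hsd",
]

DEFAULT_THRESHOLDS = (0.25, 0.50, 1.00)


@dataclass
class ErrorSummary:
    """Descriptive statistics of a set of prediction errors (diopters)."""

    n: int
    mean_error: float
    sd_error: Optional[float]
    medae: float
    median_signed: float
    pct_025: float
    pct_050: float
    pct_100: float

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_error": self.mean_error,
            "sd_error": self.sd_error,
            "medae": self.medae,
            "median_signed": self.median_signed,
            "pct_025": self.pct_025,
            "pct_050": self.pct_050,
            "pct_100": self.pct_100,
        }


@dataclass
class TestResult:
    """A test statistic with its degrees of freedom and p-value."""

    name: str
    statistic: float
    pvalue: float
    df: Optional[tuple] = None
    adjusted_pvalues: Optional[list] = None
    extra: dict = field(default_factory=dict)


def prediction_error(predicted, mrse):
    """predicted − achieved MRSE, D; positive = hyperopic prediction error."""
    predicted = np.asarray(predicted, dtype=float)
    mrse = np.asarray(mrse, dtype=float)
    if not (np.all(np.isfinite(predicted)) and np.all(np.isfinite(mrse))):
        raise InvalidInputError("prediction_error requires finite inputs")
    return predicted - mrse


def summarize(
    errors: Sequence[float], thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> ErrorSummary:
    """Summarize prediction errors; threshold proportions are inclusive
    (|e| <= t counts as within ±t)."""
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise InvalidInputError("cannot summarize an empty error list")
    abs_e = np.abs(e)
    props = [float(np.mean(abs_e <= t)) for t in thresholds]
    return ErrorSummary(
        n=int(e.size),
        mean_error=float(np.mean(e)),
        sd_error=float(np.std(e, ddof=1)) if e.size > 1 else None,
        medae=float(np.median(abs_e)),
        median_signed=float(np.median(e)),
        pct_025=props[0],
        pct_050=props[1],
        pct_100=props[2],
    )


def anova_oneway(groups: Sequence[Sequence[float]]) -> TestResult:
    """Classical one-way fixed-effects ANOVA across error groups."""
    if len(groups) < 2:
        raise InvalidInputError("ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise InvalidInputError("each ANOVA group needs n >= 2")
    k = len(arrays)
    n = sum(a.size for a in arrays)
    # identical groups give 0/0 in scipy; define F = 0, p = 1
    grand = np.concatenate(arrays)
    if np.ptp(grand) == 0.0:
        return TestResult("anova_oneway", 0.0, 1.0, df=(k - 1, n - k))
    stat, p = stats.f_oneway(*arrays)
    return TestResult("anova_oneway", float(stat), float(p), df=(k - 1, n - k))


def holm_adjust(pvalues: Sequence[float]) -> list:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="holm")[1])


def chisq_2x2(
    k1: int, n1: int, k2: int, n2: int, correction: bool = False
) -> TestResult:
    """Pearson chi-squared (df=1) comparing two success proportions k1/n1
    vs k2/n2; no Yates continuity correction unless requested."""
    for k, n in ((k1, n1), (k2, n2)):
        if not 0 <= k <= n:
            raise InvalidInputError("need 0 <= k <= n in each group")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise InvalidInputError("chi-squared expected cell count is zero")
    res = stats.chi2_contingency(table, correction=correction)
    return TestResult("chisq_2x2", float(res.statistic), float(res.pvalue), df=(1,))


def f_test_sd(sd1: float, n1: int, sd2: float, n2: int) -> TestResult:
    """Two-sided variance-ratio F test from two sample SDs.

    Treats the two samples as independent, which the study design does even
    when one set of eyes is a subset of the other — a documented
    simplification of the source analysis.
    """
    if n1 < 2 or n2 < 2:
        raise InvalidInputError("F test needs n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise InvalidInputError("F test needs positive SDs")
    F = sd1**2 / sd2**2
    df1, df2 = n1 - 1, n2 - 1
    lower = stats.f.cdf(F, df1, df2)
    p = min(1.0, 2.0 * min(lower, 1.0 - lower))
    return TestResult("f_test_sd", float(F), float(p), df=(df1, df2))


def t_test(g1: Sequence[float], g2: Sequence[float], equal_var: bool = False) -> TestResult:
    """Two-sample t test; Welch (unequal variances) by default."""
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("t test needs n >= 2 per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return TestResult("t_test", 0.0, 1.0)
        raise InvalidInputError("zero variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = (float(res.df),) if hasattr(res, "df") else None
    return TestResult("t_test", float(res.statistic), float(res.pvalue), df=df)


def tukey_hsd(groups: Sequence[Sequence[float]]) -> list:
    """All pairwise Tukey HSD comparisons; one TestResult per (i, j) pair."""
    if len(groups) < 2:
        raise InvalidInputError("Tukey HSD needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise InvalidInputError("each group needs n >= 2")
    if np.ptp(np.concatenate(arrays)) == 0.0:
        return [
            TestResult("tukey_hsd", 0.0, 1.0, extra={"pair": (i, j)})
            for i in range(len(arrays))
            for j in range(i + 1, len(arrays))
        ]
    res = stats.tukey_hsd(*arrays)
    out = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            out.append(
                TestResult(
                    "tukey_hsd",
                    float(res.statistic[i, j]),
                    float(res.pvalue[i, j]),
                    extra={"pair": (i, j)},
                )
            )
    return out
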