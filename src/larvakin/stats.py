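"""Association and group-comparison statistics for the species traits.

Thin, well-specified wrappers around scipy/statsmodels: Pearson
correlation with a Fisher-z 95% confidence interval, ordinary least
squares with a pointwise confidence band for the mean response,
Kruskal-Wallis, Mann-Whitney U (exact for small samples, corrected
normal approximation otherwise), one-way ANOVA, and Bonferroni
correction over a family of tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
import statsmodels.api as sm


@dataclass
class CorrelationResult:
    r: float
    ci95: tuple[float, float]
    p: float
    n: int


@dataclass
class TestResult:
    statistic: float
    p: float
    test: str
    group_sizes: tuple[int, ...]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    band_x: np.ndarray
    band_lo: np.ndarray
    band_hi: np.ndarray
    fitted: np.ndarray


def pearson_with_ci(x, y) -> CorrelationResult:
    """Pearson r with a Fisher-z 95% CI and a two-sided t-test p value.

    The CI is tanh(atanh(r) +/- 1.96 / sqrt(n - 3)); the p value comes
    from t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_with_ci needs paired samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance input")
    n = x.size
    r, p = sps.pearsonr(x, y)
    r = float(r)
    if abs(r) >= 1.0:
        ci = (r, r)
    elif n == 3:  # Fisher SE 1/sqrt(n-3) undefined
        ci = (-1.0, 1.0)
    else:
        z = np.arctanh(r)
        half = 1.96 / np.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    return CorrelationResult(r=r, ci95=ci, p=float(p), n=n)


def regression_with_band(x, y, level: float = 0.95) -> RegressionResult:
    """OLS fit of y on x with a pointwise confidence band for the mean.

    The band at x0 is yhat(x0) +/- t(n-2, (1+level)/2) * SE(yhat(x0)),
    evaluated at the observed x (sorted).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("regression needs paired samples with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("regression undefined: constant x")
    order = np.argsort(x)
    xs = x[order]
    model = sm.OLS(y[order], sm.add_constant(xs)).fit()
    pred = model.get_prediction(sm.add_constant(xs))
    frame = pred.summary_frame(alpha=1 - level)
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        band_x=xs,
        band_lo=frame["mean_ci_lower"].to_numpy(),
        band_hi=frame["mean_ci_upper"].to_numpy(),
        fitted=frame["mean"].to_numpy(),
    )


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H with tie correction; chi-square p on k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("kruskal_wallis needs >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "kruskal-wallis", tuple(g.size for g in groups))
    h, p = sps.kruskal(*groups)
    return TestResult(float(h), float(p), "kruskal-wallis", tuple(g.size for g in groups))


def mann_whitney_u(a, b, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U test.

    Uses the exact null distribution when the samples are small
    (n_a * n_b <= 400) and tie-free; otherwise the normal approximation
    with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size * b.size <= 400 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative=alternative, method=method, use_continuity=True
    )
    return TestResult(float(res.statistic), float(res.pvalue), "mann-whitney-u",
                      (a.size, b.size))


def one_way_anova(groups) -> TestResult:
    """One-way ANOVA: F = MS_between / MS_within, p from F(k-1, n-k).

    Zero within-group variance with nonzero between-group spread gives
    F = inf, p = 0 (flagged boundary); with zero spread everywhere the
    statistic is undefined and NaN is returned with p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    n = sum(g.size for g in groups)
    if k < 2 or n <= k:
        raise ValueError("one_way_anova needs >= 2 groups and total n > k")
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_within == 0:
        if ss_between == 0:
            return TestResult(float("nan"), 1.0, "one-way-anova",
                              tuple(g.size for g in groups))
        return TestResult(float("inf"), 0.0, "one-way-anova",
                          tuple(g.size for g in groups))
    f, p = sps.f_oneway(*groups)
    return TestResult(float(f), float(p), "one-way-anova", tuple(g.size for g in groups))


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m) elementwise.

    ``m`` defaults to the number of p values (e.g. m = 4 when testing the
    kinematics against larval length, Tave, Tmax and Tmin).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, p * m)
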