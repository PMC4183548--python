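"""Group summaries, pooled t-tests, and univariate clinical associations.

The study design compares collagen metrics between two groups with a
pooled-variance (Student's) two-sample t-test — reported either from raw
per-patient values or reconstructed from printed group means, SEMs and
sample sizes — and relates a collagen metric to continuous clinical
covariates (PSA, prostate size, symptom score, post-void residuals, age)
with ordinary least squares, one covariate at a time. Missing clinical
data are handled listwise per analysis, so each row of the association
table has its own n. No multiplicity adjustment is applied by default,
matching the univariate reporting style; Benjamini-Hochberg is available
behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TTestResult",
    "RegressionResult",
    "summarize",
    "ttest_pooled",
    "ttest_from_summary",
    "linreg",
    "run_association_battery",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean, and standard error of the mean (sd/sqrt(n))."""

    n: int
    mean: float
    sem: float
    sem_defined: bool = True


@dataclass(frozen=True)
class TTestResult:
    """Two-sided pooled-variance two-sample t-test."""

    t: float
    df: int
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class RegressionResult:
    """Simple OLS of a metric on one covariate."""

    slope: float
    slope_sem: float
    intercept: float
    r2: float
    p: float
    n: int


def summarize(values) -> GroupSummary:
    """Mean and SEM (sample sd, n-1 denominator) of a list of values.

    A single observation has no defined SEM; it is reported as 0 with
    ``sem_defined=False`` so downstream tables can flag it.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sample")
    if arr.size == 1:
        return GroupSummary(n=1, mean=float(arr[0]), sem=0.0, sem_defined=False)
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size))
    return GroupSummary(n=int(arr.size), mean=float(arr.mean()), sem=sem)


def _finish_ttest(t: float, p: float, df: int, m1: float, m2: float) -> TTestResult:
    # zero pooled variance: scipy yields nan (equal means) or +-inf (unequal)
    if math.isnan(t) or math.isnan(p):
        if m1 == m2:
            return TTestResult(t=0.0, df=df, p=1.0)
        t = math.inf if m1 > m2 else -math.inf
        return TTestResult(t=t, df=df, p=0.0, degenerate=True)
    if math.isinf(t):
        return TTestResult(t=float(t), df=df, p=0.0, degenerate=True)
    return TTestResult(t=float(t), df=df, p=float(p))


def ttest_pooled(x, y) -> TTestResult:
    """Student's pooled-variance two-sample t-test, two-sided.

    Degrees of freedom are n1 + n2 - 2. Zero pooled variance is resolved
    explicitly: equal means give t = 0, p = 1; unequal means give p = 0
    flagged degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = sps.ttest_ind(x, y, equal_var=True)
    return _finish_ttest(res.statistic, res.pvalue, x.size + y.size - 2,
                         float(x.mean()), float(y.mean()))


def ttest_from_summary(
    m1: float, sem1: float, n1: int, m2: float, sem2: float, n2: int
) -> TTestResult:
    """Pooled t-test reconstructed from printed means, SEMs and sample sizes.

    Standard deviations are recovered as sem * sqrt(n); the result is
    identical (to floating-point precision) to :func:`ttest_pooled` on any
    raw sample reduced to its summary statistics.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sem1 < 0 or sem2 < 0:
        raise ValueError("SEMs must be nonnegative")
    sd1 = sem1 * math.sqrt(n1)
    sd2 = sem2 * math.sqrt(n2)
    res = sps.ttest_ind_from_stats(m1, sd1, n1, m2, sd2, n2, equal_var=True)
    return _finish_ttest(res.statistic, res.pvalue, n1 + n2 - 2, m1, m2)


def linreg(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with slope standard error.

    Pairs with a missing value in either variable are dropped listwise.
    Requires at least 3 complete pairs and nonzero x-variance; the p-value
    is two-sided from t = slope / slope_sem with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need >= 3 complete pairs, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope is undefined")
    fit = sps.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        slope_sem=float(fit.stderr),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        p=float(fit.pvalue),
        n=int(x.size),
    )


#: Clinical covariates of the TURP cohort: name -> kind
DEFAULT_COVARIATES = {
    "age": "continuous",
    "psa": "continuous",
    "prostate_size": "continuous",
    "auasi": "continuous",
    "pvr_pre": "continuous",
    "pvr_post": "continuous",
    "finasteride": "binary",
    "alpha_blocker": "binary",
}


def run_association_battery(
    records: pd.DataFrame,
    metric: str,
    covariates: dict[str, str] | None = None,
    adjust: bool = False,
) -> pd.DataFrame:
    """Univariate association of one collagen metric with each covariate.

    Continuous covariates get an OLS regression (slope ± SEM, R², p);
    binary flags get a pooled t-test of the metric between flag groups.
    Each row reports the n with complete data for that covariate plus the
    covariate's median and IQR. Covariates with fewer than 3 complete
    pairs (or a flag group below 2) yield an ``insufficient data`` row.
    With ``adjust=True`` a Benjamini-Hochberg adjusted p column is added.
    """
    if covariates is None:
        covariates = {
            k: v for k, v in DEFAULT_COVARIATES.items() if k in records.columns
        }
    if metric not in records.columns:
        raise ValueError(f"metric column {metric!r} not in records")
    rows = []
    for cov, kind in covariates.items():
        sub = records[[cov, metric]].dropna()
        continuous = kind == "continuous" and len(sub) > 0
        row: dict = {
            "covariate": cov,
            "kind": kind,
            "n": int(len(sub)),
            "median": float(sub[cov].median()) if continuous else np.nan,
            "iqr_lo": float(sub[cov].quantile(0.25)) if continuous else np.nan,
            "iqr_hi": float(sub[cov].quantile(0.75)) if continuous else np.nan,
            "slope": np.nan, "slope_sem": np.nan, "r2": np.nan,
            "t": np.nan, "p": np.nan, "status": "ok",
        }
        try:
            if kind == "continuous":
                fit = linreg(sub[cov], sub[metric])
                row.update(slope=fit.slope, slope_sem=fit.slope_sem, r2=fit.r2, p=fit.p)
            elif kind == "binary":
                flag = sub[cov].astype(bool)
                res = ttest_pooled(sub.loc[flag, metric], sub.loc[~flag, metric])
                row.update(t=res.t, p=res.p)
            else:
                raise ValueError(f"unknown covariate kind {kind!r}")
        except ValueError as exc:
            if "unknown covariate kind" in str(exc):
                raise
            row["status"] = "insufficient data"
        rows.append(row)
    table = pd.DataFrame(rows)
    if adjust:
        from statsmodels.stats.multitest import multipletests

        ok = table["p"].notna()
        adj = np.full(len(table), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(table.loc[ok, "p"], method="fdr_bh")[1]
        table["p_adj"] = adj
    return table
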