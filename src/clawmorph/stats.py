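"""Shape-function comparative statistics.

Standardized major axis (SMA) regression relates the biomechanical scores
to PC scores; the line is symmetric in x and y (slope = sign(r)*sd(y)/sd(x))
and its significance is reported as the Pearson correlation test, the
convention of the standard SMA toolchain.  Welch's unequal-variance t-test
compares score distributions between clade groups, and five-number
summaries feed boxplot-style group descriptions.  Tests are two-sided and
uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "SMAFit",
    "SMARegression",
    "sma_fit",
    "sma_residual",
    "WelchResult",
    "welch_test",
    "group_summary",
]


@dataclass
class SMAFit:
    """A fitted standardized major axis line.

    slope, intercept
        the SMA line y = intercept + slope * x; it passes through the
        centroid (mean x, mean y) and |slope| = sd(y)/sd(x).
    r, p_corr
        Pearson correlation and its two-sided test p-value (n-2 df).
    residuals
        signed deviations of the fitting data from the line (vertical
        convention by default; see :func:`sma_residual`).
    """

    slope: float
    intercept: float
    r: float
    p_corr: float
    residuals: np.ndarray
    n: int
    x_mean: float
    y_mean: float


class SMARegression(BaseEstimator, RegressorMixin):
    """Standardized (reduced) major axis regression estimator.

    Parameters
    ----------
    residual_convention : {"vertical", "perpendicular"}
        "vertical" reports y - (intercept + slope x); "perpendicular"
        reports the signed orthogonal distance to the line.

    Attributes (fitted)
    -------------------
    slope_, intercept_, r_, p_corr_, fit_ : the SMA line and diagnostics.
    """

    def __init__(self, residual_convention: str = "vertical"):
        self.residual_convention = residual_convention

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("x and y must have equal length")
        n = x.size
        if n < 3:
            raise ValueError("SMA regression requires n >= 3")
        sx = float(np.std(x, ddof=1))
        sy = float(np.std(y, ddof=1))
        if sx == 0 or sy == 0:
            raise ValueError("zero variance in x or y")
        r, p = sps.pearsonr(x, y)
        r = float(r)
        sign = 1.0 if r >= 0 else -1.0
        slope = sign * sy / sx
        intercept = float(np.mean(y) - slope * np.mean(x))
        self.slope_ = slope
        self.intercept_ = intercept
        self.r_ = r
        self.p_corr_ = float(p)
        resid = self._residuals(x, y, slope, intercept)
        self.fit_ = SMAFit(
            slope=slope, intercept=intercept, r=r, p_corr=float(p),
            residuals=resid, n=n,
            x_mean=float(np.mean(x)), y_mean=float(np.mean(y)),
        )
        return self

    def _residuals(self, x, y, slope, intercept):
        vertical = y - (intercept + slope * x)
        if self.residual_convention == "vertical":
            return vertical
        if self.residual_convention == "perpendicular":
            return vertical / np.hypot(1.0, slope)
        raise ValueError(
            f"unknown residual convention {self.residual_convention!r}"
        )

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.slope_ * x


def sma_fit(x, y, residual_convention: str = "vertical") -> SMAFit:
    """Fit a standardized major axis line; see :class:`SMARegression`."""
    est = SMARegression(residual_convention=residual_convention)
    est.fit(x, y)
    return est.fit_


def sma_residual(fit: SMAFit, x: float, y: float,
                 convention: str = "vertical") -> float:
    """Signed residual of one point from a fitted SMA line."""
    vertical = y - (fit.intercept + fit.slope * x)
    if convention == "vertical":
        return float(vertical)
    if convention == "perpendicular":
        return float(vertical / np.hypot(1.0, fit.slope))
    raise ValueError(f"unknown residual convention {convention!r}")


@dataclass
class WelchResult:
    t: float
    df: float
    p: float


def welch_test(group_a, group_b) -> WelchResult:
    """Welch's unequal-variance two-sample t-test, two-sided.

    t = (mean_a - mean_b) / sqrt(s2a/na + s2b/nb) with Welch-Satterthwaite
    degrees of freedom.
    """
    a = np.asarray(group_a, dtype=float).reshape(-1)
    b = np.asarray(group_b, dtype=float).reshape(-1)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            # identical constant groups: no evidence of difference
            return WelchResult(t=0.0, df=float(a.size + b.size - 2), p=1.0)
        raise ValueError("zero variance in both groups")
    res = sps.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df),
                       p=float(res.pvalue))


def group_summary(values, labels) -> pd.DataFrame:
    """Five-number summary (min, Q1, median, Q3, max) per label.

    Quartiles by linear interpolation between order statistics (the default
    of mainstream statistics environments); invariant to input order.
    """
    values = np.asarray(values, dtype=float).reshape(-1)
    labels = np.asarray(labels).reshape(-1)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    rows = []
    for label in pd.unique(labels):
        sub = values[labels == label]
        if sub.size == 0:
            raise ValueError(f"empty label class {label!r}")
        q1, med, q3 = np.percentile(sub, [25, 50, 75])
        rows.append(
            {
                "label": label,
                "n": int(sub.size),
                "min": float(sub.min()),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "max": float(sub.max()),
            }
        )
    return pd.DataFrame(rows)
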