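"""Log transforms, OLS regression summaries, and normality checks.

The regressions here operate on species-level trait values (one point per
species, log scale). Simple regression is delegated to
:func:`scipy.stats.linregress`; multiple regression to :mod:`statsmodels`
OLS. The chi-squared goodness-of-fit normality test is written out
explicitly because its binning convention matters: with mean and standard
deviation estimated from the sample, df = n_bins - 3, and with 5 bins the
upper-tail p reduces to the df = 2 closed form exp(-chi2 / 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "MultiRegressionResult",
    "NormalityResult",
    "log_transform",
    "simple_regression",
    "multiple_regression",
    "chi_square_normality",
    "chi_square_pvalue",
    "qq_points",
]


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit summary for one predictor (intercept optional)."""

    slope: float
    intercept: float | None
    r_squared: float
    t: float
    p: float
    n: int
    df_residual: int
    F: float
    f_df: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "t": self.t,
            "p": self.p,
            "n": self.n,
            "df_residual": self.df_residual,
            "F": self.F,
            "f_df": list(self.f_df),
        }


@dataclass(frozen=True)
class MultiRegressionResult:
    """OLS fit with intercept and several named predictors."""

    predictors: tuple[str, ...]
    slopes: dict[str, float]
    intercept: float
    t: dict[str, float]
    p: dict[str, float]
    r_squared: float
    adjusted_r_squared: float
    F: float
    f_df: tuple[int, int]
    F_p: float
    n: int
    df_residual: int

    def to_dict(self) -> dict:
        return {
            "predictors": list(self.predictors),
            "slopes": self.slopes,
            "intercept": self.intercept,
            "t": self.t,
            "p": self.p,
            "r_squared": self.r_squared,
            "adjusted_r_squared": self.adjusted_r_squared,
            "F": self.F,
            "f_df": list(self.f_df),
            "F_p": self.F_p,
            "n": self.n,
            "df_residual": self.df_residual,
        }


@dataclass(frozen=True)
class NormalityResult:
    """Chi-squared goodness-of-fit against a fitted normal distribution."""

    chi_square: float
    df: int
    p: float
    bin_edges: np.ndarray = field(repr=False)
    observed_counts: np.ndarray = field(repr=False)
    expected_counts: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "chi_square": self.chi_square,
            "df": self.df,
            "p": self.p,
            "bin_edges": list(map(float, self.bin_edges)),
            "observed_counts": list(map(int, self.observed_counts)),
            "expected_counts": list(map(float, self.expected_counts)),
        }


def log_transform(
    values: Sequence[float],
    base: float = 10.0,
    labels: Sequence[str] | None = None,
) -> np.ndarray:
    """Elementwise logarithm; every value must be strictly positive.

    ``labels`` (e.g. species names) are used to identify the offending
    record in the error message.
    """
    arr = np.asarray(values, dtype=float)
    bad = np.nonzero(~(arr > 0))[0]
    if bad.size:
        i = int(bad[0])
        who = labels[i] if labels is not None else f"index {i}"
        raise ValueError(
            f"log transform requires positive values; got {arr[i]!r} for {who}"
        )
    return np.log(arr) / np.log(base)


def simple_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x with intercept.

    Two-sided p for the slope from t with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError(f"length mismatch: {n} x values vs {y.size} y values")
    if n < 3:
        raise ValueError(f"simple regression needs n >= 3, got n = {n}")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant; slope undefined")
    fit = sps.linregress(x, y)
    t = fit.slope / fit.stderr if fit.stderr > 0 else np.inf * np.sign(fit.slope)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        t=float(t),
        p=float(fit.pvalue),
        n=n,
        df_residual=n - 2,
        F=float(t**2),
        f_df=(1, n - 2),
    )


def multiple_regression(
    y: Sequence[float],
    x1: Sequence[float],
    x2: Sequence[float],
    names: tuple[str, str] = ("x1", "x2"),
) -> MultiRegressionResult:
    """OLS of y on an intercept plus two predictors.

    Per-coefficient t and two-sided p with df = n - 3, overall F on
    (2, n - 3) degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n = y.size
    if not (x1.size == x2.size == n):
        raise ValueError("y, x1, x2 must have equal length")
    if n < 4:
        raise ValueError(f"multiple regression needs n >= 4, got n = {n}")
    X = sm.add_constant(np.column_stack([x1, x2]))
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("design matrix is rank deficient (collinear predictors)")
    res = sm.OLS(y, X).fit()
    return MultiRegressionResult(
        predictors=names,
        slopes={names[0]: float(res.params[1]), names[1]: float(res.params[2])},
        intercept=float(res.params[0]),
        t={names[0]: float(res.tvalues[1]), names[1]: float(res.tvalues[2])},
        p={names[0]: float(res.pvalues[1]), names[1]: float(res.pvalues[2])},
        r_squared=float(res.rsquared),
        adjusted_r_squared=float(res.rsquared_adj),
        F=float(res.fvalue),
        f_df=(2, n - 3),
        F_p=float(res.f_pvalue),
        n=n,
        df_residual=n - 3,
    )


def chi_square_pvalue(statistic: float, df: int) -> float:
    """Upper-tail probability of the chi-squared distribution."""
    return float(sps.chi2.sf(statistic, df))


def chi_square_normality(
    values: Sequence[float],
    n_bins: int = 5,
    binning: Literal["equal_probability", "equal_width"] = "equal_probability",
) -> NormalityResult:
    """Chi-squared goodness-of-fit of the sample to a fitted normal.

    Mean and standard deviation are estimated from the data, so
    df = n_bins - 3. ``equal_probability`` places bin edges at normal
    quantiles (expected count n / n_bins in every bin, never zero);
    ``equal_width`` splits the observed range evenly, which can produce
    near-zero expected counts at small n.
    """
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if n_bins < 4:
        raise ValueError(f"need at least 4 bins, got {n_bins}")
    if n < n_bins:
        raise ValueError(f"need n >= n_bins, got n = {n} with {n_bins} bins")
    mu = float(np.mean(arr))
    sd = float(np.std(arr, ddof=1))
    if sd == 0:
        raise ValueError("sample is constant; normality test undefined")

    if binning == "equal_probability":
        inner = sps.norm.ppf(np.arange(1, n_bins) / n_bins, loc=mu, scale=sd)
        edges = np.concatenate([[-np.inf], inner, [np.inf]])
    elif binning == "equal_width":
        inner = np.linspace(arr.min(), arr.max(), n_bins + 1)[1:-1]
        edges = np.concatenate([[-np.inf], inner, [np.inf]])
    else:
        raise ValueError(f"unknown binning convention: {binning!r}")

    observed = np.histogram(arr, bins=edges)[0]
    cdf = sps.norm.cdf(edges, loc=mu, scale=sd)
    expected = n * np.diff(cdf)
    if np.any(expected < 1e-12):
        raise ValueError(
            "a bin has zero expected count; use binning='equal_probability'"
        )
    stat = float(np.sum((observed - expected) ** 2 / expected))
    df = n_bins - 3
    return NormalityResult(
        chi_square=stat,
        df=df,
        p=chi_square_pvalue(stat, df),
        bin_edges=edges,
        observed_counts=observed,
        expected_counts=expected,
    )


def qq_points(values: Sequence[float]) -> np.ndarray:
    """Normal Q-Q coordinates: (theoretical quantile, sorted sample value).

    Plotting positions are (i - 0.5) / n for i = 1..n.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    n = arr.size
    if n < 3:
        raise ValueError(f"Q-Q plot needs n >= 3, got n = {n}")
    theo = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return np.column_stack([theo, arr])
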