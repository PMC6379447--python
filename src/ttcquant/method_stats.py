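"""Method-comparison statistics for paired infarct-ratio measurements.

Implements the comparison design used to validate the segmentation against
a reference method on paired per-animal ratios: a two-tailed paired
Student's t-test, Pearson correlation, ordinary least squares, a
Kolmogorov-Smirnov normality check, and a variance-ratio F-test.

Test statistics are computed from their textbook formulas; tail
probabilities come from the corresponding scipy distributions.  The KS test
fits mean and SD from the sample and uses the asymptotic KS distribution
for its p-value, which is approximate in that (Lilliefors-style) setting.
The variance check is Fisher's F-test of variance equality; all p-values
are two-tailed.  Sample SDs use the n-1 denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .exceptions import ContractError, DegenerateSampleError

__all__ = [
    "PairedSample",
    "TestResult",
    "RegressionFit",
    "MethodComparison",
    "paired_t_test",
    "pearson_r",
    "linear_regression",
    "ks_normality",
    "variance_ratio_test",
    "compare_methods",
]


@dataclass(frozen=True)
class PairedSample:
    """Paired per-animal ratios from two methods, aligned by label."""

    labels: tuple[str, ...]
    x: np.ndarray
    y: np.ndarray

    @staticmethod
    def from_arrays(
        x: Sequence[float],
        y: Sequence[float],
        labels: Sequence[str] | None = None,
    ) -> "PairedSample":
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
            raise ContractError("x and y must be 1-D and of equal length")
        if x.size < 2:
            raise ContractError("paired sample requires n >= 2")
        if labels is None:
            labels = tuple(f"s{i + 1}" for i in range(x.size))
        elif len(labels) != x.size:
            raise ContractError("labels length does not match data length")
        return PairedSample(labels=tuple(labels), x=x, y=y)

    @property
    def n(self) -> int:
        return int(self.x.size)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: float | tuple[float, float] | None = None


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float


def paired_t_test(s: PairedSample) -> TestResult:
    """Two-tailed paired Student's t-test on d = x - y, df = n - 1."""
    d = s.x - s.y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateSampleError(
            "paired differences have zero variance; t is undefined"
        )
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(statistic=float(t), p_value=float(min(p, 1.0)), df=df)


def pearson_r(s: PairedSample) -> TestResult:
    """Pearson correlation with a two-tailed t-based p-value, df = n - 2."""
    if s.n < 3:
        raise ContractError("pearson correlation requires n >= 3")
    x, y = s.x, s.y
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise DegenerateSampleError("constant sample; correlation undefined")
    r = float(np.cov(x, y, ddof=1)[0, 1] / (sx * sy))
    r = max(-1.0, min(1.0, r))
    df = s.n - 2
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(min(2.0 * sps.t.sf(abs(t), df), 1.0))
    return TestResult(statistic=r, p_value=p, df=df)


def linear_regression(s: PairedSample) -> RegressionFit:
    """Ordinary least squares of y on x; r_squared is squared Pearson r."""
    x, y = s.x, s.y
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0:
        raise DegenerateSampleError("constant x; regression design is degenerate")
    sxy = float(((x - x.mean()) * (y - y.mean())).sum())
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    syy = float(((y - y.mean()) ** 2).sum())
    r_squared = 0.0 if syy == 0 else (sxy * sxy) / (sxx * syy)
    return RegressionFit(slope=float(slope), intercept=intercept, r_squared=float(r_squared))


def ks_normality(values: Sequence[float]) -> TestResult:
    """One-sample KS test against a normal fitted to the sample.

    D is the exact sup-distance between the empirical CDF and the fitted
    normal CDF; the p-value uses the asymptotic Kolmogorov distribution and
    is approximate because the null parameters are estimated.
    """
    v = np.sort(np.asarray(values, dtype=np.float64))
    n = v.size
    if n < 3:
        raise ContractError("normality check requires n >= 3")
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateSampleError("constant sample; normality test undefined")
    cdf = sps.norm.cdf(v, loc=v.mean(), scale=sd)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - cdf)
    d_minus = np.max(cdf - (i - 1) / n)
    d = float(max(d_plus, d_minus))
    p = float(min(sps.kstwobign.sf(d * np.sqrt(n)), 1.0))
    return TestResult(statistic=d, p_value=p, df=None)


def variance_ratio_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-tailed F-test of variance equality; F = larger s^2 / smaller s^2."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ContractError("variance test requires n >= 2 in both samples")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0 or vy == 0:
        raise DegenerateSampleError("zero variance; F-test undefined")
    if vx >= vy:
        f, df = vx / vy, (x.size - 1, y.size - 1)
    else:
        f, df = vy / vx, (y.size - 1, x.size - 1)
    p = float(min(2.0 * sps.f.sf(f, *df), 1.0))
    return TestResult(statistic=float(f), p_value=p, df=df)


@dataclass(frozen=True)
class MethodComparison:
    """Bundled comparison of two methods on one paired sample."""

    sample: PairedSample
    normality: TestResult
    paired_t: TestResult | None
    pearson: TestResult
    regression: RegressionFit
    notes: tuple[str, ...] = ()

    def to_text(self) -> str:
        lines = [f"n = {self.sample.n} paired measurements"]
        lines.append(
            f"KS normality of differences: D = {self.normality.statistic:.4f}, "
            f"p = {self.normality.p_value:.4f} (asymptotic)"
        )
        if self.paired_t is not None:
            lines.append(
                f"paired t-test (two-tailed): t = {self.paired_t.statistic:.4f}, "
                f"df = {self.paired_t.df}, p = {self.paired_t.p_value:.4f}"
            )
        lines.append(
            f"Pearson correlation: R = {self.pearson.statistic:.4f}, "
            f"p = {self.pearson.p_value:.4g}"
        )
        lines.append(
            f"linear regression: slope = {self.regression.slope:.4f}, "
            f"intercept = {self.regression.intercept:.4f}, "
            f"r^2 = {self.regression.r_squared:.4f}"
        )
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)

    def to_records(self) -> list[dict]:
        rows = [
            {
                "quantity": "ks_normality_of_differences",
                "statistic": self.normality.statistic,
                "df": "",
                "p_value": self.normality.p_value,
            },
            {
                "quantity": "pearson_r",
                "statistic": self.pearson.statistic,
                "df": self.pearson.df,
                "p_value": self.pearson.p_value,
            },
            {
                "quantity": "ols_slope",
                "statistic": self.regression.slope,
                "df": "",
                "p_value": "",
            },
            {
                "quantity": "ols_intercept",
                "statistic": self.regression.intercept,
                "df": "",
                "p_value": "",
            },
            {
                "quantity": "ols_r_squared",
                "statistic": self.regression.r_squared,
                "df": "",
                "p_value": "",
            },
        ]
        if self.paired_t is not None:
            rows.insert(
                1,
                {
                    "quantity": "paired_t",
                    "statistic": self.paired_t.statistic,
                    "df": self.paired_t.df,
                    "p_value": self.paired_t.p_value,
                },
            )
        return rows


def compare_methods(s: PairedSample) -> MethodComparison:
    """Full comparison report: normality of differences, paired t, R, OLS.

    If the paired differences are constant the t-test is undefined; for
    identical methods (x == y exactly) this is reported as a note instead
    of an error, since "no difference" is the informative outcome.
    """
    notes: list[str] = []
    d = s.x - s.y
    try:
        normality = ks_normality(d)
    except DegenerateSampleError:
        normality = TestResult(statistic=0.0, p_value=1.0, df=None)
        notes.append("differences are constant; normality check degenerate")
    try:
        t_res: TestResult | None = paired_t_test(s)
    except DegenerateSampleError:
        t_res = None
        if np.all(d == 0):
            notes.append("methods are identical on this sample; paired t undefined")
        else:
            notes.append("constant nonzero differences; paired t undefined")
    pearson = pearson_r(s)
    regression = linear_regression(s)
    return MethodComparison(
        sample=s,
        normality=normality,
        paired_t=t_res,
        pearson=pearson,
        regression=regression,
        notes=tuple(notes),
    )
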