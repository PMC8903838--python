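"""Size-distribution statistics for spine-head and PSD95 areas.

Synaptic size distributions are positively skewed and approximately
log-normal; analyses therefore run on base-10 logarithms where a Gaussian
description applies. Provided here: median/IQR/skewness summaries, moments of
log10 data, a Gaussian least-squares fit to the log-histogram, and the two
comparisons used for such data — the two-sample Kolmogorov–Smirnov test on raw
(skewed) samples and Welch's unequal-variance t-test on log-transformed ones.

Base 10 is used throughout: the study-scale log means (≈ −0.26 log10 µm² for
spine heads) are consistent with the ≈ 0.5 µm² medians only in base 10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .data_model import ValidationError

__all__ = [
    "AreaSummary",
    "LogStats",
    "GaussianFit",
    "summarize_areas",
    "log_stats",
    "fit_gaussian_to_log_histogram",
    "compare_distributions_ks",
    "compare_log_means_welch",
]


class FitError(RuntimeError):
    """Histogram fit is degenerate or failed to converge."""


@dataclass(frozen=True)
class AreaSummary:
    n: int
    median: float  # µm²
    q1: float
    q3: float
    skewness: float  # adjusted Fisher–Pearson, dimensionless

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


@dataclass(frozen=True)
class LogStats:
    """Moments of log10-transformed areas (unbiased n−1 variance)."""

    n: int
    mean_log10: float
    var_log10: float
    skewness_raw: float  # skewness of the untransformed areas


@dataclass(frozen=True)
class GaussianFit:
    """amplitude · exp(−(x − mu)² / (2 sigma²)) fitted to a log10 histogram."""

    mu: float
    sigma: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.amplitude <= 0:
            raise ValidationError("sigma and amplitude must be > 0")


def _positive_array(areas, min_n: int = 1) -> np.ndarray:
    a = np.asarray(areas, dtype=float)
    if a.size < min_n:
        raise ValidationError(f"need at least {min_n} value(s), got {a.size}")
    if not np.all(a > 0):
        raise ValidationError("areas must be strictly positive")
    return a


def _sample_skew(a: np.ndarray) -> float:
    """Adjusted Fisher–Pearson skewness; NaN when undefined (n < 3, constant)."""
    if a.size < 3 or np.ptp(a) == 0:
        return float("nan")
    return float(stats.skew(a, bias=False))


def summarize_areas(areas) -> AreaSummary:
    """Median, quartiles (linear interpolation) and sample skewness."""
    a = _positive_array(areas)
    q1, med, q3 = np.percentile(a, [25, 50, 75])
    return AreaSummary(n=a.size, median=float(med), q1=float(q1), q3=float(q3),
                       skewness=_sample_skew(a))


def log_stats(areas) -> LogStats:
    """Mean and unbiased variance of log10(area), plus raw skewness."""
    a = _positive_array(areas, min_n=2)
    la = np.log10(a)
    return LogStats(
        n=a.size,
        mean_log10=float(la.mean()),
        var_log10=float(la.var(ddof=1)),
        skewness_raw=_sample_skew(a),
    )


def fit_gaussian_to_log_histogram(
    areas, bin_width: float = 0.1
) -> GaussianFit:
    """Least-squares Gaussian fit to the histogram of log10 areas.

    Bins are left-closed with fixed width on the log10 axis, anchored at a
    multiple of ``bin_width``; the curve is fitted to bin centers vs counts.
    Requires >= 5 non-empty bins.
    """
    a = np.log10(_positive_array(areas, min_n=5))
    lo = np.floor(a.min() / bin_width) * bin_width
    hi = np.ceil(a.max() / bin_width) * bin_width + bin_width / 2
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(a, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    nonempty = counts > 0
    if nonempty.sum() < 5:
        raise FitError(
            f"only {int(nonempty.sum())} non-empty bin(s); need >= 5 for a "
            "3-parameter Gaussian fit"
        )

    def gauss(x, amplitude, mu, sigma):
        return amplitude * np.exp(-((x - mu) ** 2) / (2 * sigma**2))

    p0 = (counts.max(), float(a.mean()), max(float(a.std(ddof=1)), bin_width / 2))
    try:
        popt, _ = optimize.curve_fit(
            gauss, centers[nonempty], counts[nonempty], p0=p0, maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise FitError(f"Gaussian histogram fit did not converge: {exc}") from exc
    amplitude, mu, sigma = popt
    return GaussianFit(mu=float(mu), sigma=float(abs(sigma)),
                       amplitude=float(abs(amplitude)))


def compare_distributions_ks(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test (asymptotic p), for skewed data."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def compare_log_means_welch(a, b) -> tuple[float, float, float]:
    """Welch's t-test on log10 data: (t, Welch–Satterthwaite df, 2-sided p)."""
    la = np.log10(_positive_array(a, min_n=2))
    lb = np.log10(_positive_array(b, min_n=2))
    va, vb = la.var(ddof=1), lb.var(ddof=1)
    if va == 0 and vb == 0 and la.mean() == lb.mean():
        raise ValidationError(
            "both samples constant and equal: Welch statistic undefined"
        )
    res = stats.ttest_ind(la, lb, equal_var=False)
    na, nb = la.size, lb.size
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    return float(res.statistic), float(df), float(res.pvalue)
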