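"""Descriptive statistics for annual index fields.

Covers the yearly summary table (mean, median, extremes, SD, CV%, sample
skewness and excess kurtosis), the agronomic CV homogeneity classes
(< 12% low, 12-24% medium, > 24% high), a Lilliefors-corrected
Kolmogorov-Smirnov normality test, and Tukey five-number boxplot summaries
with 1.5*IQR outlier screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "SummaryStats",
    "BoxplotSummary",
    "summarize",
    "classify_cv",
    "ks_normality",
    "boxplot_summary",
]


@dataclass
class SummaryStats:
    year: int
    n: int
    mean: float
    median: float
    min: float
    max: float
    sd: float
    cv_pct: float
    skewness: float
    kurtosis_excess: float
    cv_class: str
    ks_stat: float = np.nan
    ks_p: float = np.nan
    normal_at_1pct: bool | None = None


@dataclass
class BoxplotSummary:
    year: int
    min_whisker: float
    q1: float
    median: float
    q3: float
    max_whisker: float
    outliers: list[float] = field(default_factory=list)


def classify_cv(cv_pct: float) -> str:
    """CV homogeneity class: < 12% low, 12-24% medium (inclusive), > 24% high."""
    if cv_pct < 0:
        raise ValueError("CV cannot be negative")
    if cv_pct < 12.0:
        return "low"
    if cv_pct <= 24.0:
        return "medium"
    return "high"


def summarize(values, year: int, ks: bool = True, alpha: float = 0.01) -> SummaryStats:
    """Yearly descriptive summary of an index sample.

    Uses the sample (n-1) standard deviation; skewness and kurtosis are the
    bias-corrected sample-adjusted forms (excess kurtosis: a normal sample
    reads ~0).  A constant sample gets skewness/kurtosis 0 by convention.
    Needs n >= 4 so kurtosis is defined.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError(f"need at least 4 values, got {x.size}")
    sd = float(np.std(x, ddof=1))
    mean = float(np.mean(x))
    if sd == 0.0:
        skew = kurt = 0.0
    else:
        skew = float(sps.skew(x, bias=False))
        kurt = float(sps.kurtosis(x, fisher=True, bias=False))
    cv = 100.0 * sd / mean if mean != 0 else np.nan
    out = SummaryStats(
        year=int(year),
        n=int(x.size),
        mean=mean,
        median=float(np.median(x)),
        min=float(np.min(x)),
        max=float(np.max(x)),
        sd=sd,
        cv_pct=float(cv),
        skewness=skew,
        kurtosis_excess=kurt,
        cv_class=classify_cv(cv) if np.isfinite(cv) else "low",
    )
    if ks and x.size >= 5:
        try:
            stat, p, normal = ks_normality(x, alpha=alpha)
        except ValueError:
            stat, p, normal = np.nan, np.nan, False
        out.ks_stat, out.ks_p, out.normal_at_1pct = stat, p, normal
    return out


def ks_normality(values, alpha: float = 0.01):
    """KS test against a normal with estimated parameters (Lilliefors).

    Returns (statistic, p, normal) with normal = (p > alpha).  The
    Lilliefors correction is used because the reference normal's mean and SD
    are fitted from the same sample, which makes the plain KS p-value
    anti-conservative.  A zero-variance sample is not testable: raises.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError(f"need at least 5 values for the KS test, got {x.size}")
    if np.std(x, ddof=1) == 0.0:
        raise ValueError("zero-variance sample: normality test undefined")
    stat, p = lilliefors(x, dist="norm", pvalmethod="table")
    return float(stat), float(p), bool(p > alpha)


def boxplot_summary(values, year: int) -> BoxplotSummary:
    """Tukey five-number summary with 1.5*IQR fences.

    Quartiles use linear interpolation between order statistics; whiskers
    sit at the most extreme points inside the fences; everything outside is
    an outlier.  Needs n >= 5.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError(f"need at least 5 values, got {x.size}")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo) & (x <= hi)]
    out = np.sort(x[(x < lo) | (x > hi)])
    return BoxplotSummary(
        year=int(year),
        min_whisker=float(inside.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max_whisker=float(inside.max()),
        outliers=[float(v) for v in out],
    )
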