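"""Empirical semivariograms, theoretical models, and WLS model fitting.

The empirical semivariogram is the classical Matheron estimator

    gamma(h) = 1/(2 N(h)) * sum over pairs at lag h of (Z(x_i) - Z(x_i+h))^2

binned over distance classes.  Three isotropic model families are supported
(spherical, exponential, gaussian), all parameterised by a nugget ``C0``, a
TOTAL sill ``C0 + C`` and a practical range ``a`` (the exponential and
gaussian forms use the -3 scaling so that gamma(a) = C0 + 0.95*C).  Fitting
is bounded weighted least squares with Cressie weights N(h)/gamma_model(h)^2
and a small multi-start to avoid local minima.

The degree of spatial dependence (DSD) is the nugget-to-sill ratio in
percent: < 25% strong, 25-75% moderate, > 75% weak spatial dependence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

FAMILIES = ("spherical", "exponential", "gaussian")

__all__ = [
    "FAMILIES",
    "EmpiricalVariogram",
    "VariogramModel",
    "VariogramEstimator",
    "empirical_semivariogram",
    "model_semivariance",
    "fit_model",
    "dsd",
]


@dataclass
class EmpiricalVariogram:
    """Binned semivariance estimates.

    ``semivariances`` is NaN for bins that received no pairs; such bins are
    kept so the lag layout stays regular, and skipped by the fitter.
    """

    lag_centers: np.ndarray
    semivariances: np.ndarray
    pair_counts: np.ndarray
    lag_width: float
    max_dist: float

    def defined(self) -> np.ndarray:
        """Boolean mask of bins holding at least one pair."""
        return self.pair_counts > 0


@dataclass
class VariogramModel:
    """A fitted (or hand-specified) isotropic semivariogram model."""

    family: str
    nugget_c0: float
    sill_total: float
    range_a: float
    dsd_pct: float = field(default=np.nan)
    dsd_class: str = field(default="")
    fit_r2: float = field(default=np.nan)
    fit_weighted_sse: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown variogram family {self.family!r}")
        if not (0.0 <= self.nugget_c0 <= self.sill_total):
            raise ValueError(
                f"need 0 <= nugget <= sill, got C0={self.nugget_c0}, "
                f"sill={self.sill_total}"
            )
        if self.range_a <= 0:
            raise ValueError("range must be positive")
        if np.isnan(self.dsd_pct) and self.sill_total > 0:
            self.dsd_pct, self.dsd_class = dsd(self.nugget_c0, self.sill_total)

    def semivariance(self, h) -> np.ndarray:
        """gamma(h) for this model; gamma(0) = 0 exactly."""
        return model_semivariance(
            self.family, self.nugget_c0, self.sill_total, self.range_a, h
        )

    def covariance(self, h) -> np.ndarray:
        """Stationary covariance C(h) = sill - gamma(h) implied by the model."""
        return self.sill_total - self.semivariance(h)


def model_semivariance(family, nugget_c0, sill_total, range_a, h):
    """Evaluate a theoretical semivariogram at distance(s) ``h`` (meters).

    gamma(0) = 0 by convention (the nugget is a jump as h -> 0+); for h > 0:

    - spherical:   C0 + C*(1.5 h/a - 0.5 (h/a)^3) for h <= a, else C0 + C
    - exponential: C0 + C*(1 - exp(-3 h / a))
    - gaussian:    C0 + C*(1 - exp(-3 h^2 / a^2))

    with partial sill C = sill_total - nugget_c0.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("distances must be non-negative")
    if family not in FAMILIES:
        raise ValueError(f"unknown variogram family {family!r}")
    c = sill_total - nugget_c0
    hr = h / range_a
    if family == "spherical":
        g = np.where(hr <= 1.0, 1.5 * hr - 0.5 * hr**3, 1.0)
    elif family == "exponential":
        g = 1.0 - np.exp(-3.0 * hr)
    else:  # gaussian
        g = 1.0 - np.exp(-3.0 * hr**2)
    out = np.where(h > 0, nugget_c0 + c * g, 0.0)
    return out if out.ndim else float(out)


def empirical_semivariogram(
    points,
    values,
    n_lags: int = 12,
    lag_width: float | None = None,
    max_dist: float | None = None,
) -> EmpiricalVariogram:
    """Matheron estimator binned into ``n_lags`` uniform distance classes.

    Parameters
    ----------
    points : (n, 2) array of planar coordinates in meters.
    values : (n,) array of the regionalized variable.
    lag_width, max_dist : bin layout; by default max_dist is half the maximum
        pairwise distance and lag_width = max_dist / n_lags.

    Zero-distance pairs (duplicate coordinates) carry no spatial information
    at h > 0 and are excluded with a warning.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(values)
    if points.shape != (n, 2):
        raise ValueError("points must be (n, 2) and aligned with values")
    if n < 2:
        raise ValueError(f"need at least 2 points, got {n}")
    if n < 10:
        warnings.warn(
            f"semivariogram from only {n} points is unreliable", stacklevel=2
        )

    d = pdist(points)
    if np.any(d == 0):
        warnings.warn(
            "duplicate coordinates: zero-distance pairs excluded from the "
            "semivariogram",
            stacklevel=2,
        )
    sq = pdist(values[:, None], metric="sqeuclidean")

    if max_dist is None:
        max_dist = 0.5 * float(d.max())
    if lag_width is None:
        lag_width = max_dist / n_lags
    if lag_width <= 0:
        raise ValueError("lag_width must be positive")
    n_lags = int(np.ceil(max_dist / lag_width - 1e-12))

    all_bins = np.floor(d / lag_width).astype(np.intp)
    keep = (d > 0) & (all_bins < n_lags)
    if not np.any(keep):
        raise ValueError("all point pairs lie beyond max_dist; empty variogram")
    bins = all_bins[keep]
    counts = np.bincount(bins, minlength=n_lags)
    sums = np.bincount(bins, weights=sq[keep], minlength=n_lags)
    dsums = np.bincount(bins, weights=d[keep], minlength=n_lags)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sums / (2.0 * counts), np.nan)
        # lag center = mean pair distance in the bin (midpoint if empty):
        # gridded data fill bins unevenly, and midpoints would misattribute
        # the estimate and bias the fitted nugget upward
        centers = np.where(
            counts > 0,
            dsums / np.maximum(counts, 1),
            (np.arange(n_lags) + 0.5) * lag_width,
        )
    return EmpiricalVariogram(
        lag_centers=centers,
        semivariances=gamma,
        pair_counts=counts,
        lag_width=float(lag_width),
        max_dist=float(n_lags * lag_width),
    )


def dsd(nugget_c0: float, sill_total: float) -> tuple[float, str]:
    """Degree of spatial dependence: 100*C0/sill and its class.

    < 25% strong, 25-75% moderate (inclusive), > 75% weak.
    """
    if sill_total <= 0:
        raise ValueError("DSD undefined for non-positive sill")
    if not 0 <= nugget_c0 <= sill_total:
        raise ValueError("need 0 <= nugget <= sill")
    pct = 100.0 * nugget_c0 / sill_total
    if pct < 25.0:
        cls = "strong"
    elif pct <= 75.0:
        cls = "moderate"
    else:
        cls = "weak"
    return pct, cls


class FitError(RuntimeError):
    """Raised when no multi-start WLS attempt converges to a usable model."""


def _wls_fit(h, g, n_pairs, family, x0, bounds):
    """One bounded least-squares start. x = (c0, c, a); Cressie residuals."""

    def resid(x):
        c0, c, a = x
        gm = model_semivariance(family, c0, c0 + c, a, h)
        gm = np.maximum(gm, 1e-12)
        return np.sqrt(n_pairs) * (g - gm) / gm

    return least_squares(resid, x0, bounds=bounds, method="trf", xtol=1e-12)


class VariogramEstimator(BaseEstimator):
    """Fit an isotropic semivariogram model to point data, sklearn-style.

    Computes the empirical (Matheron) semivariogram of ``(X, y)`` and fits
    the requested model family by bounded multi-start WLS with Cressie
    weights ``N(h)/gamma_model(h)^2``.

    Parameters
    ----------
    family : {'spherical', 'exponential', 'gaussian'}
    n_lags, lag_width, max_dist : empirical-variogram bin layout
        (defaults: 12 uniform bins out to half the maximum pair distance).

    Attributes
    ----------
    nugget_, sill_, range_ : fitted parameters (sill_ is the total sill).
    dsd_pct_, dsd_class_ : degree of spatial dependence.
    model_ : the fitted :class:`VariogramModel`.
    empirical_ : the :class:`EmpiricalVariogram` the fit was based on.
    """

    def __init__(
        self,
        family: str = "gaussian",
        n_lags: int = 12,
        lag_width: float | None = None,
        max_dist: float | None = None,
    ):
        self.family = family
        self.n_lags = n_lags
        self.lag_width = lag_width
        self.max_dist = max_dist

    def fit(self, X, y):
        emp = empirical_semivariogram(
            X, y, n_lags=self.n_lags, lag_width=self.lag_width,
            max_dist=self.max_dist,
        )
        self.model_ = fit_model(emp, self.family)
        self.empirical_ = emp
        self.nugget_ = self.model_.nugget_c0
        self.sill_ = self.model_.sill_total
        self.range_ = self.model_.range_a
        self.dsd_pct_ = self.model_.dsd_pct
        self.dsd_class_ = self.model_.dsd_class
        return self

    def predict_semivariance(self, h):
        check_is_fitted(self, "model_")
        return self.model_.semivariance(h)


def fit_model(emp: EmpiricalVariogram, family: str) -> VariogramModel:
    """Fit one model family to an empirical semivariogram by Cressie WLS.

    Three starts (method-of-moments, flat/high-nugget, steep/short-range);
    the winner has the lowest weighted SSE, ties broken by lower nugget.
    Requires >= 4 non-empty lag bins.
    """
    ok = emp.defined()
    if ok.sum() < 4:
        raise FitError(f"only {int(ok.sum())} non-empty lag bins; need >= 4")
    h = emp.lag_centers[ok]
    g = emp.semivariances[ok]
    npairs = emp.pair_counts[ok].astype(float)

    gmax = float(g.max())
    if gmax <= 0:  # constant field: pure-nugget zero model
        return VariogramModel(family, 0.0, 0.0 + 1e-30, emp.max_dist)

    tail = float(np.mean(g[-max(1, len(g) // 3):]))
    head = float(np.clip(g[0], 0.0, tail))
    a_lo = emp.lag_width / 10.0
    a_hi = 3.0 * emp.max_dist
    bounds = ([0.0, 0.0, a_lo], [2.0 * gmax, 4.0 * gmax, a_hi])
    starts = [
        # method-of-moments: nugget from first bin, sill from the tail
        (head, max(tail - head, 1e-6 * gmax), 0.66 * emp.max_dist),
        # flat: mostly nugget
        (0.9 * tail, max(0.1 * tail, 1e-6 * gmax), 0.33 * emp.max_dist),
        # steep: no nugget, short range
        (0.0, tail, 0.15 * emp.max_dist),
    ]

    best = None
    for x0 in starts:
        x0 = np.clip(x0, bounds[0], bounds[1])
        try:
            res = _wls_fit(h, g, npairs, family, x0, bounds)
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        sse = float(np.sum(res.fun**2))
        key = (sse, res.x[0])
        if best is None or key < best[0]:
            best = (key, res)
    if best is None:
        raise FitError(f"WLS fit failed for family {family!r} on all starts")

    c0, c, a = best[1].x
    sill = c0 + c
    gm = model_semivariance(family, c0, sill, a, h)
    sst = float(np.sum((g - g.mean()) ** 2))
    r2 = 1.0 - float(np.sum((g - gm) ** 2)) / sst if sst > 0 else 1.0
    return VariogramModel(
        family=family,
        nugget_c0=float(c0),
        sill_total=float(sill),
        range_a=float(a),
        fit_r2=r2,
        fit_weighted_sse=best[0][0],
    )
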