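"""Ordinary kriging with kriging standard errors.

Semivariogram-form ordinary kriging: weights at a target location solve

    [ Gamma  1 ] [ w  ]   [ gamma_0 ]
    [ 1^T    0 ] [ mu ] = [ 1       ]

where Gamma holds model semivariances between samples (gamma(0) = 0 on the
diagonal — the whole nugget lives in the variogram, the standard
exact-interpolation convention) and gamma_0 the semivariances to the
target.  The kriging variance is w . gamma_0 + mu.  The unbiasedness
constraint makes the weights sum to 1.

:class:`OrdinaryKriging` is a scikit-learn compatible regressor (fit /
predict with ``return_std``); :func:`kriging_weights` and
:func:`predict_grid` are thin functional wrappers over it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve
from scipy.spatial import cKDTree, distance

from .region import RegionSpec
from .variogram import VariogramModel

__all__ = ["OrdinaryKriging", "KrigingResult", "kriging_weights", "predict_grid"]

_COINCIDE_TOL = 1e-9


class SingularKrigingSystem(np.linalg.LinAlgError):
    pass


def _augmented_matrix(coords: np.ndarray, model: VariogramModel) -> np.ndarray:
    n = len(coords)
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = model.semivariance(distance.squareform(distance.pdist(coords)))
    a[:n, n] = 1.0
    a[n, :n] = 1.0
    a[n, n] = 0.0
    return a


class OrdinaryKriging:
    """Ordinary-kriging interpolator as a scikit-learn style regressor.

    Parameters
    ----------
    variogram : VariogramModel
        Fitted semivariogram model of the variable being interpolated.
    max_n : int or None
        If set, use at most this many nearest samples per target (local
        neighborhood); None (default) uses all samples (global).
    radius_m : float or None
        If set, restrict the local neighborhood to this search radius.
        Targets with fewer than 2 samples in the radius come back NaN.

    Attributes
    ----------
    X_, y_ : training coordinates (n, 2) and values (n,).
    n_samples_ : number of training samples.
    """

    def __init__(
        self,
        variogram: VariogramModel | None = None,
        max_n: int | None = None,
        radius_m: float | None = None,
    ):
        self.variogram = variogram
        self.max_n = max_n
        self.radius_m = radius_m

    # -- sklearn plumbing ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "variogram": self.variogram,
            "max_n": self.max_n,
            "radius_m": self.radius_m,
        }

    def set_params(self, **params) -> "OrdinaryKriging":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- estimator API ------------------------------------------------------
    def fit(self, X, y) -> "OrdinaryKriging":
        if self.variogram is None:
            raise ValueError("OrdinaryKriging requires a fitted variogram model")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2 or len(X) != len(y):
            raise ValueError("X must be (n, 2) and aligned with y")
        if len(X) < 1:
            raise ValueError("need at least one sample")
        if len(X) > 1:
            d = distance.pdist(X)
            if d.min() <= _COINCIDE_TOL:
                raise ValueError(
                    "duplicate sample coordinates make the kriging system "
                    "singular; deduplicate the input"
                )
        self.X_ = X
        self.y_ = y
        self.n_samples_ = len(y)
        self._lu = None
        self._tree = None
        if self.max_n is None and self.radius_m is None and len(X) > 1:
            a = _augmented_matrix(X, self.variogram)
            try:
                self._lu = lu_factor(a)
            except np.linalg.LinAlgError as err:  # pragma: no cover
                raise SingularKrigingSystem(str(err)) from err
        else:
            self._tree = cKDTree(X)
        return self

    def _check_fitted(self):
        if not hasattr(self, "X_"):
            raise ValueError("this OrdinaryKriging instance is not fitted yet")

    def _solve_global(self, targets: np.ndarray):
        n = self.n_samples_
        d0 = distance.cdist(self.X_, targets)
        rhs = np.empty((n + 1, len(targets)))
        rhs[:n] = self.variogram.semivariance(d0)
        rhs[n] = 1.0
        if n == 1:
            w = np.ones((1, len(targets)))
            mu = rhs[0]  # Lagrange multiplier equals gamma(d) when n = 1
        else:
            sol = lu_solve(self._lu, rhs)
            w, mu = sol[:n], sol[n]
        pred = w.T @ self.y_
        var = np.einsum("ij,ij->j", w, rhs[:n]) + mu
        return pred, var, w, mu

    def _solve_local(self, target: np.ndarray):
        k = min(self.max_n or self.n_samples_, self.n_samples_)
        dist_, idx = self._tree.query(target, k=k)
        dist_, idx = np.atleast_1d(dist_), np.atleast_1d(idx)
        if self.radius_m is not None:
            keep = dist_ <= self.radius_m
            dist_, idx = dist_[keep], idx[keep]
        if len(idx) < 2:
            return np.nan, np.nan
        a = _augmented_matrix(self.X_[idx], self.variogram)
        rhs = np.concatenate([self.variogram.semivariance(dist_), [1.0]])
        try:
            sol = np.linalg.solve(a, rhs)
        except np.linalg.LinAlgError:
            return np.nan, np.nan
        w, mu = sol[:-1], sol[-1]
        return float(w @ self.y_[idx]), float(w @ rhs[:-1] + mu)

    def predict(self, X, return_std: bool = False):
        """Kriging prediction (and standard error) at target coordinates.

        Targets coinciding with a sample return the sample value with zero
        standard error (exact interpolation).  Negative kriging variances
        from round-off are clipped at zero with a warning.
        """
        self._check_fitted()
        targets = np.asarray(X, dtype=float)
        if targets.ndim != 2 or targets.shape[1] != 2:
            raise ValueError("targets must be (m, 2)")
        m = len(targets)
        pred = np.empty(m)
        var = np.empty(m)

        d_samp = distance.cdist(targets, self.X_)
        hit = d_samp.min(axis=1) <= _COINCIDE_TOL
        if np.any(hit):
            pred[hit] = self.y_[d_samp[hit].argmin(axis=1)]
            var[hit] = 0.0
        todo = ~hit
        if np.any(todo):
            if self._lu is not None or self.n_samples_ == 1:
                p, v, _, _ = self._solve_global(targets[todo])
                pred[todo], var[todo] = p, v
            else:
                for j in np.flatnonzero(todo):
                    pred[j], var[j] = self._solve_local(targets[j])
        if np.any(var < -1e-8 * max(self.variogram.sill_total, 1.0)):
            warnings.warn("negative kriging variance clipped to 0", stacklevel=2)
        var = np.clip(var, 0.0, None)
        if return_std:
            return pred, np.sqrt(var)
        return pred

    def score(self, X, y):
        """R^2 of predictions, for sklearn model-selection compatibility."""
        y = np.asarray(y, dtype=float)
        pred = self.predict(X)
        sst = np.sum((y - y.mean()) ** 2)
        return 1.0 - float(np.sum((y - pred) ** 2)) / sst if sst > 0 else 0.0


def kriging_weights(sample_locs, sample_vals, target, model: VariogramModel):
    """Ordinary-kriging weights, Lagrange multiplier and variance for one target.

    Thin wrapper over :class:`OrdinaryKriging`; the weights solve the
    augmented system and sum to 1 (a single sample degenerately gets
    weight 1).
    """
    ok = OrdinaryKriging(variogram=model).fit(sample_locs, sample_vals)
    target = np.asarray(target, dtype=float).reshape(1, 2)
    _, var, w, mu = ok._solve_global(target)
    return w[:, 0], float(np.atleast_1d(mu)[0]), float(max(var[0], 0.0))


@dataclass
class KrigingResult:
    """A kriged surface: prediction and standard-error rasters.

    ``values``/``sigma`` are (nrows, ncols) arrays with rows ordered from
    south to north (index 0 = ymin); NaN marks no-data cells.  ``xs``/``ys``
    are the cell-center coordinates.
    """

    values: np.ndarray
    sigma: np.ndarray
    xs: np.ndarray
    ys: np.ndarray
    cell_m: float
    model: VariogramModel

    @property
    def xllcorner(self) -> float:
        return float(self.xs[0] - self.cell_m / 2)

    @property
    def yllcorner(self) -> float:
        return float(self.ys[0] - self.cell_m / 2)

    def valid_values(self) -> np.ndarray:
        v = self.values.ravel()
        return v[np.isfinite(v)]


def predict_grid(
    samples: pd.DataFrame,
    model: VariogramModel,
    region: RegionSpec,
    cell_m: float = 4000.0,
    max_n: int | None = None,
    radius_m: float | None = None,
) -> KrigingResult:
    """Krige a point table onto a regular raster over the region.

    ``samples`` needs columns x_m, y_m and thi (or a single value column
    named ``thi``).  Cell centers are laid on the region's own lattice
    (first center at the bounds corner), so sample locations on the lattice
    are reproduced exactly.  Cells whose center falls in no subregion, or
    with fewer than 2 local neighbors, are NaN.
    """
    if cell_m <= 0:
        raise ValueError("cell_m must be positive")
    if samples.empty:
        raise ValueError("no samples to interpolate")
    coords = samples[["x_m", "y_m"]].to_numpy(float)
    vals = samples["thi"].to_numpy(float)
    xmin, ymin, xmax, ymax = region.bounds
    xs = xmin + cell_m * np.arange(int(np.floor((xmax - xmin) / cell_m + 1e-9)) + 1)
    ys = ymin + cell_m * np.arange(int(np.floor((ymax - ymin) / cell_m + 1e-9)) + 1)
    gx, gy = np.meshgrid(xs, ys)
    targets = np.column_stack([gx.ravel(), gy.ravel()])

    inside = np.array(
        [region.label_point(x, y) is not None for x, y in targets]
    )
    ok = OrdinaryKriging(variogram=model, max_n=max_n, radius_m=radius_m)
    ok.fit(coords, vals)
    pred = np.full(len(targets), np.nan)
    sig = np.full(len(targets), np.nan)
    if not np.any(inside):
        raise ValueError("no raster cell falls inside the region")
    p, s = ok.predict(targets[inside], return_std=True)
    pred[inside], sig[inside] = p, s
    shape = (len(ys), len(xs))
    return KrigingResult(
        values=pred.reshape(shape),
        sigma=sig.reshape(shape),
        xs=xs,
        ys=ys,
        cell_m=float(cell_m),
        model=model,
    )
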