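"""Synthetic multi-year climate fields with prescribed spatial structure.

Stands in for a gridded remote-sensing climate export: annual maximum and
minimum air temperature and mean wind speed on a ~4-km point lattice, each
drawn from a stationary Gaussian random field whose semivariogram is one of
the spherical/exponential/gaussian families.  The covariance used for
simulation is the one the variogram model implies, C(h) = sill - gamma(h)
for h > 0 and C(0) = sill, realized by dense Cholesky factorization (the
intended scale is desk-size grids, <= 5000 points).

All draws are pure functions of (region, parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .region import RegionSpec, lonlat_from_xy
from .variogram import FAMILIES, model_semivariance

__all__ = ["FieldParams", "simulate_gaussian_field", "simulate_climate_series"]

MAX_DENSE_POINTS = 5000
CLIMATE_COLUMNS = [
    "point_id", "x_m", "y_m", "lon", "lat", "region", "year",
    "tmax_c", "tmin_c", "ws_ms",
]


@dataclass
class FieldParams:
    """Spatial-structure parameters of one simulated variable.

    mean : field average, in the variable's units.
    model : variogram family ('spherical' | 'exponential' | 'gaussian').
    nugget, sill : variance units (sill is the TOTAL sill, >= nugget).
    range_m : practical range in meters.
    trend : optional (per-km-x, per-km-y) linear spatial gradient, applied
        around the domain center so the field mean stays `mean`.
    """

    mean: float
    model: str = "gaussian"
    nugget: float = 0.0
    sill: float = 1.0
    range_m: float = 50_000.0
    trend: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.model not in FAMILIES:
            raise ValueError(f"unknown variogram family {self.model!r}")
        if self.nugget < 0 or self.sill < self.nugget:
            raise ValueError("need 0 <= nugget <= sill")
        if self.range_m <= 0:
            raise ValueError("range_m must be positive")


def simulate_gaussian_field(
    region: RegionSpec, params: FieldParams, seed
) -> np.ndarray:
    """One draw of a stationary Gaussian field at the region's grid points.

    ``seed`` may be an int or a numpy Generator/SeedSequence.  The same seed
    reproduces the same values exactly.
    """
    if region.points is None:
        raise ValueError("region has no materialized points; use make_region")
    coords = region.points[["x_m", "y_m"]].to_numpy(float)
    n = len(coords)
    if n > MAX_DENSE_POINTS:
        raise ValueError(
            f"{n} points exceeds the dense-covariance guard "
            f"({MAX_DENSE_POINTS}); coarsen the grid"
        )
    rng = np.random.default_rng(seed)

    if params.sill == 0.0:
        values = np.full(n, params.mean)
    else:
        gam = model_semivariance(
            params.model, params.nugget, params.sill, params.range_m,
            squareform(pdist(coords)),
        )
        cov = params.sill - gam  # C(0)=sill on the diagonal, nugget drop off it
        cov[np.diag_indices(n)] += 1e-10 * params.sill
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "covariance not positive definite after nugget "
                f"regularization (model={params.model}, sill={params.sill}, "
                f"range={params.range_m})"
            ) from err
        values = params.mean + chol @ rng.standard_normal(n)

    if params.trend is not None:
        tx, ty = params.trend
        cx = coords.mean(axis=0)
        values = values + (coords[:, 0] - cx[0]) / 1000.0 * tx
        values = values + (coords[:, 1] - cx[1]) / 1000.0 * ty
    return values


def simulate_climate_series(
    region: RegionSpec,
    years: list[int],
    tmax_params: FieldParams,
    tmin_params: FieldParams,
    ws_params: FieldParams,
    seed: int,
    min_temp_gap: float = 0.2,
) -> pd.DataFrame:
    """Simulate an annual Tmax/Tmin/Ws table, one row per point-year.

    Tmax, Tmin and Ws are independent fields, redrawn each year (years are
    independent realizations of the same spatial structure).  Physical
    constraints are enforced after the draw: Tmin is clipped to at most
    Tmax - ``min_temp_gap`` (degC) and Ws is truncated at 0.
    """
    if not years:
        raise ValueError("year list is empty")
    if tmax_params.mean <= tmin_params.mean:
        raise ValueError("tmax mean must exceed tmin mean")
    if ws_params.mean < 0:
        raise ValueError("wind-speed mean must be non-negative")
    if region.points is None:
        raise ValueError("region has no materialized points; use make_region")

    pts = region.points
    lon, lat = lonlat_from_xy(pts["x_m"].to_numpy(), pts["y_m"].to_numpy())
    frames = []
    # one independent child seed per (year, variable)
    children = np.random.SeedSequence(seed).spawn(len(years) * 3)
    for k, year in enumerate(years):
        tmax = simulate_gaussian_field(region, tmax_params, children[3 * k])
        tmin = simulate_gaussian_field(region, tmin_params, children[3 * k + 1])
        ws = simulate_gaussian_field(region, ws_params, children[3 * k + 2])
        tmin = np.minimum(tmin, tmax - min_temp_gap)
        ws = np.maximum(ws, 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "point_id": pts["point_id"],
                    "x_m": pts["x_m"],
                    "y_m": pts["y_m"],
                    "lon": lon,
                    "lat": lat,
                    "region": pts["region"],
                    "year": year,
                    "tmax_c": tmax,
                    "tmin_c": tmin,
                    "ws_ms": ws,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[CLIMATE_COLUMNS]
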