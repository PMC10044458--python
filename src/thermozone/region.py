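"""Study regions: a rectangular extent partitioned into named subregions.

Coordinates are planar meters in a local frame (distances are Euclidean,
matching variogram ranges given in meters).  A region materializes a regular
point lattice — the synthetic stand-in for a ~4-km climate sampling grid —
with every point labeled by the subregion polygon that contains it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, box
from shapely.ops import unary_union

__all__ = ["RegionSpec", "make_region", "strip_subregions"]

# equirectangular origin used to derive optional lon/lat columns
_ORIGIN_LON, _ORIGIN_LAT = -41.0, -9.0
_M_PER_DEG_LAT = 111_320.0


class RegionConfigError(ValueError):
    """Invalid region geometry (overlap, gaps, degenerate bounds)."""


@dataclass
class RegionSpec:
    """A named rectangular study area split into subregion polygons.

    ``bounds`` is (xmin, ymin, xmax, ymax) in meters; ``subregions`` is a
    list of (name, shapely Polygon) that must tile the bounds without
    overlap.  ``points`` (set by :func:`make_region`) is a DataFrame with
    columns ``point_id, x_m, y_m, region``.
    """

    name: str
    bounds: tuple[float, float, float, float]
    subregions: list[tuple[str, Polygon]]
    grid_spacing: float = 4000.0
    points: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def polygon(self) -> Polygon:
        return box(*self.bounds)

    def subregion_names(self) -> list[str]:
        return [name for name, _ in self.subregions]

    def label_point(self, x: float, y: float) -> str | None:
        """Name of the first subregion covering (x, y), or None."""
        p = Point(x, y)
        for name, poly in self.subregions:
            if poly.covers(p):
                return name
        return None


def strip_subregions(
    bounds: tuple[float, float, float, float],
    names: list[str],
    fractions: list[float] | None = None,
) -> list[tuple[str, Polygon]]:
    """Split bounds into vertical strips, one per name (fractions sum to 1)."""
    xmin, ymin, xmax, ymax = bounds
    if fractions is None:
        fractions = [1.0 / len(names)] * len(names)
    if len(fractions) != len(names):
        raise RegionConfigError("one width fraction per subregion name")
    edges = xmin + (xmax - xmin) * np.concatenate([[0.0], np.cumsum(fractions)])
    if not np.isclose(edges[-1], xmax):
        raise RegionConfigError("strip fractions must sum to 1")
    edges[-1] = xmax
    return [
        (name, box(edges[i], ymin, edges[i + 1], ymax))
        for i, name in enumerate(names)
    ]


def make_region(
    name: str,
    bounds: tuple[float, float, float, float],
    subregions: list[tuple[str, Polygon]],
    grid_spacing: float = 4000.0,
) -> RegionSpec:
    """Build a region and materialize its labeled grid-point lattice.

    The lattice includes both boundary corners (floor(extent/spacing) + 1
    points per axis).  Raises ``RegionConfigError`` if subregions overlap,
    leave part of the bounds uncovered, or any lattice point is unlabeled.
    """
    xmin, ymin, xmax, ymax = bounds
    if not (xmax > xmin and ymax > ymin):
        raise RegionConfigError("degenerate bounds")
    if grid_spacing <= 0:
        raise RegionConfigError("grid_spacing must be positive")
    if not subregions:
        raise RegionConfigError("need at least one subregion")

    area_tol = 1e-9 * (xmax - xmin) * (ymax - ymin)
    for i in range(len(subregions)):
        for j in range(i + 1, len(subregions)):
            inter = subregions[i][1].intersection(subregions[j][1])
            if inter.area > area_tol:
                raise RegionConfigError(
                    f"subregions {subregions[i][0]!r} and "
                    f"{subregions[j][0]!r} overlap (area {inter.area:.3g})"
                )
    union = unary_union([poly for _, poly in subregions])
    if box(xmin, ymin, xmax, ymax).difference(union).area > area_tol:
        raise RegionConfigError("subregions do not cover the bounds")

    region = RegionSpec(name, tuple(bounds), list(subregions), float(grid_spacing))
    xs = xmin + grid_spacing * np.arange(int(np.floor((xmax - xmin) / grid_spacing + 1e-9)) + 1)
    ys = ymin + grid_spacing * np.arange(int(np.floor((ymax - ymin) / grid_spacing + 1e-9)) + 1)
    gx, gy = np.meshgrid(xs, ys)
    gx, gy = gx.ravel(), gy.ravel()
    labels = [region.label_point(x, y) for x, y in zip(gx, gy)]
    if any(lab is None for lab in labels):
        bad = next(i for i, lab in enumerate(labels) if lab is None)
        raise RegionConfigError(
            f"grid point ({gx[bad]}, {gy[bad]}) lies in no subregion"
        )
    region.points = pd.DataFrame(
        {
            "point_id": [f"p{i:05d}" for i in range(len(gx))],
            "x_m": gx,
            "y_m": gy,
            "region": labels,
        }
    )
    return region


def lonlat_from_xy(x_m, y_m):
    """Equirectangular lon/lat for planar meters, from a fixed SW origin."""
    lat = _ORIGIN_LAT + np.asarray(y_m) / _M_PER_DEG_LAT
    lon = _ORIGIN_LON + np.asarray(x_m) / (
        _M_PER_DEG_LAT * np.cos(np.deg2rad(_ORIGIN_LAT))
    )
    return lon, lat
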