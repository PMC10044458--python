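"""Breed suitability zoning against critical THI limits.

Each sheep breed carries a critical THI limit above which the environment
is considered heat-stressful for it (hair breeds generally tolerate higher
THI than wool breeds).  A location is suitable for a breed when the mapped
THI does not exceed its limit (inclusive: a breed exactly at its limit is
counted suitable).  Zoning reports per-breed boolean rasters, area
fractions, the per-subregion fractions, and empirical cumulative
distributions of THI by subregion and multi-year period.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .kriging import KrigingResult
from .region import RegionSpec

__all__ = [
    "BreedThreshold",
    "SuitabilityResult",
    "RegionalCDF",
    "load_breed_registry",
    "suitable_breeds",
    "suitability_masks",
    "regional_cdf",
    "DEFAULT_PERIODS",
]

# default multi-year reporting periods (quadrennial)
DEFAULT_PERIODS = {
    "2010-2013": [2010, 2011, 2012, 2013],
    "2014-2017": [2014, 2015, 2016, 2017],
    "2018-2021": [2018, 2019, 2020, 2021],
}


@dataclass(frozen=True)
class BreedThreshold:
    breed: str
    cover: str  # 'hair' | 'wool'
    thi_limit: float


@dataclass
class SuitabilityResult:
    breed: str
    cover: str
    thi_limit: float
    mask: np.ndarray  # boolean raster, True where suitable; aligned to THI raster
    area_fraction_pct: float
    per_region_fraction: dict[str, float]
    usable_regions: list[str] = field(default_factory=list)


@dataclass
class RegionalCDF:
    region: str
    period: str
    sorted_values: np.ndarray

    def cdf_at(self, threshold: float, inclusive: bool = True) -> float:
        """Empirical CDF: fraction of values <= threshold (or < if not)."""
        side = "right" if inclusive else "left"
        return float(
            np.searchsorted(self.sorted_values, threshold, side=side)
            / len(self.sorted_values)
        )


class RegistryError(ValueError):
    pass


def load_breed_registry(path: str | Path | None = None) -> list[BreedThreshold]:
    """Load the breed/cover/THI-limit registry (packaged CSV by default)."""
    if path is None:
        src = resources.files("thermozone").joinpath("data/breeds.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"breed", "cover", "thi_limit"}
    if not required.issubset(df.columns):
        raise RegistryError(f"registry needs columns {sorted(required)}")
    if df["breed"].duplicated().any():
        dup = df.loc[df["breed"].duplicated(), "breed"].iloc[0]
        line = int(df.index[df["breed"] == dup][-1]) + 2  # header is line 1
        raise RegistryError(f"duplicate breed {dup!r} (line {line})")
    bad = pd.to_numeric(df["thi_limit"], errors="coerce").isna()
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise RegistryError(f"non-numeric THI limit at line {line}")
    entries = [
        BreedThreshold(r.breed, r.cover, float(r.thi_limit))
        for r in df.itertuples()
    ]
    for e in entries:
        if e.thi_limit <= 0:
            raise RegistryError(f"non-positive THI limit for {e.breed!r}")
    return entries


def suitable_breeds(thi: float, registry) -> list[BreedThreshold]:
    """Breeds whose critical limit is >= thi, sorted by descending limit."""
    hits = [b for b in registry if b.thi_limit >= thi]
    return sorted(hits, key=lambda b: (-b.thi_limit, b.breed))


def _cell_regions(result: KrigingResult, region: RegionSpec) -> np.ndarray:
    labels = np.empty(result.values.shape, dtype=object)
    for i, y in enumerate(result.ys):
        for j, x in enumerate(result.xs):
            labels[i, j] = region.label_point(x, y)
    return labels


def suitability_masks(
    thi_raster: KrigingResult,
    registry,
    region: RegionSpec,
    min_fraction: float = 100.0,
) -> list[SuitabilityResult]:
    """Per-breed suitability over a kriged THI raster.

    A cell is suitable when THI <= the breed's limit; fractions are over
    non-no-data cells.  A subregion is "usable" for a breed when at least
    ``min_fraction`` percent of its cells are suitable (default 100%).
    """
    vals = thi_raster.values
    valid = np.isfinite(vals)
    if not np.any(valid):
        raise ValueError("raster holds no valid cells")
    labels = _cell_regions(thi_raster, region)
    names = region.subregion_names()
    out = []
    for b in registry:
        mask = valid & (vals <= b.thi_limit)
        area_pct = 100.0 * mask.sum() / valid.sum()
        per_region = {}
        usable = []
        for name in names:
            sel = valid & (labels == name)
            frac = 100.0 * mask[sel].sum() / sel.sum() if sel.any() else np.nan
            per_region[name] = frac
            if np.isfinite(frac) and frac >= min_fraction:
                usable.append(name)
        out.append(
            SuitabilityResult(
                breed=b.breed,
                cover=b.cover,
                thi_limit=b.thi_limit,
                mask=mask,
                area_fraction_pct=float(area_pct),
                per_region_fraction=per_region,
                usable_regions=usable,
            )
        )
    return out


def regional_cdf(thi_fields: pd.DataFrame, region_name: str, period) -> RegionalCDF:
    """Empirical CDF of point THI values in one subregion over a year set.

    ``thi_fields`` is a multi-year THI table (columns region, year, thi);
    ``period`` is a (label, years) pair, a list of years, or a label from
    :data:`DEFAULT_PERIODS`.
    """
    if isinstance(period, str):
        label, years = period, DEFAULT_PERIODS[period]
    elif isinstance(period, tuple):
        label, years = period
    else:
        years = list(period)
        label = f"{min(years)}-{max(years)}"
    if region_name not in set(thi_fields["region"]):
        raise ValueError(f"unknown region {region_name!r}")
    sel = thi_fields[
        (thi_fields["region"] == region_name) & thi_fields["year"].isin(years)
    ]
    if sel.empty:
        raise ValueError(f"no THI values for {region_name!r} in {label}")
    return RegionalCDF(
        region=region_name,
        period=label,
        sorted_values=np.sort(sel["thi"].to_numpy(float)),
    )
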