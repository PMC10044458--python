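"""Readers and writers: climate CSV, ESRI ASCII rasters, YAML configs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kriging import KrigingResult
from .synthetic import CLIMATE_COLUMNS

NODATA = -9999.0

__all__ = [
    "read_climate_csv",
    "write_esri_ascii",
    "read_esri_ascii",
    "load_config",
]


def read_climate_csv(path) -> pd.DataFrame:
    """Read a point climate table; lon/lat columns are optional."""
    df = pd.read_csv(path)
    needed = [c for c in CLIMATE_COLUMNS if c not in ("lon", "lat")]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"climate CSV {path} missing columns {missing}")
    return df


def write_esri_ascii(
    path, array: np.ndarray, xllcorner: float, yllcorner: float,
    cellsize: float, nodata: float = NODATA, fmt: str = "%.4f",
) -> None:
    """Write a raster as an ESRI ASCII grid.

    ``array`` rows are ordered south to north (row 0 = ymin); the format
    stores north first, so rows are flipped on write.  NaN cells become the
    NODATA sentinel.
    """
    arr = np.asarray(array, dtype=float)
    out = np.where(np.isfinite(arr), arr, nodata)
    nrows, ncols = out.shape
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {xllcorner:.4f}\n"
        f"yllcorner {yllcorner:.4f}\n"
        f"cellsize {cellsize:.4f}\n"
        f"NODATA_value {nodata:g}\n"
    )
    body = "\n".join(" ".join(fmt % v for v in row) for row in out[::-1])
    Path(path).write_text(header + body + "\n")


def read_esri_ascii(path):
    """Read an ESRI ASCII grid -> (array rows south-to-north, header dict)."""
    lines = Path(path).read_text().splitlines()
    header = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
    ):
        key, val = lines[i].split()
        header[key.lower()] = float(val)
        i += 1
    arr = np.loadtxt(lines[i:], dtype=float)
    arr = np.atleast_2d(arr)[::-1]  # back to south-first rows
    nodata = header.get("nodata_value", NODATA)
    arr[arr == nodata] = np.nan
    return arr, header


def write_kriging_result(result: KrigingResult, value_path, sigma_path=None):
    write_esri_ascii(
        value_path, result.values, result.xllcorner, result.yllcorner,
        result.cell_m,
    )
    if sigma_path is not None:
        write_esri_ascii(
            sigma_path, result.sigma, result.xllcorner, result.yllcorner,
            result.cell_m,
        )


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} is not a mapping")
    return cfg
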