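"""Temperature-humidity index (THI) from annual air temperature and wind.

The index used here is the quadratic form

    THI = (6.3952 + 0.08964 * Tair + 0.01018 * Ws)^2

with Tair the mean air temperature (degC) and Ws the mean wind speed
(m s^-1).  Despite the name, this variant carries no humidity term; it is
strictly increasing in both arguments over the physical domain, and for
Tair in [20, 32] degC and Ws in [0, 6] m/s spans roughly THI 67-84.  Higher
values mean a more heat-stressful environment for livestock.

Annual THI is the index of annual means: one evaluation per point-year from
that year's mean Tair and Ws (not a mean of monthly indices — the form is
nonlinear, so the two differ).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

THI_INTERCEPT = 6.3952
THI_TAIR_COEF = 0.08964
THI_WS_COEF = 0.01018

THI_COLUMNS = ["point_id", "x_m", "y_m", "region", "year", "tair_c", "thi"]

__all__ = ["mean_air_temperature", "compute_thi", "annual_thi", "thi_table"]


def mean_air_temperature(tmax_c, tmin_c):
    """Tair = (Tmax + Tmin) / 2, validating Tmax > Tmin elementwise."""
    tmax = np.asarray(tmax_c, dtype=float)
    tmin = np.asarray(tmin_c, dtype=float)
    bad = ~(tmax > tmin)
    if np.any(bad):
        idx = np.flatnonzero(np.atleast_1d(bad))[:5].tolist()
        raise ValueError(
            f"tmax_c must exceed tmin_c; violated at row(s) {idx}"
        )
    out = 0.5 * (tmax + tmin)
    return out if out.ndim else float(out)


def compute_thi(tair_c, ws_ms):
    """Evaluate the index; vectorized, exact to float round-off."""
    ws = np.asarray(ws_ms, dtype=float)
    if np.any(ws < 0):
        raise ValueError("wind speed must be non-negative")
    base = THI_INTERCEPT + THI_TAIR_COEF * np.asarray(tair_c, float) + THI_WS_COEF * ws
    out = base**2
    return out if out.ndim else float(out)


def annual_thi(samples: pd.DataFrame, year: int) -> pd.DataFrame:
    """Per-point THI for one year of a climate table.

    ``samples`` needs columns point_id, x_m, y_m, region, year, tmax_c,
    tmin_c, ws_ms.  Returns one row per point with tair_c and thi.  Raises
    on an absent year or duplicate (point_id, year) rows.
    """
    sub = samples[samples["year"] == year]
    if sub.empty:
        raise ValueError(f"no samples for year {year}")
    if sub["point_id"].duplicated().any():
        dup = sub.loc[sub["point_id"].duplicated(), "point_id"].iloc[0]
        raise ValueError(f"duplicate (point_id, year) for {dup!r}, {year}")
    tair = mean_air_temperature(sub["tmax_c"].to_numpy(), sub["tmin_c"].to_numpy())
    thi = compute_thi(tair, sub["ws_ms"].to_numpy())
    out = sub[["point_id", "x_m", "y_m", "region"]].copy().reset_index(drop=True)
    out["year"] = year
    out["tair_c"] = tair
    out["thi"] = thi
    return out[THI_COLUMNS]


def thi_table(samples: pd.DataFrame, years=None) -> pd.DataFrame:
    """annual_thi for every requested year (default: all years present)."""
    if years is None:
        years = sorted(samples["year"].unique())
    return pd.concat(
        [annual_thi(samples, y) for y in years], ignore_index=True
    )
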