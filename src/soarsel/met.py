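"""Soaring-meteorology covariates: thermal height, w*, boundary-layer wind.

Three parameters summarize the atmospheric resource available to a
soaring bird over each 12 km grid cell: the convective boundary-layer
(CBL) depth, read as the maximum thermal height; the convective velocity
scale w*, the characteristic thermal updraft speed; and the wind speed
averaged vertically over the boundary-layer depth.  Daily values near
mid-day (21Z over the Pacific coast) are averaged to calendar-month
means, then to multi-year monthly climatologies, and attached to
ecoregions as unweighted means over every overlapping grid cell.

w* follows the standard convective scaling

    w* = (g * z_i * Q0 / theta)^(1/3)

with g = 9.81 m/s^2, z_i the boundary-layer depth (m), Q0 the surface
kinematic heat flux (K m/s) and theta the CBL mean potential temperature
(K).  Stable conditions (Q0 < 0) carry no convection and clip to w* = 0.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .grids import PolygonLayer

logger = logging.getLogger(__name__)

G = 9.81  # m s^-2

MET_PARAMETERS = ("thermal_height", "thermal_velocity", "wind_speed")


def thermal_velocity(
    surface_heat_flux: float | np.ndarray,
    bl_height: float | np.ndarray,
    mean_potential_temperature: float | np.ndarray = 300.0,
) -> float | np.ndarray:
    """Convective velocity scale w* (m/s).

    Parameters are the surface kinematic heat flux (K m/s), the
    boundary-layer depth (m) and the CBL mean potential temperature (K).
    Negative flux (stable stratification) is clipped to zero with a
    warning.
    """
    flux = np.asarray(surface_heat_flux, dtype=float)
    zi = np.asarray(bl_height, dtype=float)
    theta = np.asarray(mean_potential_temperature, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("potential temperature must be positive (kelvin)")
    if np.any(zi < 0):
        raise ValueError("boundary-layer height must be non-negative")
    if np.any(flux < 0):
        warnings.warn("negative surface heat flux clipped to 0 (stable conditions)")
        flux = np.clip(flux, 0.0, None)
    wstar = (G * zi * flux / theta) ** (1 / 3)
    return float(wstar) if wstar.ndim == 0 else wstar


def bl_mean_wind(
    level_speeds: np.ndarray, level_heights: np.ndarray, bl_height: float
) -> float:
    """Wind speed averaged vertically over the boundary-layer depth.

    ``level_speeds`` (m/s) are point values at ``level_heights`` (m above
    ground, increasing).  The profile is integrated by the trapezoid rule
    over [0, bl_height] — constant below the lowest level and linearly
    interpolated between levels — and divided by the depth.
    """
    v = np.asarray(level_speeds, dtype=float)
    z = np.asarray(level_heights, dtype=float)
    if v.shape != z.shape or v.ndim != 1 or len(v) == 0:
        raise ValueError("level speeds and heights must be matching 1-D arrays")
    if np.any(np.diff(z) <= 0):
        raise ValueError("level heights must be strictly increasing")
    if bl_height <= 0:
        raise ValueError("boundary-layer height must be positive")
    if z[0] > bl_height:
        raise ValueError("no wind levels at or below the boundary-layer height")
    # clip profile at the BL top, extend constant below the first level
    zz = np.concatenate([[0.0], z[z < bl_height], [bl_height]])
    vv = np.concatenate([[v[0]], v[z < bl_height],
                         [float(np.interp(bl_height, z, v))]])
    return float(np.trapezoid(vv, zz) / bl_height)


def monthly_midday_mean(daily: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Average daily mid-day values into a per-month climatology.

    ``daily`` needs columns ``date`` (datetime-like) and ``value_col``;
    values are averaged within each (year, month), then the year means
    are averaged per calendar month, so years with unequal day coverage
    weigh equally.  NaNs are ignored; an all-NaN month propagates NaN.
    """
    df = daily.copy()
    dates = pd.to_datetime(df["date"])
    df["year"], df["month"] = dates.dt.year, dates.dt.month
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN months -> NaN
        per_ym = df.groupby(["year", "month"])[value_col].mean().reset_index()
        out = per_ym.groupby("month")[value_col].mean().reset_index()
    return out.rename(columns={value_col: "mean_value"})


def zonal_means(
    met_table: pd.DataFrame,
    cell_geometry: PolygonLayer,
    ecoregions: PolygonLayer,
) -> pd.DataFrame:
    """Ecoregion-level monthly means of each met parameter.

    A grid cell contributes to an ecoregion when the two geometries
    intersect with positive area; contributing cells enter an unweighted
    mean.  Ecoregions overlapping no cell are excluded with a warning
    (data-poor zones drop out of the analysis).

    Returns a long table (ecoregion, year, month, parameter, value).
    """
    membership: dict[int, list[int]] = {}
    for eco_id, eco_geom in ecoregions.geometries.items():
        cells = [
            cid
            for cid, geom in cell_geometry.geometries.items()
            if geom.intersects(eco_geom) and geom.intersection(eco_geom).area > 0
        ]
        if not cells:
            logger.warning("ecoregion %s overlaps no met cell; excluded", eco_id)
            continue
        membership[eco_id] = cells

    rows = []
    grouped = met_table.groupby(["year", "month", "parameter"])["value"]
    by_cell = met_table.set_index(["year", "month", "parameter", "cell_id"])["value"]
    for eco_id, cells in membership.items():
        for (year, month, param), _ in grouped:
            vals = [
                by_cell.get((year, month, param, cid)) for cid in cells
            ]
            vals = [v for v in vals if v is not None and not pd.isna(v)]
            if vals:
                rows.append((eco_id, year, month, param, float(np.mean(vals))))
    return pd.DataFrame(rows, columns=["ecoregion", "year", "month", "parameter", "value"])


def met_wide(zonal: pd.DataFrame) -> pd.DataFrame:
    """Pivot zonal means to one row per (ecoregion, year, month)."""
    wide = zonal.pivot_table(
        index=["ecoregion", "year", "month"], columns="parameter", values="value"
    ).reset_index()
    wide.columns.name = None
    return wide
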