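"""Use, availability, and ln(rf) selection ratios within monthly home ranges.

For each bird-month the home range (99% UD isopleth) frames the
comparison: *use* of a unit (habitat class or ecoregion) is the UD
probability mass over the unit's cells inside the home range,
renormalized over the home range; *availability* is the unit's share of
home-range cells (cells are equal-area).  The selection ratio is

    ln(rf) = ln(use / availability)

which is symmetric around proportional use: a unit used twice its
availability scores +ln 2 and one used at half its availability scores
-ln 2.  Positive values indicate selection, negative avoidance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import PolygonLayer, Raster
from .kernel import HomeRange, UtilizationDistribution

logger = logging.getLogger(__name__)

# The motivating analysis reclassifies a fine state landcover legend into
# 12 habitat types labeled A-L.
HABITAT_CLASS_NAMES = {
    1: "agriculture",
    2: "coastal_dune",
    3: "coastal_rock",
    4: "deciduous_forest",
    5: "evergreen_forest",
    6: "grassland",
    7: "modified_land",
    8: "savanna",
    9: "shrubland",
    10: "sparse_vegetation",
    11: "unsuitable",
    12: "wetland",
}

# Synthetic example of a fine-legend -> 12-class reclassification table
# (stand-in for a real crosswalk, which is survey-specific configuration).
EXAMPLE_LANDCOVER_MAPPING = {
    raw: (raw - 101) % 12 + 1 for raw in range(101, 149)
}


@dataclass
class SelectionRecord:
    """One bird-month x unit row of the selection analysis."""

    bird_id: str
    year: int
    month: int
    scale: str  # "habitat" | "ecoregion"
    unit: int
    use: float
    availability: float
    ln_rf: float  # NaN when use == 0 (undefined log-ratio; excluded from models)


def _unit_grid(raster: Raster, ud: UtilizationDistribution) -> np.ndarray:
    """Unit labels on the UD grid (nearest-neighbor; exact when co-gridded)."""
    template = Raster(np.zeros(ud.shape), ud.origin, ud.cell)
    return raster.resample_to(template).values


def habitat_use(
    ud: UtilizationDistribution, home_range: HomeRange, habitat_raster: Raster
) -> dict[int, float]:
    """UD probability of occurrence per unit within the home range.

    ``use_j = sum(UD over HR cells of class j) / sum(UD over HR cells)``.
    """
    units = _unit_grid(habitat_raster, ud)
    mask = home_range.mask
    total = ud.values[mask].sum()
    if total <= 0 or not mask.any():
        raise ValueError("home range does not overlap the raster / carries no mass")
    out: dict[int, float] = {}
    for u in np.unique(units[mask]):
        sel = mask & (units == u)
        out[int(u)] = float(ud.values[sel].sum() / total)
    return out


def habitat_use_from_fixes(
    points: np.ndarray, home_range: HomeRange, habitat_raster: Raster,
    ud: UtilizationDistribution,
) -> dict[int, float]:
    """Count-based use estimator: fix frequency per unit within the home range.

    The UD argument fixes the grid on which units are resolved.  This
    estimator avoids the attenuation that kernel smoothing induces at
    patch boundaries; the UD-mass estimator (:func:`habitat_use`) remains
    the default used for home-range delineation.
    """
    units = _unit_grid(habitat_raster, ud)
    x0, y0 = home_range.origin
    points = np.asarray(points, dtype=float)
    col = ((points[:, 0] - x0) // home_range.cell).astype(int)
    row = ((points[:, 1] - y0) // home_range.cell).astype(int)
    nrows, ncols = home_range.mask.shape
    ok = (row >= 0) & (row < nrows) & (col >= 0) & (col < ncols)
    row, col = row[ok], col[ok]
    inside = home_range.mask[row, col]
    row, col = row[inside], col[inside]
    if len(row) == 0:
        raise ValueError("no fixes fall inside the home range")
    labels = units[row, col]
    out: dict[int, float] = {}
    present = np.unique(units[home_range.mask])
    for u in present:
        out[int(u)] = float((labels == u).sum() / len(labels))
    return out


def availability(home_range: HomeRange, categorical_raster: Raster,
                 ud: UtilizationDistribution) -> dict[int, float]:
    """Unit share of home-range cells (equal-area cells => area share)."""
    units = _unit_grid(categorical_raster, ud)
    mask = home_range.mask
    n = mask.sum()
    if n == 0:
        raise ValueError("empty home range")
    out: dict[int, float] = {}
    for u in np.unique(units[mask]):
        out[int(u)] = float((units[mask] == u).sum() / n)
    return out


def selection_ratio(
    use: dict[int, float],
    avail: dict[int, float],
    use_floor: float = 0.0,
) -> dict[int, float]:
    """ln(use/availability) per unit.

    Units with zero availability are excluded (they cannot be compared);
    zero use with positive availability yields NaN — the log-ratio is
    undefined — unless a positive ``use_floor`` is supplied.
    """
    if not avail or all(a == 0 for a in avail.values()):
        raise ValueError("all availabilities are zero; invalid panel")
    out: dict[int, float] = {}
    n_undefined = 0
    for u, a in avail.items():
        if a <= 0:
            continue
        p = use.get(u, 0.0)
        if p <= 0:
            p = use_floor
        if p <= 0:
            out[u] = float("nan")
            n_undefined += 1
        else:
            out[u] = float(np.log(p / a))
    if n_undefined:
        logger.info("%d unit(s) with zero use flagged as undefined ln(rf)", n_undefined)
    return out


def ecoregion_panel(
    ud: UtilizationDistribution,
    home_range: HomeRange,
    ecoregion_layer: PolygonLayer | Raster,
    bird_id: str = "",
    year: int = 0,
    month: int = 0,
) -> list[SelectionRecord]:
    """Selection records at ecoregion scale for one bird-month."""
    if isinstance(ecoregion_layer, PolygonLayer):
        template = Raster(np.zeros(ud.shape), ud.origin, ud.cell)
        raster = ecoregion_layer.rasterize(template)
    else:
        raster = ecoregion_layer
    use = habitat_use(ud, home_range, raster)
    avail = availability(home_range, raster, ud)
    lnrf = selection_ratio(use, avail)
    return [
        SelectionRecord(bird_id, year, month, "ecoregion", u,
                        use.get(u, 0.0), avail[u], lnrf[u])
        for u in sorted(avail)
    ]


def habitat_panel(
    ud: UtilizationDistribution,
    home_range: HomeRange,
    habitat_raster: Raster,
    bird_id: str = "",
    year: int = 0,
    month: int = 0,
    points: np.ndarray | None = None,
    use_estimator: str = "ud",
) -> list[SelectionRecord]:
    """Selection records at habitat scale for one bird-month."""
    if use_estimator == "ud":
        use = habitat_use(ud, home_range, habitat_raster)
    elif use_estimator == "counts":
        if points is None:
            raise ValueError("count-based use estimator needs the fix coordinates")
        use = habitat_use_from_fixes(points, home_range, habitat_raster, ud)
    else:
        raise ValueError(f"unknown use estimator {use_estimator!r}")
    avail = availability(home_range, habitat_raster, ud)
    lnrf = selection_ratio(use, avail)
    return [
        SelectionRecord(bird_id, year, month, "habitat", u,
                        use.get(u, 0.0), avail[u], lnrf[u])
        for u in sorted(avail)
    ]


def records_to_frame(records: list[SelectionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "bird_id": r.bird_id, "year": r.year, "month": r.month,
                "scale": r.scale, "unit": r.unit, "use": r.use,
                "availability": r.availability, "ln_rf": r.ln_rf,
            }
            for r in records
        ]
    )


def reclassify_landcover(raw_raster: Raster, mapping: dict[int, int]) -> Raster:
    """Collapse a fine landcover legend into habitat classes.

    Every raw code present in the raster must appear in the mapping;
    unmapped codes raise with the offending codes listed.
    """
    values = raw_raster.values
    if not np.issubdtype(values.dtype, np.integer):
        if not np.allclose(values, np.round(values)):
            raise ValueError("landcover raster is not categorical (non-integer codes)")
        values = values.astype(int)
    present = np.unique(values)
    unmapped = [int(c) for c in present if int(c) not in mapping]
    if unmapped:
        raise ValueError(f"landcover codes without a mapping entry: {unmapped}")
    lut_max = int(present.max())
    lut = np.zeros(lut_max + 1, dtype=int)
    for code in present:
        lut[int(code)] = mapping[int(code)]
    return Raster(lut[values], raw_raster.origin, raw_raster.cell,
                  nodata=raw_raster.nodata)
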