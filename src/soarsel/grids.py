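"""Planar raster container and plain-text spatial I/O.

All spatial data in this package live in a projected planar coordinate
system in meters (synthetic scenarios are generated directly in planar
coordinates; real telemetry should be projected to a metric equal-area
CRS before ingest).  Rasters are row-major numpy arrays anchored at a
lower-left origin with square cells; they serialize to ESRI ASCII grids
(.asc), and polygon layers serialize to GeoJSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import mapping, shape


@dataclass
class Raster:
    """A single-band raster on a regular square grid.

    Parameters
    ----------
    values
        2-D array indexed ``[row, col]``; row 0 is the *southernmost* row
        (y increases with row index), col 0 the westernmost column.
    origin
        ``(x0, y0)`` of the lower-left corner of cell ``[0, 0]`` in meters.
    cell
        Cell edge length in meters.
    """

    values: np.ndarray
    origin: tuple[float, float]
    cell: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster extent."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.ncols * self.cell, y0 + self.nrows * self.cell)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of x (per column) and y (per row) cell-center coordinates."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.ncols) + 0.5) * self.cell
        ys = y0 + (np.arange(self.nrows) + 0.5) * self.cell
        return xs, ys

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing planar points (clipped to grid)."""
        x0, y0 = self.origin
        col = np.clip(((np.asarray(x) - x0) // self.cell).astype(int), 0, self.ncols - 1)
        row = np.clip(((np.asarray(y) - y0) // self.cell).astype(int), 0, self.nrows - 1)
        return row, col

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Nearest-neighbor sample of raster values at planar points."""
        row, col = self.index_of(x, y)
        return self.values[row, col]

    def resample_to(self, template: "Raster") -> "Raster":
        """Nearest-neighbor resample onto another raster's grid.

        Categorical-safe: each target cell takes the value of the source
        cell containing its center.
        """
        xs, ys = template.cell_centers()
        xx, yy = np.meshgrid(xs, ys)
        vals = self.sample(xx.ravel(), yy.ravel()).reshape(template.shape)
        return Raster(vals, template.origin, template.cell, nodata=self.nodata)

    # -- ESRI ASCII grid I/O ------------------------------------------------

    def write_ascii(self, path: str | Path) -> None:
        """Write as an ESRI ASCII grid (text; first data row is northernmost)."""
        x0, y0 = self.origin
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {x0}\n"
            f"yllcorner {y0}\n"
            f"cellsize {self.cell}\n"
            f"NODATA_value {self.nodata}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            # ESRI convention stores the top (north) row first
            np.savetxt(fh, self.values[::-1], fmt="%.10g")

    @classmethod
    def read_ascii(cls, path: str | Path) -> "Raster":
        with open(path) as fh:
            hdr = {}
            for _ in range(6):
                key, val = fh.readline().split()
                hdr[key.lower()] = float(val)
            values = np.loadtxt(fh)
        values = np.atleast_2d(values)[::-1].copy()
        return cls(
            values,
            (hdr["xllcorner"], hdr["yllcorner"]),
            hdr["cellsize"],
            nodata=hdr.get("nodata_value", -9999.0),
        )


@dataclass
class PolygonLayer:
    """Labeled polygons (e.g. ecoregions or met-grid cells) with GeoJSON I/O."""

    geometries: dict = field(default_factory=dict)  # label -> shapely geometry

    def write_geojson(self, path: str | Path, id_field: str = "id") -> None:
        features = [
            {
                "type": "Feature",
                "properties": {id_field: label},
                "geometry": mapping(geom),
            }
            for label, geom in self.geometries.items()
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)

    @classmethod
    def read_geojson(cls, path: str | Path, id_field: str = "id") -> "PolygonLayer":
        with open(path) as fh:
            fc = json.load(fh)
        geoms = {
            feat["properties"][id_field]: shape(feat["geometry"])
            for feat in fc["features"]
        }
        return cls(geoms)

    def rasterize(self, template: Raster) -> Raster:
        """Burn polygon labels onto a template grid (cell-center-in-polygon).

        Labels must be convertible to int; cells outside every polygon get
        the template nodata value.
        """
        from shapely import contains_xy

        xs, ys = template.cell_centers()
        xx, yy = np.meshgrid(xs, ys)
        out = np.full(template.shape, int(template.nodata), dtype=int)
        for label, geom in self.geometries.items():
            inside = contains_xy(geom, xx, yy)
            out[inside] = int(label)
        return Raster(out, template.origin, template.cell, nodata=template.nodata)
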