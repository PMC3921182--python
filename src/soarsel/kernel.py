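"""Fixed-kernel utilization distributions and home-range isopleths.

The monthly utilization distribution (UD) is a bivariate Gaussian kernel
density estimate evaluated on a regular grid (100 m cells by default) and
normalized to unit mass.  The home range is the 99% volume isopleth: the
smallest set of highest-density cells whose cumulative mass reaches the
level.  Bandwidth starts from the bivariate-normal reference rule

    h_ref = sqrt((s_x^2 + s_y^2) / 2) * n^(-1/6)

and the working (ad-hoc) bandwidth is the smallest scanned multiple of
h_ref whose 99% isopleth remains a single connected polygon, which keeps
the outward home-range boundary from being over-smoothed while avoiding
the fragmentation that small bandwidths produce around clustered roost
and perch locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


class DegenerateSpreadError(ValueError):
    """All points identical; no bandwidth is defined."""


class ResolutionError(ValueError):
    """Requested grid too large; advise a coarser cell size."""


class NoContiguousSolutionError(RuntimeError):
    """No scanned bandwidth multiplier produced a single connected isopleth."""


@dataclass
class UtilizationDistribution:
    """Probability-mass grid with bandwidth provenance.

    ``values[row, col]`` is the probability mass of the cell; row 0 is the
    southernmost row.  ``origin`` is the lower-left corner of cell (0, 0).
    """

    values: np.ndarray
    origin: tuple[float, float]
    cell: float
    h: float
    h_ref: float | None = None

    @property
    def multiplier(self) -> float | None:
        return None if self.h_ref is None else self.h / self.h_ref

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.values.shape[1]) + 0.5) * self.cell
        ys = y0 + (np.arange(self.values.shape[0]) + 0.5) * self.cell
        return xs, ys


@dataclass
class HomeRange:
    """Volume-isopleth cell set of a UD."""

    mask: np.ndarray  # boolean grid, True inside the isopleth
    mass: float
    level: float
    n_components: int
    origin: tuple[float, float]
    cell: float
    _polygons: list | None = field(default=None, repr=False)

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())

    @property
    def area_m2(self) -> float:
        return self.n_cells * self.cell**2

    def polygons(self):
        """Boundary polygons traced along cell edges (shapely geometries)."""
        if self._polygons is None:
            import shapely
            from shapely.geometry import box

            rows, cols = np.nonzero(self.mask)
            x0, y0 = self.origin
            boxes = [
                box(x0 + c * self.cell, y0 + r * self.cell,
                    x0 + (c + 1) * self.cell, y0 + (r + 1) * self.cell)
                for r, c in zip(rows, cols)
            ]
            merged = shapely.unary_union(boxes)
            self._polygons = (
                list(merged.geoms) if merged.geom_type == "MultiPolygon" else [merged]
            )
        return self._polygons


def reference_bandwidth(points: np.ndarray) -> float:
    """Bivariate-normal reference bandwidth h_ref (meters)."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = len(points)
    if n < 5:
        raise ValueError("need at least 5 points for a reference bandwidth")
    sx = points[:, 0].std(ddof=1)
    sy = points[:, 1].std(ddof=1)
    if sx == 0 and sy == 0:
        raise DegenerateSpreadError("all points identical; bandwidth undefined")
    return float(np.sqrt((sx**2 + sy**2) / 2) * n ** (-1 / 6))


def kernel_ud(
    points: np.ndarray,
    h: float,
    cell: float = 100.0,
    pad: float | None = None,
    h_ref: float | None = None,
    max_cells: int = 25_000_000,
) -> UtilizationDistribution:
    """Gaussian kernel UD on a regular grid covering the points.

    Cell mass is the kernel sum evaluated at the cell center,
    renormalized to total 1 (truncation outside the padded grid is below
    1e-3 of mass for ``pad >= 3 h``).  The grid origin is snapped to a
    multiple of ``cell`` so UDs and co-gridded rasters align exactly.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or len(points) == 0:
        raise ValueError("points must be a non-empty (n, 2) array")
    if h <= 0 or cell <= 0:
        raise ValueError("bandwidth and cell size must be positive")
    pad = 3 * h if pad is None else max(pad, 3 * h)

    x_lo = np.floor((points[:, 0].min() - pad) / cell) * cell
    y_lo = np.floor((points[:, 1].min() - pad) / cell) * cell
    ncols = int(np.ceil((points[:, 0].max() + pad - x_lo) / cell))
    nrows = int(np.ceil((points[:, 1].max() + pad - y_lo) / cell))
    if nrows * ncols > max_cells:
        raise ResolutionError(
            f"UD grid would need {nrows}x{ncols} cells (> {max_cells}); "
            "use a coarser cell size"
        )

    xs = x_lo + (np.arange(ncols) + 0.5) * cell
    ys = y_lo + (np.arange(nrows) + 0.5) * cell
    # separable Gaussian: values = Gy @ Gx.T
    gx = np.exp(-((xs[:, None] - points[None, :, 0]) ** 2) / (2 * h**2))
    gy = np.exp(-((ys[:, None] - points[None, :, 1]) ** 2) / (2 * h**2))
    values = gy @ gx.T
    total = values.sum()
    if total <= 0:
        raise ValueError("kernel mass underflowed; bandwidth too small for this grid")
    values /= total
    return UtilizationDistribution(values, (x_lo, y_lo), cell, h=h, h_ref=h_ref)


def volume_isopleth(ud: UtilizationDistribution, level: float = 0.99) -> HomeRange:
    """Smallest highest-density cell set holding ``level`` of the UD mass."""
    if not 0 < level < 1:
        raise ValueError("isopleth level must be in (0, 1)")
    flat = ud.values.ravel()
    order = np.argsort(flat, kind="stable")[::-1]
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, level) + 1)
    k = min(k, len(flat))
    mask = np.zeros(flat.shape, dtype=bool)
    mask[order[:k]] = True
    mask = mask.reshape(ud.values.shape)
    _, n_comp = ndimage.label(mask, structure=EIGHT_CONNECTED)
    return HomeRange(
        mask=mask,
        mass=float(csum[k - 1]),
        level=level,
        n_components=int(n_comp),
        origin=ud.origin,
        cell=ud.cell,
    )


def select_adhoc_bandwidth(
    points: np.ndarray,
    level: float = 0.99,
    multipliers: np.ndarray | None = None,
    cell: float = 100.0,
    escalate_to: float = 2.0,
    max_cells: int = 25_000_000,
) -> tuple[float, UtilizationDistribution, HomeRange]:
    """Smallest h_ref multiplier whose isopleth is a single connected region.

    Scans the multiplier grid (default 0.1 .. 1.0 in steps of 0.1) in
    increasing order and returns the first — hence smallest — multiplier
    whose ``level`` isopleth has one 8-connected component, together with
    the corresponding UD and home range.  If no scanned multiplier is
    contiguous the scan escalates above 1.0 in 0.1 steps up to
    ``escalate_to`` before failing.
    """
    h_ref = reference_bandwidth(points)
    if multipliers is None:
        multipliers = np.round(np.arange(0.1, 1.01, 0.1), 10)
    scan = np.sort(np.asarray(multipliers, dtype=float))
    if escalate_to > scan[-1]:
        extra = np.round(np.arange(scan[-1] + 0.1, escalate_to + 1e-9, 0.1), 10)
        scan = np.concatenate([scan, extra])
    pad = 3 * h_ref * scan[-1]  # shared grid extent across the scan
    for m in scan:
        ud = kernel_ud(points, m * h_ref, cell=cell, pad=pad, h_ref=h_ref,
                       max_cells=max_cells)
        hr = volume_isopleth(ud, level)
        if hr.n_components == 1:
            return float(m), ud, hr
    raise NoContiguousSolutionError(
        f"no multiplier up to {scan[-1]} gave a contiguous {level:.0%} isopleth"
    )
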