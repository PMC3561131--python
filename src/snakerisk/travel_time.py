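"""Slope-penalized cost-surface travel-time model.

Per-cell traversal time is

    t = (cell_size / cos(alpha)) / v + beta_r * alpha^2

with v the cell speed (road class or land class) in m/s, alpha the slope
in degrees, and beta_r a slope penalty coefficient (seconds per squared
degree) that differs between road and off-road cells. Accumulated time
from a source set is the 8-connected shortest path where a move between
adjacent cells costs the mean of the two endpoint cell times, scaled by
sqrt(2) on diagonals. Station and facility accumulations are summed to a
total ambulance round-trip raster; the double counting of off-road legs
is intentional (those stretches are walked both ways).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .raster import RasterGrid, require_aligned

__all__ = [
    "SpeedModel",
    "CostSurface",
    "AccumulatedTime",
    "TIME_CATEGORIES",
    "rasterize_roads",
    "build_speed_raster",
    "slope_raster",
    "cell_cost",
    "build_cost_surface",
    "accumulate_time",
    "total_time",
    "extract_mean_time",
    "categorize_time",
    "population_time_summary",
]

TIME_CATEGORIES = ("<2 h", "2–3 h", ">3 h")  # en dash, as printed
UNREACHABLE = "unreachable"

_ROAD_CODE = {"none": 0, "primary": 1, "secondary_urban": 2, "tertiary": 3}
_LAND_CODE = {"open": 0, "forest": 1, "water": 2}


@dataclass
class SpeedModel:
    """Assumed speeds (km/h) and slope penalties (s per squared degree)."""

    road_speeds: dict = field(
        default_factory=lambda: {"primary": 60.0, "secondary_urban": 40.0,
                                 "tertiary": 20.0}
    )
    offroad_open: float = 6.0
    offroad_forest: float = 3.0  # 50% slower than open
    water: float = 1.2  # one fifth of open terrain
    slope_beta_road: float = 0.001
    slope_beta_offroad: float = 0.02

    def __post_init__(self) -> None:
        speeds = [*self.road_speeds.values(), self.offroad_open,
                  self.offroad_forest, self.water]
        if any(s <= 0 for s in speeds):
            raise ValueError("all speeds must be positive")


@dataclass
class CostSurface:
    """Per-cell traversal time in seconds plus provenance."""

    time_s: RasterGrid
    slope_deg: RasterGrid
    is_road: np.ndarray
    model: SpeedModel


@dataclass
class AccumulatedTime:
    """Minimum time (seconds) from the nearest source; inf = unreachable."""

    time_s: RasterGrid
    label: str


def rasterize_roads(segments, grid: RasterGrid) -> RasterGrid:
    """Burn classed road segments into a raster; fastest class wins overlaps.

    ``segments``: iterable of ((x0, y0), (x1, y1), class_name).
    """
    road = np.zeros(grid.shape, dtype=int)
    for p0, p1, cls in segments:
        if cls not in _ROAD_CODE or cls == "none":
            raise ValueError(f"unknown road class: {cls!r}")
        code = _ROAD_CODE[cls]
        (x0, y0), (x1, y1) = p0, p1
        length = math.hypot(x1 - x0, y1 - y0)
        n_steps = max(int(length / (grid.cell_size / 4.0)), 1)
        t = np.linspace(0.0, 1.0, n_steps + 1)
        r, c = grid.index_of(x0 + t * (x1 - x0), y0 + t * (y1 - y0))
        ok = (r >= 0) & (r < grid.n_rows) & (c >= 0) & (c < grid.n_cols)
        for rr, cc in zip(r[ok], c[ok]):
            if road[rr, cc] == 0 or code < road[rr, cc]:
                road[rr, cc] = code
    return grid.like(road, nodata=-1)


def build_speed_raster(
    road_class: RasterGrid, land_class: RasterGrid, model: SpeedModel | None = None
) -> tuple[RasterGrid, np.ndarray]:
    """Speed (km/h) per cell. Road cells keep road speed regardless of the
    land class beneath (roads crossing water or forest are still roads).

    Returns (speed raster, boolean is_road array).
    """
    model = model or SpeedModel()
    require_aligned(road_class, land_class)
    road = road_class.values.astype(int)
    land = land_class.values.astype(int)
    speed = np.empty(road.shape, dtype=float)
    speed[land == _LAND_CODE["open"]] = model.offroad_open
    speed[land == _LAND_CODE["forest"]] = model.offroad_forest
    speed[land == _LAND_CODE["water"]] = model.water
    for name, code in _ROAD_CODE.items():
        if code:
            speed[road == code] = model.road_speeds[name]
    return road_class.like(speed, nodata=-1.0), road > 0


def slope_raster(elevation: RasterGrid, cell_size: float | None = None) -> RasterGrid:
    """Gradient-magnitude slope in degrees, central differences.

    One-sided differences at edges; isotropic (direction of travel is not
    considered). Values lie in [0, 90).
    """
    cs = cell_size if cell_size is not None else elevation.cell_size
    z = np.asarray(elevation.values, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("elevation must be finite everywhere")
    gy, gx = np.gradient(z, cs)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    return elevation.like(slope, nodata=-1.0)


def cell_cost(speed_kmh, alpha_deg, is_road, cell_size: float = 30.0,
              model: SpeedModel | None = None):
    """Seconds to traverse one cell: hypotenuse distance over speed plus
    the squared-slope penalty."""
    model = model or SpeedModel()
    speed_kmh = np.asarray(speed_kmh, dtype=float)
    alpha = np.asarray(alpha_deg, dtype=float)
    if np.any(speed_kmh <= 0):
        raise ValueError("speed must be positive")
    if np.any((alpha < 0) | (alpha >= 90)):
        raise ValueError("slope must lie in [0, 90) degrees")
    v_ms = speed_kmh / 3.6
    beta = np.where(np.asarray(is_road, bool),
                    model.slope_beta_road, model.slope_beta_offroad)
    t = (cell_size / np.cos(np.radians(alpha))) / v_ms + beta * alpha**2
    return float(t) if t.ndim == 0 else t


def build_cost_surface(
    road_class: RasterGrid,
    land_class: RasterGrid,
    elevation: RasterGrid,
    model: SpeedModel | None = None,
) -> CostSurface:
    model = model or SpeedModel()
    require_aligned(road_class, land_class, elevation)
    speed, is_road = build_speed_raster(road_class, land_class, model)
    slope = slope_raster(elevation)
    t = cell_cost(speed.values, slope.values, is_road,
                  cell_size=elevation.cell_size, model=model)
    return CostSurface(
        time_s=elevation.like(t, nodata=-1.0),
        slope_deg=slope, is_road=is_road, model=model,
    )


def _grid_graph(cost: np.ndarray) -> sp.csr_matrix:
    """8-connected move graph; edge weight = mean endpoint cost x step factor."""
    nr, nc = cost.shape
    idx = np.arange(nr * nc).reshape(nr, nc)
    rows, cols, data = [], [], []
    # offsets covering each undirected edge once
    for dr, dc, k in ((0, 1, 1.0), (1, 0, 1.0), (1, 1, math.sqrt(2)),
                      (1, -1, math.sqrt(2))):
        r0 = slice(0, nr - dr)
        r1 = slice(dr, nr)
        if dc >= 0:
            c0, c1 = slice(0, nc - dc), slice(dc, nc)
        else:
            c0, c1 = slice(-dc, nc), slice(0, nc + dc)
        a = idx[r0, c0].ravel()
        b = idx[r1, c1].ravel()
        w = 0.5 * (cost.ravel()[a] + cost.ravel()[b]) * k
        ok = np.isfinite(w)
        rows.append(a[ok])
        cols.append(b[ok])
        data.append(w[ok])
    return sp.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nr * nc, nr * nc),
    )


def accumulate_time(cost: CostSurface, sources, label: str = "",
                    as_cells: bool = False) -> AccumulatedTime:
    """Minimum cumulative travel time from the nearest source.

    ``sources``: (x, y) planar points snapped to their containing cells,
    or (row, col) index pairs when ``as_cells`` is true. Source cells get
    time 0.
    """
    grid = cost.time_s
    cells = []
    for src in sources:
        if as_cells:
            r, c = int(src[0]), int(src[1])
            if not (0 <= r < grid.n_rows and 0 <= c < grid.n_cols):
                raise ValueError(f"source cell {src} outside grid")
        else:
            x, y = src
            if not grid.contains(x, y):
                raise ValueError(f"source ({x}, {y}) outside grid extent")
            r, c = (int(v) for v in grid.index_of(x, y))
        cells.append((r, c))
    if not cells:
        raise ValueError("no sources on the grid")
    graph = _grid_graph(np.asarray(grid.values, dtype=float))
    src_idx = [r * grid.n_cols + c for r, c in cells]
    dist = dijkstra(graph, directed=False, indices=src_idx, min_only=True)
    return AccumulatedTime(
        time_s=grid.like(dist.reshape(grid.shape), nodata=-1.0), label=label
    )


def total_time(from_stations: AccumulatedTime,
               from_facilities: AccumulatedTime) -> RasterGrid:
    """Cellwise sum of the two accumulations, in hours; inf stays inf."""
    a, b = from_stations.time_s, from_facilities.time_s
    require_aligned(a, b)
    total = (np.asarray(a.values) + np.asarray(b.values)) / 3600.0
    return a.like(total, nodata=-1.0)


def extract_mean_time(total_hours: RasterGrid, unit_masks: dict) -> pd.DataFrame:
    """Mean total time over each unit's masked cells.

    ``unit_masks``: {unit_id: boolean array of the grid shape}. Cells with
    non-finite time are excluded; an all-excluded mask reports the unit as
    unreachable (NaN mean).
    """
    rows = []
    vals = np.asarray(total_hours.values, dtype=float)
    for unit_id, mask in unit_masks.items():
        mask = np.asarray(mask, bool)
        if mask.shape != vals.shape:
            raise ValueError("mask shape does not match raster")
        if not mask.any():
            raise ValueError(f"unit {unit_id}: empty mask")
        sel = vals[mask]
        sel = sel[np.isfinite(sel)]
        rows.append(
            {"unit_id": unit_id,
             "mean_hours": float(sel.mean()) if len(sel) else float("nan"),
             "n_cells": int(mask.sum())}
        )
    return pd.DataFrame(rows)


def unit_buffer_masks(units, grid: RasterGrid, radius: float = 2000.0) -> dict:
    """Boolean per-unit masks: cells whose centers lie within radius."""
    xs, ys = grid.cell_centers()
    tree = cKDTree(np.column_stack([xs.ravel(), ys.ravel()]))
    masks = {}
    for cu in units:
        m = np.zeros(grid.shape, dtype=bool)
        idx = tree.query_ball_point([cu.x, cu.y], r=radius)
        m.ravel()[idx] = True
        masks[cu.unit_id] = m
    return masks


def time_category_labels(bounds=(2.0, 3.0)) -> tuple[str, str, str]:
    lo, hi = bounds
    if (lo, hi) == (2.0, 3.0):
        return TIME_CATEGORIES
    return (f"<{lo:g} h", f"{lo:g}–{hi:g} h", f">{hi:g} h")


def categorize_time(hours, bounds=(2.0, 3.0)):
    """Map hours to categories with half-open bounds: [0,lo) / [lo,hi) /
    [hi,inf). Defaults reproduce the printed <2 h / 2–3 h / >3 h split."""
    lo, hi = bounds
    if not lo < hi:
        raise ValueError("category bounds must be increasing")
    labels = time_category_labels(bounds)
    arr = np.asarray(hours, dtype=float)
    if np.any(arr < 0):
        raise ValueError("travel time must be nonnegative")
    flat = np.atleast_1d(arr)
    out = np.empty(flat.shape, dtype=object)
    out[flat < lo] = labels[0]
    out[(flat >= lo) & (flat < hi)] = labels[1]
    out[flat >= hi] = labels[2]
    out[~np.isfinite(flat)] = UNREACHABLE
    return out.item() if np.isscalar(hours) or arr.ndim == 0 else out


def population_time_summary(categories, populations, bounds=(2.0, 3.0)) -> dict:
    """Population-weighted fractions per travel-time category.

    Includes an ``unreachable`` bucket; fractions sum to 1.
    """
    categories = np.atleast_1d(np.asarray(categories, dtype=object))
    pop = np.asarray(populations, dtype=float)
    total = pop.sum()
    if total <= 0:
        raise ValueError("total population is zero")
    out = {}
    for cat in (*time_category_labels(bounds), UNREACHABLE):
        out[cat] = float(pop[categories == cat].sum() / total)
    return out
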