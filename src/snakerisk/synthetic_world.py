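"""Synthetic study-region generator.

Builds a rectangular district lattice with queen adjacency, per-district
covariates and populations, spatially correlated case counts from the
Poisson log-linear model, individual case records (with injected exact
duplicates to exercise the cleaning rules), and a raster world (elevation,
land class, roads, biotic units) with facility, ambulance-station, EBAIS
and census-centroid point sets. Everything is deterministic under
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import minimum_spanning_tree
from shapely.geometry import Polygon

from .adjacency import AdjacencyGraph, lattice_queen_adjacency
from .disease_mapping import COVARIATES, DistrictTable, build_design
from .raster import RasterGrid

__all__ = [
    "WorldConfig",
    "RasterWorld",
    "CensusUnit",
    "LAND_CLASSES",
    "ROAD_CLASSES",
    "BIOTIC_UNITS",
    "generate_district_lattice",
    "sample_covariates",
    "sample_car_field",
    "generation_offsets",
    "sample_case_counts",
    "sample_yearly_counts",
    "sample_case_records",
    "generate_raster_world",
]

LAND_CLASSES = {0: "open", 1: "forest", 2: "water"}
ROAD_CLASSES = {0: "none", 1: "primary", 2: "secondary_urban", 3: "tertiary"}
BIOTIC_UNITS = {0: "Moist", 1: "Wet", 2: "Pluvial", 3: "Dry", 4: "Other"}

# marginal case-record frequencies echoing the descriptive results the
# generator is meant to resemble
_MALE_FRACTION = 0.72
# printed band percentages sum to 102%; normalized here
_AGE_BAND_PROBS = tuple(p / 1.02 for p in (0.27, 0.32, 0.21, 0.22))
_AGE_BANDS = ((0, 14), (15, 29), (30, 44), (45, 85))


@dataclass
class WorldConfig:
    lattice_rows: int = 10
    lattice_cols: int = 10
    raster_rows: int = 120
    raster_cols: int = 120
    cell_size: float = 30.0
    n_years: int = 18
    start_year: int = 1990
    beta_true: tuple = (-0.94, 0.43, -0.51, 0.37, -0.42)  # order = COVARIATES
    beta0_true: float = 0.0
    sigma_u: float = 0.3
    base_rate_per_100k: float = 15.0
    population_range: tuple = (500, 20000)
    duplicate_rate: float = 0.02
    n_facilities: int = 3
    n_stations: int = 4
    n_ebais: int = 6
    n_towns: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lattice_rows", "lattice_cols", "raster_rows", "raster_cols"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if not 0 <= self.duplicate_rate <= 1:
            raise ValueError("duplicate_rate must be in [0, 1]")
        if len(self.beta_true) != len(COVARIATES):
            raise ValueError(f"beta_true must have {len(COVARIATES)} entries")
        lo, hi = self.population_range
        if lo <= 0 or hi < lo:
            raise ValueError("population_range must satisfy 0 < min <= max")

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) of the world in meters."""
        return (self.raster_cols * self.cell_size, self.raster_rows * self.cell_size)


@dataclass
class CensusUnit:
    unit_id: int
    x: float
    y: float
    population: float
    urban: bool
    district_id: int


@dataclass
class RasterWorld:
    elevation: RasterGrid
    land_class: RasterGrid  # codes per LAND_CLASSES
    road_class: RasterGrid  # codes per ROAD_CLASSES
    biotic: RasterGrid  # codes per BIOTIC_UNITS
    facilities: list = field(default_factory=list)  # [(x, y), ...]
    stations: list = field(default_factory=list)
    ebais: list = field(default_factory=list)
    census_units: list = field(default_factory=list)  # [CensusUnit, ...]
    road_segments: list = field(default_factory=list)  # [((x0,y0),(x1,y1), class), ...]

    def __post_init__(self) -> None:
        from .raster import require_aligned

        require_aligned(self.elevation, self.land_class, self.road_class, self.biotic)
        for pts in (self.facilities, self.stations, self.ebais):
            for x, y in pts:
                if not self.elevation.contains(x, y):
                    raise ValueError(f"point ({x}, {y}) outside grid extent")
        for cu in self.census_units:
            if not self.elevation.contains(cu.x, cu.y):
                raise ValueError(f"census unit {cu.unit_id} outside grid extent")


def generate_district_lattice(
    config: WorldConfig,
) -> tuple[pd.DataFrame, AdjacencyGraph]:
    """Rectangular districts tiling the world extent, with queen adjacency."""
    rows, cols = config.lattice_rows, config.lattice_cols
    if rows * cols < 2:
        raise ValueError("a 1x1 lattice has no neighbors; CAR undefined")
    width, height = config.extent
    dx, dy = width / cols, height / rows
    records, polys = [], []
    for r in range(rows):
        for c in range(cols):
            x0, x1 = c * dx, (c + 1) * dx
            # row 0 is northernmost, matching raster convention
            y1, y0 = height - r * dy, height - (r + 1) * dy
            polys.append(Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)]))
            records.append(
                {"district_id": r * cols + c, "row": r, "col": c,
                 "cx": (x0 + x1) / 2, "cy": (y0 + y1) / 2}
            )
    df = pd.DataFrame(records)
    df["geometry"] = polys
    return df, lattice_queen_adjacency(rows, cols)


def _smooth_lattice_field(rows, cols, rng, n_bumps=6, noise=0.1):
    """Smooth positive field on a lattice: seeded Gaussian bumps + noise."""
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    fld = np.zeros((rows, cols))
    scale = max(rows, cols)
    for _ in range(n_bumps):
        r0, c0 = rng.uniform(0, rows), rng.uniform(0, cols)
        amp = rng.uniform(0.3, 1.0)
        width = rng.uniform(0.15, 0.45) * scale
        fld += amp * np.exp(-(((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * width**2)))
    fld += noise * rng.standard_normal((rows, cols))
    return fld


def sample_covariates(districts: pd.DataFrame, config: WorldConfig) -> pd.DataFrame:
    """Per-district covariates and populations.

    Elevation is a spatially smooth field; precipitation declines with
    elevation (humid lowlands); dry months discretize inverse
    precipitation; forest/urban fractions are Beta draws.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    rows, cols = config.lattice_rows, config.lattice_cols
    n = len(districts)

    # smooth enough for positive spatial autocorrelation, rough enough to
    # stay identifiable next to the CAR field
    elev_field = _smooth_lattice_field(rows, cols, rng, noise=0.45)
    elev = elev_field[districts["row"].to_numpy(), districts["col"].to_numpy()]
    lo, hi = elev.min(), elev.max()
    elevation = 2000.0 * (elev - lo) / (hi - lo) if hi > lo else np.full(n, 500.0)

    precip = 4200.0 - 0.9 * elevation + rng.normal(0, 500.0, n)
    precip = np.clip(precip, 500.0, None)
    p01 = (precip - precip.min()) / max(precip.max() - precip.min(), 1e-9)
    dry = np.round(8.0 * (1.0 - p01) + rng.normal(0, 1.2, n)).clip(0, 10)

    # fraction covariates: spatially structured (like real land use), with
    # wide Beta marginals so the [0,1]-scale coefficients stay identified
    from scipy.stats import beta as beta_dist, rankdata

    rr = districts["row"].to_numpy()
    cc = districts["col"].to_numpy()
    f_field = _smooth_lattice_field(rows, cols, rng, noise=0.35)[rr, cc]
    u_field = _smooth_lattice_field(rows, cols, rng, noise=0.35)[rr, cc]
    forest = beta_dist.ppf(rankdata(f_field) / (n + 1), 0.9, 0.9)
    urban = beta_dist.ppf(rankdata(u_field) / (n + 1), 0.7, 1.4)

    pop_lo, pop_hi = config.population_range
    raw = rng.lognormal(mean=0.0, sigma=0.7, size=n) * (1.0 + 2.0 * urban)
    pop = pop_lo + (pop_hi - pop_lo) * (raw - raw.min()) / max(raw.max() - raw.min(), 1e-9)
    population = np.clip(np.round(pop), pop_lo, pop_hi).astype(int)

    out = districts[["district_id", "row", "col"]].copy()
    out["population"] = population
    out["urban_frac"] = urban
    out["forest_frac"] = forest
    out["elevation_m"] = elevation
    out["precipitation_mm_yr"] = precip
    out["dry_months"] = dry
    return out


def sample_car_field(graph: AdjacencyGraph, sigma_u: float, seed) -> np.ndarray:
    """Exact draw from the intrinsic Besag CAR field, centered.

    The Besag precision Q = D - W is eigendecomposed; the null space
    (constant vector, for a connected graph) is removed and the field is
    drawn with covariance sigma_u^2 Q^+ then centered. No burn-in needed.
    """
    graph.require_connected()
    if sigma_u < 0:
        raise ValueError("sigma_u must be >= 0")
    n = graph.n
    if sigma_u == 0:
        return np.zeros(n)
    rng = np.random.default_rng(seed)
    q = graph.laplacian().toarray()
    evals, evecs = np.linalg.eigh(q)
    keep = evals > 1e-10 * evals.max()
    z = rng.standard_normal(int(keep.sum()))
    u = evecs[:, keep] @ (z / np.sqrt(evals[keep])) * sigma_u
    return u - u.mean()


def generation_offsets(covariates: pd.DataFrame, config: WorldConfig) -> np.ndarray:
    """Offsets used at generation time: E_i = pop_i * years * base_rate / 1e5."""
    return (
        covariates["population"].to_numpy(dtype=float)
        * config.n_years
        * config.base_rate_per_100k
        / 1e5
    )


def _linear_predictor(covariates: pd.DataFrame, beta_true, u, config) -> np.ndarray:
    """beta0 + X beta + u with X built exactly as the fitting module builds it."""
    table = DistrictTable(
        district_id=covariates["district_id"].to_numpy(),
        Y=np.zeros(len(covariates), dtype=int),
        population=covariates["population"].to_numpy(),
        covariates=covariates[COVARIATES],
        n_years=config.n_years,
    )
    X, _ = build_design(table)
    return config.beta0_true + X @ np.asarray(beta_true, dtype=float) + np.asarray(u)


def sample_case_counts(
    covariates: pd.DataFrame,
    beta_true,
    u,
    config: WorldConfig,
    E: np.ndarray | None = None,
    rng=None,
) -> np.ndarray:
    """Per-district counts Y_i ~ Poisson(E_i exp(beta0 + x_i beta + u_i))."""
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence((config.seed, 2))
    )
    if E is None:
        E = generation_offsets(covariates, config)
    eta = _linear_predictor(covariates, beta_true, u, config)
    mean = E * np.exp(eta)
    if not np.all(np.isfinite(mean)):
        raise ValueError("non-finite Poisson mean (check beta_true / u / offsets)")
    return rng.poisson(mean)


def sample_yearly_counts(
    covariates: pd.DataFrame,
    beta_true,
    u,
    config: WorldConfig,
    rng=None,
) -> pd.DataFrame:
    """Year x district count matrix over the configured observation span.

    Rows are years (start_year..start_year + n_years - 1), columns district
    ids. Column sums are distributed as :func:`sample_case_counts`.
    """
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence((config.seed, 2))
    )
    E = generation_offsets(covariates, config)
    eta = _linear_predictor(covariates, beta_true, u, config)
    annual_mean = E * np.exp(eta) / config.n_years
    years = np.arange(config.start_year, config.start_year + config.n_years)
    counts = rng.poisson(np.tile(annual_mean, (config.n_years, 1)))
    return pd.DataFrame(counts, index=pd.Index(years, name="year"),
                        columns=covariates["district_id"].to_numpy())


def sample_case_records(
    counts, config: WorldConfig, rng=None
) -> pd.DataFrame:
    """Individual case records with injected exact duplicates.

    ``counts`` is a per-district count vector (indexable by position) or a
    pandas Series indexed by district id. Each base record independently
    spawns one exact duplicate (on the four key fields) with probability
    ``config.duplicate_rate``; duplicates are appended after the base
    records so the stable keep-first dedupe rule retains originals.
    """
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence((config.seed, 3))
    )
    if isinstance(counts, pd.Series):
        district_ids = counts.index.to_numpy()
        counts_arr = counts.to_numpy()
    else:
        counts_arr = np.asarray(counts)
        district_ids = np.arange(len(counts_arr))
    if np.any(counts_arr < 0):
        raise ValueError("counts must be nonnegative")

    district_col = np.repeat(district_ids, counts_arr)
    n = len(district_col)
    band_idx = rng.choice(len(_AGE_BANDS), size=n, p=_AGE_BAND_PROBS)
    lo = np.array([b[0] for b in _AGE_BANDS])[band_idx]
    hi = np.array([b[1] for b in _AGE_BANDS])[band_idx]
    ages = rng.integers(lo, hi + 1)
    sexes = np.where(rng.uniform(size=n) < _MALE_FRACTION, "M", "F")
    months = rng.integers(1, 13, size=n)
    base = pd.DataFrame(
        {"age": ages, "sex": sexes, "month": months, "district_id": district_col}
    )
    dup_mask = rng.uniform(size=n) < config.duplicate_rate
    records = pd.concat([base, base[dup_mask]], ignore_index=True)
    records.insert(0, "id", np.arange(len(records)))
    return records


def _draw_segment_cells(grid: RasterGrid, p0, p1):
    """Cells touched by the segment p0-p1 (dense sampling at cell_size/4)."""
    (x0, y0), (x1, y1) = p0, p1
    length = np.hypot(x1 - x0, y1 - y0)
    n_steps = max(int(length / (grid.cell_size / 4.0)), 1)
    t = np.linspace(0.0, 1.0, n_steps + 1)
    xs = x0 + t * (x1 - x0)
    ys = y0 + t * (y1 - y0)
    r, c = grid.index_of(xs, ys)
    ok = (r >= 0) & (r < grid.n_rows) & (c >= 0) & (c < grid.n_cols)
    return np.unique(np.stack([r[ok], c[ok]], axis=1), axis=0)


def generate_raster_world(
    config: WorldConfig, districts: pd.DataFrame | None = None
) -> RasterWorld:
    """Raster world: smooth elevation, land classes, a connected road tree
    over town/facility/station nodes, and census units on or near roads."""
    if config.n_facilities < 1 or config.n_stations < 1:
        raise ValueError("need at least one facility and one ambulance station")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 4)))
    nr, nc = config.raster_rows, config.raster_cols
    width, height = config.extent
    grid0 = RasterGrid(np.zeros((nr, nc)), x_origin=0.0, y_origin=height,
                       cell_size=config.cell_size)

    # elevation: smooth bumps scaled to [0, 2000] m
    fld = _smooth_lattice_field(nr, nc, rng, n_bumps=8, noise=0.02)
    fld = (fld - fld.min()) / max(fld.max() - fld.min(), 1e-9)
    elevation = grid0.like(2000.0 * fld)

    # moisture field drives forest and biotic units
    moist = _smooth_lattice_field(nr, nc, rng, n_bumps=8, noise=0.05)
    moist = (moist - moist.min()) / max(moist.max() - moist.min(), 1e-9)

    # land class: lowest-elevation cells water, wettest non-water forest
    land = np.zeros((nr, nc), dtype=int)
    water = fld <= np.quantile(fld, 0.05)
    land[water] = 2
    forest = (moist >= np.quantile(moist, 0.70)) & ~water
    land[forest] = 1

    # biotic units: quantiles of moisture; very high ground is Other
    biotic = np.full((nr, nc), 3, dtype=int)  # Dry
    q1, q2, q3 = np.quantile(moist, [0.35, 0.6, 0.85])
    biotic[moist >= q1] = 0  # Moist
    biotic[moist >= q2] = 1  # Wet
    biotic[moist >= q3] = 2  # Pluvial
    biotic[elevation.values > 1800.0] = 4  # Other

    # network nodes: towns, facilities/stations/ebais at a subset of them
    n_nodes = max(config.n_towns, config.n_facilities + 1, config.n_stations + 1)
    margin = 2.5 * config.cell_size
    nodes = np.column_stack(
        [rng.uniform(margin, width - margin, n_nodes),
         rng.uniform(margin, height - margin, n_nodes)]
    )
    # snap nodes to cell centers so point sets land exactly on road cells
    r, c = grid0.index_of(nodes[:, 0], nodes[:, 1])
    nodes = np.column_stack(grid0.cell_center(r, c))

    # minimum spanning tree of the complete Euclidean graph
    d = np.sqrt(((nodes[:, None, :] - nodes[None, :, :]) ** 2).sum(-1))
    mst = minimum_spanning_tree(sp.csr_matrix(d)).tocoo()
    edges = sorted(zip(mst.row, mst.col), key=lambda e: -d[e[0], e[1]])

    road = np.zeros((nr, nc), dtype=int)
    segments = []
    n_edges = len(edges)
    for k, (i, j) in enumerate(edges):
        # longest edges become primary trunks, then secondary, then tertiary
        if k < max(n_edges // 3, 1):
            cls = 1
        elif k < max(2 * n_edges // 3, 2):
            cls = 2
        else:
            cls = 3
        cells = _draw_segment_cells(grid0, nodes[i], nodes[j])
        for rr, cc in cells:
            if road[rr, cc] == 0 or cls < road[rr, cc]:  # fastest class wins
                road[rr, cc] = cls
        segments.append((tuple(nodes[i]), tuple(nodes[j]), ROAD_CLASSES[cls]))

    perm = rng.permutation(n_nodes)
    facilities = [tuple(nodes[i]) for i in perm[: config.n_facilities]]
    stations = [tuple(nodes[i]) for i in rng.permutation(n_nodes)[: config.n_stations]]
    ebais = [tuple(nodes[i]) for i in rng.permutation(n_nodes)[: config.n_ebais]]

    # census units: mostly near road cells, populations summing per district
    if districts is None:
        lattice, _ = generate_district_lattice(config)
        districts = sample_covariates(lattice, config)
    road_cells = np.argwhere(road > 0)
    dcols = config.lattice_cols
    ddx, ddy = width / config.lattice_cols, height / config.lattice_rows
    units: list[CensusUnit] = []
    uid = 0
    for _, drow in districts.iterrows():
        did = int(drow["district_id"])
        pop = float(drow["population"])
        urban_frac = float(drow["urban_frac"])
        n_units = int(np.clip(1 + pop // 4000, 1, 6))
        shares = rng.dirichlet(np.ones(n_units) * 2.0) * pop
        # district bounding box (row 0 northern)
        r0 = int(drow["row"]) if "row" in drow else did // dcols
        c0 = int(drow["col"]) if "col" in drow else did % dcols
        x_lo, x_hi = c0 * ddx, (c0 + 1) * ddx
        y_hi, y_lo = height - r0 * ddy, height - (r0 + 1) * ddy
        # road cells inside the district, if any, attract units
        in_box = [
            (rr, cc)
            for rr, cc in road_cells
            if x_lo <= grid0.cell_center(rr, cc)[0] < x_hi
            and y_lo < grid0.cell_center(rr, cc)[1] <= y_hi
        ]
        for s in shares:
            if in_box and rng.uniform() < 0.8:
                rr, cc = in_box[rng.integers(len(in_box))]
                x, y = grid0.cell_center(rr, cc)
                x += rng.uniform(-0.4, 0.4) * config.cell_size
                y += rng.uniform(-0.4, 0.4) * config.cell_size
            else:
                x = rng.uniform(x_lo + 1e-3, x_hi - 1e-3)
                y = rng.uniform(y_lo + 1e-3, y_hi - 1e-3)
            units.append(
                CensusUnit(
                    unit_id=uid, x=float(x), y=float(y),
                    population=float(np.round(s)),
                    urban=bool(rng.uniform() < urban_frac),
                    district_id=did,
                )
            )
            uid += 1

    return RasterWorld(
        elevation=elevation,
        land_class=grid0.like(land),
        road_class=grid0.like(road),
        biotic=grid0.like(biotic),
        facilities=facilities,
        stations=stations,
        ebais=ebais,
        census_units=units,
        road_segments=segments,
    )
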