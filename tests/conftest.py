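import numpy as np
import pandas as pd
import pytest

from snakerisk.adjacency import lattice_queen_adjacency
from snakerisk.disease_mapping import COVARIATES, DistrictTable, compute_offsets
from snakerisk.synthetic_world import (
    WorldConfig,
    generate_district_lattice,
    sample_car_field,
    sample_case_counts,
    sample_covariates,
)


@pytest.fixture(scope="session")
def small_cfg():
    return WorldConfig(
        lattice_rows=6, lattice_cols=6, raster_rows=40, raster_cols=40,
        cell_size=100.0, n_years=5, base_rate_per_100k=200.0,
        population_range=(1000, 10000), seed=42,
    )


@pytest.fixture(scope="session")
def small_world(small_cfg):
    lattice, graph = generate_district_lattice(small_cfg)
    covariates = sample_covariates(lattice, small_cfg)
    return lattice, graph, covariates


@pytest.fixture(scope="session")
def small_table(small_cfg, small_world):
    _, graph, covariates = small_world
    u = sample_car_field(graph, small_cfg.sigma_u,
                         np.random.SeedSequence((small_cfg.seed, 10)))
    y = sample_case_counts(covariates, small_cfg.beta_true, u, small_cfg)
    table = DistrictTable(
        district_id=covariates["district_id"].to_numpy(),
        Y=y,
        population=covariates["population"].to_numpy(),
        covariates=covariates[COVARIATES],
        n_years=small_cfg.n_years,
    )
    table.E = compute_offsets(table)
    return table


@pytest.fixture
def chain_graph():
    """3-district path: 0 - 1 - 2."""
    from snakerisk.adjacency import AdjacencyGraph

    return AdjacencyGraph(neighbors=[[1], [0, 2], [1]])


def toy_table(y, pop, n_years=1.0):
    """Minimal district table with benign covariates for small fixtures."""
    n = len(y)
    rng = np.random.default_rng(0)
    cov = pd.DataFrame(
        {
            "urban_frac": np.linspace(0.1, 0.9, n),
            "forest_frac": np.linspace(0.8, 0.2, n),
            "elevation_m": np.linspace(100, 900, n),
            "precipitation_mm_yr": 3000 + 100 * rng.standard_normal(n),
            "dry_months": np.arange(n) % 5 + 1.0,
        }
    )
    return DistrictTable(
        district_id=np.arange(n), Y=np.asarray(y),
        population=np.asarray(pop, dtype=float), covariates=cov,
        n_years=n_years,
    )
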