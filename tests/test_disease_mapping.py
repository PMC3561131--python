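import math

import numpy as np
import pandas as pd
import pytest

from snakerisk.adjacency import AdjacencyGraph, lattice_queen_adjacency
from snakerisk.disease_mapping import (
    COVARIATES,
    DistrictTable,
    McmcConfig,
    ModelPriors,
    PosteriorSamples,
    build_design,
    compute_offsets,
    exceedance_probability,
    fit_car_poisson,
    incidence_ratio_summary,
    log_posterior,
    posterior_incidence,
    rhat,
    standardize_covariates,
)
from snakerisk.synthetic_world import (
    WorldConfig,
    generate_district_lattice,
    sample_car_field,
    sample_case_counts,
    sample_covariates,
)

from conftest import toy_table


class TestOffsets:
    def test_proportionality(self):
        t = toy_table(y=[3, 5], pop=[1000, 3000])
        np.testing.assert_allclose(compute_offsets(t), [2.0, 6.0])

    def test_equal_populations_equal_offsets(self):
        t = toy_table(y=[1, 2, 3], pop=[500, 500, 500])
        e = compute_offsets(t)
        assert len(set(np.round(e, 12))) == 1

    def test_conservation(self, small_table):
        e = compute_offsets(small_table)
        assert abs(e.sum() - small_table.Y.sum()) <= 1e-9 * small_table.Y.sum()

    def test_zero_cases_rejected(self):
        t = toy_table(y=[0, 0], pop=[100, 100])
        with pytest.raises(ValueError):
            compute_offsets(t)


class TestStandardize:
    def test_two_point_column(self):
        t = toy_table(y=[1, 1], pop=[100, 100])
        t.covariates["elevation_m"] = [0.0, 2.0]
        std, scaling = standardize_covariates(t)
        np.testing.assert_allclose(std["elevation_m"], [-1.0, 1.0])
        assert scaling.means["elevation_m"] == 1.0
        assert scaling.sds["elevation_m"] == 1.0  # population SD

    def test_idempotent(self):
        t = toy_table(y=[1, 1, 1, 1], pop=[1] * 4)
        col = np.array([-1.3, -0.2, 0.4, 1.1])
        col = (col - col.mean()) / col.std(ddof=0)
        t.covariates["precipitation_mm_yr"] = col
        std, _ = standardize_covariates(t)
        np.testing.assert_allclose(std["precipitation_mm_yr"], col, atol=1e-12)

    def test_fractions_left_alone(self, small_table):
        std, scaling = standardize_covariates(small_table)
        np.testing.assert_array_equal(
            std["urban_frac"], small_table.covariates["urban_frac"]
        )
        assert "urban_frac" not in scaling.sds

    def test_constant_column_named_in_error(self):
        t = toy_table(y=[1, 1], pop=[1, 1])
        t.covariates["dry_months"] = [2.0, 2.0]
        with pytest.raises(ValueError, match="dry_months"):
            standardize_covariates(t)


class TestLogPosteriorOracle:
    def test_hand_computed_three_districts(self, chain_graph):
        t = toy_table(y=[2, 0, 3], pop=[100.0, 200.0, 150.0])
        t.E = np.array([1.5, 2.5, 1.0])
        priors = ModelPriors()
        beta0, tau = 0.3, 4.0
        beta = [0.1, -0.2, 0.05, 0.4, -0.3]
        u = [0.2, -0.15, -0.05]

        value = log_posterior(beta0, np.array(beta), np.array(u), tau, t,
                              chain_graph, priors)

        # --- independent arithmetic, pure Python, following the stated
        # definition term by term
        cols = {}
        for name in COVARIATES:
            cols[name] = [float(v) for v in t.covariates[name]]
        for name in ("elevation_m", "precipitation_mm_yr", "dry_months"):
            vals = cols[name]
            m = sum(vals) / 3
            sd = math.sqrt(sum((v - m) ** 2 for v in vals) / 3)
            cols[name] = [(v - m) / sd for v in vals]
        x_rows = [[cols[name][i] for name in COVARIATES] for i in range(3)]
        y = [2.0, 0.0, 3.0]
        e = [1.5, 2.5, 1.0]
        expected = 0.0
        for i in range(3):
            eta = beta0 + sum(x_rows[i][j] * beta[j] for j in range(5)) + u[i]
            expected += y[i] * math.log(e[i]) + y[i] * eta - e[i] * math.exp(eta)
            expected -= math.lgamma(y[i] + 1.0)
        prec = 0.0001
        for b in beta:
            expected += 0.5 * math.log(prec / (2 * math.pi)) - 0.5 * prec * b * b
        quad = (u[0] - u[1]) ** 2 + (u[1] - u[2]) ** 2
        expected += 0.5 * (3 - 1) * math.log(tau) - 0.5 * tau * quad
        a, b_ = 0.5, 0.0005
        expected += (a * math.log(b_) - math.lgamma(a)
                     + (a - 1) * math.log(tau) - b_ * tau)

        assert value == pytest.approx(expected, abs=1e-10)


class TestFit:
    def test_sum_to_zero_every_draw(self, small_table, small_world):
        _, graph, _ = small_world
        mcmc = McmcConfig(n_burn=400, n_keep=400, n_chains=2, seed=5)
        fitted = fit_car_poisson(small_table, graph, mcmc=mcmc)
        assert np.all(np.abs(fitted.flat("u").mean(axis=1)) < 1e-8)

    def test_recovery_single_replicate(self):
        cfg = WorldConfig(lattice_rows=10, lattice_cols=10, n_years=5,
                          base_rate_per_100k=1000.0,
                          population_range=(5000, 50000), seed=77)
        lattice, graph = generate_district_lattice(cfg)
        cov = sample_covariates(lattice, cfg)
        u = sample_car_field(graph, cfg.sigma_u,
                             np.random.SeedSequence((cfg.seed, 10)))
        y = sample_case_counts(cov, cfg.beta_true, u, cfg)
        table = DistrictTable(
            district_id=cov["district_id"].to_numpy(), Y=y,
            population=cov["population"].to_numpy(),
            covariates=cov[COVARIATES], n_years=cfg.n_years,
        )
        table.E = compute_offsets(table)
        samples = fit_car_poisson(
            table, graph, mcmc=McmcConfig(n_burn=1500, n_keep=1500,
                                          n_chains=1, seed=8)
        )
        err = np.abs(samples.flat("beta").mean(axis=0) - np.array(cfg.beta_true))
        assert np.all(err < 0.15)

    def test_offset_doubling_shifts_intercept(self, small_table, small_world):
        _, graph, _ = small_world
        mcmc = McmcConfig(n_burn=800, n_keep=800, n_chains=1, seed=3)
        s1 = fit_car_poisson(small_table, graph, mcmc=mcmc)
        doubled = DistrictTable(
            district_id=small_table.district_id, Y=small_table.Y,
            population=small_table.population,
            covariates=small_table.covariates, n_years=small_table.n_years,
            E=2.0 * small_table.E,
        )
        s2 = fit_car_poisson(doubled, graph, mcmc=mcmc)
        shift = s2.flat("beta0").mean() - s1.flat("beta0").mean()
        assert shift == pytest.approx(-math.log(2.0), abs=0.08)

    def test_null_recovery_coverage(self):
        # beta = 0, sigma_u ~ 0: each coefficient's CrI covers 0 in >= 90%
        # of seeded replicates
        hits = np.zeros(5)
        n_reps = 10
        for rep in range(n_reps):
            cfg = WorldConfig(lattice_rows=7, lattice_cols=7, n_years=5,
                              base_rate_per_100k=300.0,
                              beta_true=(0.0,) * 5, sigma_u=0.0,
                              population_range=(2000, 20000), seed=900 + rep)
            lattice, graph = generate_district_lattice(cfg)
            cov = sample_covariates(lattice, cfg)
            y = sample_case_counts(cov, cfg.beta_true, np.zeros(49), cfg)
            table = DistrictTable(
                district_id=cov["district_id"].to_numpy(), Y=y,
                population=cov["population"].to_numpy(),
                covariates=cov[COVARIATES], n_years=cfg.n_years,
            )
            table.E = compute_offsets(table)
            s = fit_car_poisson(table, graph,
                                mcmc=McmcConfig(n_burn=600, n_keep=600,
                                                n_chains=1, seed=rep))
            b = s.flat("beta")
            lo = np.percentile(b, 2.5, axis=0)
            hi = np.percentile(b, 97.5, axis=0)
            hits += (lo <= 0.0) & (0.0 <= hi)
        assert np.all(hits >= 0.9 * n_reps - 1)

    def test_shrinkage_on_sparse_data(self):
        # small-population districts: smoothed rates deviate less from the
        # global rate than raw rates do
        cfg = WorldConfig(lattice_rows=8, lattice_cols=8, n_years=1,
                          base_rate_per_100k=50.0, sigma_u=0.1,
                          population_range=(300, 3000), seed=21)
        lattice, graph = generate_district_lattice(cfg)
        cov = sample_covariates(lattice, cfg)
        u = sample_car_field(graph, cfg.sigma_u, 1)
        y = sample_case_counts(cov, cfg.beta_true, u, cfg)
        y[0] += 1  # guarantee a nonzero total
        table = DistrictTable(
            district_id=cov["district_id"].to_numpy(), Y=y,
            population=cov["population"].to_numpy(),
            covariates=cov[COVARIATES], n_years=1,
        )
        table.E = compute_offsets(table)
        s = fit_car_poisson(table, graph,
                            mcmc=McmcConfig(n_burn=600, n_keep=600,
                                            n_chains=1, seed=2))
        smoothed = posterior_incidence(s, table).mean(axis=0)
        raw = 1e5 * table.Y / (table.population * table.n_years)
        global_rate = 1e5 * table.Y.sum() / table.population.sum()
        small = table.population < np.median(table.population)
        mad_raw = np.abs(raw[small] - global_rate).mean()
        mad_smoothed = np.abs(smoothed[small] - global_rate).mean()
        assert mad_smoothed < mad_raw

    def test_nonfinite_inputs_rejected(self, small_table, small_world):
        _, graph, _ = small_world
        bad = DistrictTable(
            district_id=small_table.district_id, Y=small_table.Y,
            population=small_table.population,
            covariates=small_table.covariates, n_years=small_table.n_years,
            E=np.where(np.arange(small_table.n) == 0, np.inf, small_table.E),
        )
        with pytest.raises(ValueError, match="finite"):
            fit_car_poisson(bad, graph,
                            mcmc=McmcConfig(n_burn=50, n_keep=50, n_chains=1))

    def test_disconnected_graph_rejected(self, small_table):
        # right size (36) but two components
        g = AdjacencyGraph(
            neighbors=[[1], [0]] + [([i + 1] if i % 2 == 0 else [i - 1])
                                    for i in range(2, 36)]
        )
        with pytest.raises(ValueError, match="disconnected"):
            fit_car_poisson(small_table, g)


class TestRhat:
    def test_identical_chains_exactly_one(self):
        chain = np.sin(np.arange(100.0))
        assert rhat(np.stack([chain, chain])) == 1.0

    def test_disjoint_supports_large(self):
        c1 = np.random.default_rng(0).normal(0, 1, 200)
        c2 = c1 + 50.0
        assert rhat(np.stack([c1, c2])) > 10

    def test_single_short_chain_rejected(self):
        with pytest.raises(ValueError):
            rhat(np.arange(6.0)[None, :])

    def test_converged_fit_below_105(self, small_table, small_world):
        _, graph, _ = small_world
        s = fit_car_poisson(
            small_table, graph,
            mcmc=McmcConfig(n_burn=2000, n_keep=4000, n_chains=2, seed=12),
        )
        for j in range(5):
            assert rhat(s.beta[:, :, j]) < 1.05
        assert rhat(s.beta0) < 1.05


class TestIncidence:
    def _samples(self, table, eta_draws):
        x, scaling = build_design(table)
        n_draws, n = eta_draws.shape
        s = PosteriorSamples(
            beta0=np.zeros((1, n_draws)),
            beta=np.zeros((1, n_draws, 5)),
            u=eta_draws[None, :, :],
            sigma2_u=np.ones((1, n_draws)),
            covariate_names=list(COVARIATES),
            scaling=scaling,
        )
        s._X = x
        return s

    def test_eta_zero_gives_uniform_mean_rate(self):
        t = toy_table(y=[5, 5], pop=[10000, 40000], n_years=2.0)
        t.E = compute_offsets(t)
        s = self._samples(t, np.zeros((10, 2)))
        rates = posterior_incidence(s, t)
        overall = 1e5 * 10 / (50000 * 2.0)
        np.testing.assert_allclose(rates, overall)

    def test_unit_conversion(self):
        # E * exp(eta) = 15 cases, pop 10,000, 5 years -> 30 per 100,000
        t = toy_table(y=[15, 1], pop=[10000, 10000], n_years=5.0)
        t.E = np.array([5.0, 1.0])
        eta = np.log(np.array([[15.0 / 5.0, 1.0]]))
        rates = posterior_incidence(self._samples(t, eta), t)
        assert rates[0, 0] == pytest.approx(30.0)

    def test_monotone_in_eta(self):
        t = toy_table(y=[1, 1], pop=[1000, 1000], n_years=1.0)
        t.E = np.array([1.0, 1.0])
        r1 = posterior_incidence(self._samples(t, np.array([[0.1, 0.1]])), t)
        r2 = posterior_incidence(self._samples(t, np.array([[0.2, 0.1]])), t)
        assert r2[0, 0] > r1[0, 0]
        assert r2[0, 1] == r1[0, 1]


class TestExceedance:
    def test_all_above(self):
        assert exceedance_probability(np.full((10, 1), 50.0), 30.0)[0] == 1.0

    def test_half(self):
        draws = np.array([[20.0], [40.0]])
        assert exceedance_probability(draws, 30.0)[0] == 0.5

    def test_infinite_threshold(self):
        draws = np.random.default_rng(0).uniform(0, 100, (50, 3))
        np.testing.assert_array_equal(
            exceedance_probability(draws, np.inf), np.zeros(3)
        )

    def test_strict_inequality(self):
        draws = np.full((4, 1), 30.0)
        assert exceedance_probability(draws, 30.0)[0] == 0.0


class TestIncidenceRatio:
    def test_constant_draws(self, small_table):
        x, scaling = build_design(small_table)
        beta = np.full((1, 100, 5), math.log(0.60))
        s = PosteriorSamples(
            beta0=np.zeros((1, 100)), beta=beta, u=np.zeros((1, 100, 2)),
            sigma2_u=np.ones((1, 100)), covariate_names=list(COVARIATES),
            scaling=scaling,
        )
        table = incidence_ratio_summary(s)
        assert np.allclose(table["incidence_ratio"], 0.60)
        assert np.allclose(table["cri_low"], 0.60)
        assert np.allclose(table["cri_high"], 0.60)

    def test_symmetric_draws_straddle_one(self, small_table):
        _, scaling = build_design(small_table)
        rng = np.random.default_rng(4)
        beta = rng.normal(0.0, 0.3, (1, 4000, 5))
        s = PosteriorSamples(
            beta0=np.zeros((1, 4000)), beta=beta, u=np.zeros((1, 4000, 2)),
            sigma2_u=np.ones((1, 4000)), covariate_names=list(COVARIATES),
            scaling=scaling,
        )
        table = incidence_ratio_summary(s)
        assert (table["cri_low"] < 1.0).all()
        assert (table["cri_high"] > 1.0).all()

    def test_schema_and_units(self, small_table, small_world):
        _, graph, _ = small_world
        s = fit_car_poisson(small_table, graph,
                            mcmc=McmcConfig(n_burn=200, n_keep=200,
                                            n_chains=1, seed=1))
        table = incidence_ratio_summary(s)
        assert list(table.columns) == [
            "covariate", "unit", "incidence_ratio", "cri_low", "cri_high"
        ]
        units = dict(zip(table["covariate"], table["unit"]))
        assert units["urban_frac"] == "+100%-units"
        assert units["elevation_m"].startswith("+")
        assert units["elevation_m"].endswith(" m")
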