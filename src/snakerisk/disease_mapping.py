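"""Bayesian Poisson disease mapping with an intrinsic CAR spatial prior.

The model for district case counts is

    Y_i ~ Poisson(E_i * exp(beta0 + x_i' beta + u_i))

with E_i the expected count were cases distributed evenly over the
population (the offset), beta0 given an improper flat prior, beta_j given
independent N(0, precision 0.0001) priors, and u an intrinsic Besag CAR
field over queen contiguity with a sum-to-zero constraint and a gamma
prior on its precision. Fitting is Metropolis-within-Gibbs: adaptive
random-walk updates for beta0 and beta, single-site (color-blocked)
random-walk updates for u, and a conjugate gamma draw for the CAR
precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .adjacency import AdjacencyGraph, polygon_queen_adjacency

__all__ = [
    "COVARIATES",
    "CONTINUOUS_COVARIATES",
    "FRACTION_COVARIATES",
    "DistrictTable",
    "ModelPriors",
    "McmcConfig",
    "ScalingRecord",
    "PosteriorSamples",
    "build_adjacency",
    "compute_offsets",
    "standardize_covariates",
    "build_design",
    "log_posterior",
    "fit_car_poisson",
    "rhat",
    "posterior_incidence",
    "exceedance_probability",
    "incidence_ratio_summary",
]

# Column order of the design matrix. Fraction-valued covariates stay on
# their natural [0, 1] scale; continuous ones are standardized before
# fitting.
FRACTION_COVARIATES = ["urban_frac", "forest_frac"]
CONTINUOUS_COVARIATES = ["elevation_m", "precipitation_mm_yr", "dry_months"]
COVARIATES = FRACTION_COVARIATES + CONTINUOUS_COVARIATES

_NATURAL_UNITS = {
    "urban_frac": "+100%-units",
    "forest_frac": "+100%-units",
    "elevation_m": "m",
    "precipitation_mm_yr": "mm/year",
    "dry_months": "months",
}


@dataclass
class DistrictTable:
    """Per-district data: counts, population, covariates, offsets.

    ``Y`` is the case count over the whole modeled period (``n_years``);
    ``E`` is the offset, set by :func:`compute_offsets`.
    """

    district_id: np.ndarray
    Y: np.ndarray
    population: np.ndarray
    covariates: pd.DataFrame  # columns = COVARIATES
    n_years: float
    E: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.district_id = np.asarray(self.district_id)
        self.Y = np.asarray(self.Y)
        self.population = np.asarray(self.population, dtype=float)
        if np.any(self.Y < 0) or not np.all(np.equal(np.mod(self.Y, 1), 0)):
            raise ValueError("Y must be nonnegative integers")
        if np.any(self.population <= 0):
            raise ValueError("population must be positive")
        missing = [c for c in COVARIATES if c not in self.covariates.columns]
        if missing:
            raise ValueError(f"covariate columns missing: {missing}")
        if self.E is not None:
            self.E = np.asarray(self.E, dtype=float)
            if np.any(self.E <= 0):
                raise ValueError("offsets E must be positive")

    @property
    def n(self) -> int:
        return len(self.Y)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"district_id": self.district_id, "Y": self.Y,
                           "population": self.population})
        for c in COVARIATES:
            df[c] = np.asarray(self.covariates[c])
        df["n_years"] = self.n_years
        if self.E is not None:
            df["E"] = self.E
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DistrictTable":
        n_years = float(df["n_years"].iloc[0])
        return cls(
            district_id=df["district_id"].to_numpy(),
            Y=df["Y"].to_numpy(),
            population=df["population"].to_numpy(),
            covariates=df[COVARIATES].copy(),
            n_years=n_years,
            E=df["E"].to_numpy() if "E" in df.columns else None,
        )


@dataclass
class ModelPriors:
    coef_mean: float = 0.0
    coef_precision: float = 0.0001
    car_gamma_shape: float = 0.5
    car_gamma_rate: float = 0.0005

    def __post_init__(self) -> None:
        if self.coef_precision <= 0:
            raise ValueError("coef_precision must be > 0")
        if self.car_gamma_shape <= 0 or self.car_gamma_rate <= 0:
            raise ValueError("gamma hyperparameters must be > 0")


@dataclass
class McmcConfig:
    n_burn: int = 2000
    n_keep: int = 2000
    thin: int = 1
    n_chains: int = 2
    seed: int = 0
    adapt_interval: int = 50
    target_accept: float = 0.44

    def __post_init__(self) -> None:
        if self.n_burn <= 0 or self.n_keep <= 0:
            raise ValueError("n_burn and n_keep must be positive")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class ScalingRecord:
    """Original mean/SD (population convention, ddof=0) per standardized column."""

    means: dict[str, float]
    sds: dict[str, float]

    def natural_unit(self, name: str) -> str:
        if name in self.sds:
            return f"+{self.sds[name]:g} {_NATURAL_UNITS[name]}"
        return _NATURAL_UNITS[name]


@dataclass
class PosteriorSamples:
    """MCMC draws, kept per chain: shapes (n_chains, n_draws[, dim])."""

    beta0: np.ndarray
    beta: np.ndarray
    u: np.ndarray
    sigma2_u: np.ndarray
    covariate_names: list[str]
    scaling: ScalingRecord
    accept_rates: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.beta0.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta0.shape[1]

    def flat(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    def eta(self) -> np.ndarray:
        """Linear predictor draws, shape (total draws, n districts).

        Requires the design matrix to be re-attached via ``_X`` (set by
        :func:`fit_car_poisson`).
        """
        x = self._X  # type: ignore[attr-defined]
        return (
            self.flat("beta0")[:, None]
            + self.flat("beta") @ x.T
            + self.flat("u")
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"chain": np.repeat(np.arange(self.n_chains), self.n_draws),
                "beta0": self.flat("beta0"),
                "sigma2_u": self.flat("sigma2_u")}
        df = pd.DataFrame(cols)
        beta = self.flat("beta")
        for j, name in enumerate(self.covariate_names):
            df[f"beta[{name}]"] = beta[:, j]
        u = self.flat("u")
        for i in range(u.shape[1]):
            df[f"u[{i}]"] = u[:, i]
        return df


def build_adjacency(polygons, ids=None) -> AdjacencyGraph:
    """Queen contiguity between district polygons (border or corner contact)."""
    graph = polygon_queen_adjacency(polygons, ids=ids)
    graph.require_no_islands()
    return graph


def compute_offsets(table: DistrictTable) -> np.ndarray:
    """Expected counts under even distribution of all cases by population."""
    total_pop = table.population.sum()
    if total_pop <= 0:
        raise ValueError("total population is zero")
    total_cases = table.Y.sum()
    if total_cases <= 0:
        raise ValueError("total case count is zero; offsets undefined")
    return total_cases * table.population / total_pop


def standardize_covariates(
    table: DistrictTable,
) -> tuple[pd.DataFrame, ScalingRecord]:
    """Standardize continuous covariates to mean 0, SD 1 (population SD).

    Fraction-valued covariates (urban, forest) are left on [0, 1] so their
    coefficients read per +100%-units.
    """
    cov = table.covariates[COVARIATES].astype(float).copy()
    means, sds = {}, {}
    for name in CONTINUOUS_COVARIATES:
        col = cov[name].to_numpy()
        mu = float(col.mean())
        sd = float(col.std(ddof=0))
        if sd == 0:
            raise ValueError(f"covariate '{name}' is constant; cannot standardize")
        cov[name] = (col - mu) / sd
        means[name], sds[name] = mu, sd
    return cov, ScalingRecord(means=means, sds=sds)


def build_design(table: DistrictTable) -> tuple[np.ndarray, ScalingRecord]:
    cov, scaling = standardize_covariates(table)
    return cov[COVARIATES].to_numpy(dtype=float), scaling


def log_posterior(
    beta0: float,
    beta: np.ndarray,
    u: np.ndarray,
    tau: float,
    table: DistrictTable,
    graph: AdjacencyGraph,
    priors: ModelPriors,
    X: np.ndarray | None = None,
) -> float:
    """Joint log density of the model (up to the flat-intercept constant).

    Terms, in order:
      Poisson log-likelihood  sum_i [Y_i log(E_i) + Y_i eta_i - E_i e^eta_i
                                      - lgamma(Y_i + 1)]
      coefficient priors      sum_j [0.5 log(prec/(2 pi)) - 0.5 prec beta_j^2]
      intrinsic CAR           ((n - c)/2) log tau
                              - (tau/2) sum_{i<j adjacent} (u_i - u_j)^2
      gamma prior on tau      a log b - lgamma(a) + (a - 1) log tau - b tau

    with c the number of connected components of the graph.
    """
    if X is None:
        X, _ = build_design(table)
    beta = np.asarray(beta, dtype=float)
    u = np.asarray(u, dtype=float)
    E = table.E
    if E is None:
        raise ValueError("offsets E must be set before evaluating the posterior")
    eta = beta0 + X @ beta + u
    loglik = float(
        np.sum(table.Y * np.log(E) + table.Y * eta - E * np.exp(eta))
        - np.sum(gammaln(table.Y + 1.0))
    )
    prec = priors.coef_precision
    logprior_beta = float(
        0.5 * len(beta) * math.log(prec / (2 * math.pi))
        - 0.5 * prec * np.sum(beta**2)
    )
    n_comp, _ = graph.components()
    quad = sum((u[i] - u[j]) ** 2 for i, j in graph.edge_list())
    log_car = 0.5 * (graph.n - n_comp) * math.log(tau) - 0.5 * tau * quad
    a, b = priors.car_gamma_shape, priors.car_gamma_rate
    log_tau_prior = a * math.log(b) - float(gammaln(a)) + (a - 1) * math.log(tau) - b * tau
    return loglik + logprior_beta + log_car + log_tau_prior


def _run_chain(
    Y, E, X, graph, priors, mcmc, seed, sigma_u_init=0.1
):
    rng = np.random.default_rng(seed)
    n, p = X.shape
    w = graph.sparse_w()
    lap = graph.laplacian()
    n_nb = graph.n_neighbors.astype(float)
    colors = graph.coloring()
    a0, b0 = priors.car_gamma_shape, priors.car_gamma_rate
    prec = priors.coef_precision

    beta0 = math.log(max(Y.sum(), 1.0) / E.sum())
    beta = np.zeros(p)
    # start u at damped log-residuals: avoids the intrinsic-CAR trap where
    # u = 0 makes the precision explode and pins the field at zero
    u = 0.5 * (np.log((Y + 0.5) / E) - beta0)
    u -= u.mean()
    rank = n - graph.components()[0]
    q0 = float(u @ (graph.laplacian() @ u))
    tau = rank / q0 if q0 > 0 else 1.0 / sigma_u_init**2
    eta = beta0 + X @ beta + u
    mu = E * np.exp(eta)

    # adaptive random-walk scales
    s_beta0 = 0.1
    s_beta = np.full(p, 0.1)
    s_u = 0.5
    s_joint = 1.0
    s_scale = 0.3
    s_conf = np.full(p, 0.05)
    # centered covariate columns and their CAR quadratic forms, for the
    # likelihood-invariant confounding-direction moves
    x_mean = X.mean(axis=0)
    c_cent = [X[:, j] - x_mean[j] for j in range(p)]
    cLu = [np.asarray(lap @ c) for c in c_cent]
    cLc = [float(c @ lc) for c, lc in zip(c_cent, cLu)]
    acc = {"beta0": 0, "beta": np.zeros(p), "u": 0, "u_total": 0,
           "joint": 0, "joint_total": 0, "scale": 0, "scale_total": 0,
           "conf": np.zeros(p), "conf_total": np.zeros(p)}
    n_since_adapt = 0

    # Fisher-preconditioned joint proposal for beta: component-wise walks
    # mix poorly under collinear covariates. Covariance from the Laplace
    # approximation at the (u-fixed) Poisson GLM mode, refreshed from the
    # chain history later in burn-in.
    hist_n = 0
    hist_mean = np.zeros(p)
    hist_m2 = np.zeros((p, p))
    joint_start = 400
    Xc = np.column_stack([np.ones(n), X])
    coef = np.concatenate([[beta0], beta])
    for _ in range(25):  # Newton steps to the conditional mode
        mu_w = E * np.exp(Xc @ coef + u)
        grad = Xc.T @ (Y - mu_w) - prec * np.concatenate([[0.0], coef[1:]])
        fisher = Xc.T @ (mu_w[:, None] * Xc) + prec * np.diag([0.0] + [1.0] * p)
        step = np.linalg.solve(fisher, grad)
        coef = coef + np.clip(step, -2.0, 2.0)
        if np.max(np.abs(step)) < 1e-8:
            break
    beta0, beta = float(coef[0]), coef[1:].copy()
    mu = E * np.exp(Xc @ coef + u)
    fisher_cov = np.linalg.inv(fisher)[1:, 1:]
    chol = np.linalg.cholesky((2.38**2 / p) * fisher_cov)

    sum_Y = float(Y.sum())
    Yx = Y @ X  # per-coefficient sufficient statistic

    n_iter = mcmc.n_burn + mcmc.n_keep * mcmc.thin
    keep_every = mcmc.thin
    draws_beta0 = np.empty(mcmc.n_keep)
    draws_beta = np.empty((mcmc.n_keep, p))
    draws_u = np.empty((mcmc.n_keep, n))
    draws_sigma2 = np.empty(mcmc.n_keep)
    k = 0

    for it in range(n_iter):
        # --- intercept (flat prior)
        d = rng.normal(0.0, s_beta0)
        dlog = d * sum_Y - (math.expm1(d)) * mu.sum()
        if math.log(rng.uniform()) < dlog:
            beta0 += d
            mu *= math.exp(d)
            acc["beta0"] += 1

        # --- coefficients
        for j in range(p):
            d = rng.normal(0.0, s_beta[j])
            xj = X[:, j]
            dlog = (
                d * Yx[j]
                - float(mu @ np.expm1(d * xj))
                - 0.5 * prec * ((beta[j] + d) ** 2 - beta[j] ** 2)
            )
            if not math.isfinite(dlog):
                raise FloatingPointError(
                    f"non-finite log-posterior change at iteration {it} (beta[{j}])"
                )
            if math.log(rng.uniform()) < dlog:
                beta[j] += d
                mu *= np.exp(d * xj)
                acc["beta"][j] += 1

        # --- joint beta block with adapted covariance
        hist_n += 1
        delta_mean = beta - hist_mean
        hist_mean += delta_mean / hist_n
        hist_m2 += np.outer(delta_mean, beta - hist_mean)
        if hist_n > joint_start and hist_n % 25 == 0:
            cov = hist_m2 / (hist_n - 1) + 1e-9 * np.eye(p)
            try:
                chol = np.linalg.cholesky((2.38**2 / p) * cov)
            except np.linalg.LinAlgError:
                chol = None
        for _ in range(2):
            step = s_joint * (chol @ rng.standard_normal(p))
            d_eta = X @ step
            dlog = (
                float(Y @ d_eta)
                - float(mu @ np.expm1(d_eta))
                - 0.5 * prec * float(np.sum((beta + step) ** 2 - beta**2))
            )
            acc["joint_total"] += 1
            if math.isfinite(dlog) and math.log(rng.uniform()) < dlog:
                beta += step
                mu *= np.exp(d_eta)
                acc["joint"] += 1

        # --- likelihood-invariant confounding-direction moves: shift
        # beta_j while subtracting the (centered) covariate pattern from u
        # and absorbing the mean into beta0, leaving eta untouched. Only
        # the CAR and coefficient priors weigh in, so these cheap moves
        # traverse the weakly identified beta-u ridge that plain updates
        # crawl along.
        for j in range(p):
            d = rng.normal(0.0, s_conf[j])
            dlog = (
                -0.5 * tau * (d * d * cLc[j] - 2.0 * d * float(cLu[j] @ u))
                - 0.5 * prec * ((beta[j] + d) ** 2 - beta[j] ** 2)
            )
            acc["conf_total"][j] += 1
            if math.log(rng.uniform()) < dlog:
                beta[j] += d
                u -= d * c_cent[j]
                beta0 -= d * x_mean[j]
                acc["conf"][j] += 1

        # --- refresh the CAR precision before updating the field
        quad = float(u @ (lap @ u))
        tau = rng.gamma(a0 + 0.5 * rank, 1.0 / (b0 + 0.5 * quad))

        # --- CAR effects, color-blocked single-site random walks (two
        # sweeps: the field is the slowest-mixing part of the state)
        for block in colors + colors:
            if len(block) == 0:
                continue
            delta = rng.normal(0.0, s_u, size=len(block))
            s_nb = np.asarray(w[block] @ u).ravel()  # neighbor sums, fixed in block
            u_b = u[block]
            u_new = u_b + delta
            dlog = (
                Y[block] * delta
                - mu[block] * np.expm1(delta)
                - 0.5 * tau * (n_nb[block] * (u_new**2 - u_b**2)
                               - 2.0 * s_nb * delta)
            )
            accept = np.log(rng.uniform(size=len(block))) < dlog
            if accept.any():
                idx = block[accept]
                u[idx] += delta[accept]
                mu[idx] *= np.exp(delta[accept])
            acc["u"] += int(accept.sum())
            acc["u_total"] += len(block)

        # --- joint scaling move on (u, tau): u' = c u, tau' = tau / c^2.
        # The CAR quadratic form is invariant; determinant, Jacobian and
        # gamma-prior terms reduce to the expression below. Beats the slow
        # random-walk drift of the field's global scale.
        eps = rng.normal(0.0, s_scale)
        c = math.exp(eps)
        d_eta = (c - 1.0) * u
        dlog = (
            float(Y @ d_eta)
            - float(mu @ np.expm1(d_eta))
            - 2.0 * eps * a0
            - b0 * tau * math.expm1(-2.0 * eps)
        )
        acc["scale_total"] += 1
        if math.isfinite(dlog) and math.log(rng.uniform()) < dlog:
            u *= c
            tau *= math.exp(-2.0 * eps)
            mu *= np.exp(d_eta)
            acc["scale"] += 1

        # --- recenter (sum-to-zero identification; eta and mu unchanged)
        m = u.mean()
        u -= m
        beta0 += m

        # --- CAR precision: conjugate gamma
        quad = float(u @ (lap @ u))
        tau = rng.gamma(a0 + 0.5 * rank, 1.0 / (b0 + 0.5 * quad))

        if not np.isfinite(mu).all():
            raise FloatingPointError(f"non-finite Poisson mean at iteration {it}")

        # --- adapt proposal scales during burn-in
        n_since_adapt += 1
        if it < mcmc.n_burn and n_since_adapt == mcmc.adapt_interval:
            tgt = mcmc.target_accept
            s_beta0 *= math.exp((acc["beta0"] / n_since_adapt - tgt))
            for j in range(p):
                s_beta[j] *= math.exp((acc["beta"][j] / n_since_adapt - tgt))
            if acc["u_total"]:
                s_u *= math.exp((acc["u"] / acc["u_total"] - tgt))
            if acc["joint_total"]:
                s_joint *= math.exp((acc["joint"] / acc["joint_total"] - 0.23))
            if acc["scale_total"]:
                s_scale *= math.exp((acc["scale"] / acc["scale_total"] - tgt))
            for j in range(p):
                if acc["conf_total"][j]:
                    s_conf[j] *= math.exp(
                        acc["conf"][j] / acc["conf_total"][j] - tgt
                    )
            acc = {"beta0": 0, "beta": np.zeros(p), "u": 0, "u_total": 0,
                   "joint": 0, "joint_total": 0, "scale": 0, "scale_total": 0,
                   "conf": np.zeros(p), "conf_total": np.zeros(p)}
            n_since_adapt = 0

        if it >= mcmc.n_burn and (it - mcmc.n_burn) % keep_every == 0 and k < mcmc.n_keep:
            draws_beta0[k] = beta0
            draws_beta[k] = beta
            draws_u[k] = u
            draws_sigma2[k] = 1.0 / tau
            k += 1

    rates = {
        "beta0": acc["beta0"] / max(n_since_adapt, 1),
        "u": acc["u"] / max(acc["u_total"], 1),
    }
    return draws_beta0, draws_beta, draws_u, draws_sigma2, rates


def fit_car_poisson(
    table: DistrictTable,
    graph: AdjacencyGraph,
    priors: ModelPriors | None = None,
    mcmc: McmcConfig | None = None,
) -> PosteriorSamples:
    """Fit the CAR Poisson model by Metropolis-within-Gibbs MCMC."""
    priors = priors or ModelPriors()
    mcmc = mcmc or McmcConfig()
    graph.require_connected()
    if graph.n != table.n:
        raise ValueError("adjacency graph and district table sizes differ")
    if table.E is None:
        raise ValueError("offsets E must be computed before fitting")
    X, scaling = build_design(table)
    Y = np.asarray(table.Y, dtype=float)
    E = np.asarray(table.E, dtype=float)
    if not (np.all(np.isfinite(E)) and np.all(np.isfinite(Y))
            and np.all(np.isfinite(X))):
        raise ValueError("Y, E and covariates must be finite to fit")

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    chains = [
        _run_chain(Y, E, X, graph, priors, mcmc, seed)
        for seed in seeds
    ]
    samples = PosteriorSamples(
        beta0=np.stack([c[0] for c in chains]),
        beta=np.stack([c[1] for c in chains]),
        u=np.stack([c[2] for c in chains]),
        sigma2_u=np.stack([c[3] for c in chains]),
        covariate_names=list(COVARIATES),
        scaling=scaling,
        accept_rates=chains[0][4],
    )
    samples._X = X  # type: ignore[attr-defined]
    samples._table = table  # type: ignore[attr-defined]
    return samples


def rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction for one scalar parameter.

    ``chains`` has shape (n_chains, n_draws). Each chain is split in half,
    and the classic Gelman-Rubin statistic is computed over the split
    chains. Finite-sample values below 1 are floored at 1.0, so identical
    chains return exactly 1.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("chains must be 2-D (n_chains, n_draws)")
    m, n = chains.shape
    if n < 4:
        raise ValueError("chains too short for split-Rhat (need >= 4 draws)")
    if m == 1 and n < 8:
        raise ValueError("a single short chain cannot support split-Rhat")
    half = n // 2
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m2, n2 = split.shape
    chain_means = split.mean(axis=1)
    chain_vars = split.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n2 * chain_means.var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else math.inf
    var_plus = (n2 - 1) / n2 * w + b / n2
    return max(1.0, math.sqrt(var_plus / w))


def rhat_summary(samples: PosteriorSamples) -> dict[str, float]:
    out = {"beta0": rhat(samples.beta0), "sigma2_u": rhat(samples.sigma2_u)}
    for j, name in enumerate(samples.covariate_names):
        out[f"beta[{name}]"] = rhat(samples.beta[:, :, j])
    return out


def posterior_incidence(
    samples: PosteriorSamples, table: DistrictTable
) -> np.ndarray:
    """Draws of smoothed annual incidence per 100,000, shape (draws, n)."""
    if table.E is None:
        raise ValueError("offsets E must be set")
    eta = samples.eta()
    return 1e5 * table.E * np.exp(eta) / (table.population * table.n_years)


def exceedance_probability(rate_draws: np.ndarray, threshold: float = 30.0) -> np.ndarray:
    """Per-district fraction of rate draws strictly above the threshold."""
    rate_draws = np.asarray(rate_draws)
    if rate_draws.shape[0] < 1:
        raise ValueError("need at least one retained draw")
    return (rate_draws > threshold).mean(axis=0)


def incidence_ratio_summary(samples: PosteriorSamples) -> pd.DataFrame:
    """Per-covariate incidence ratios with 95% credible intervals.

    Continuous covariates are reported per +1 SD in original units;
    fraction covariates per +100%-units.
    """
    beta = samples.flat("beta")
    rows = []
    for j, name in enumerate(samples.covariate_names):
        ir = np.exp(beta[:, j])
        rows.append(
            {
                "covariate": name,
                "unit": samples.scaling.natural_unit(name),
                "incidence_ratio": float(np.mean(ir)),
                "cri_low": float(np.percentile(ir, 2.5)),
                "cri_high": float(np.percentile(ir, 97.5)),
            }
        )
    return pd.DataFrame(rows)
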