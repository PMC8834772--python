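"""Bayesian autoregressive age-period-cohort (APC) Poisson model.

Registry counts ``y[a, p]`` with person-years ``n[a, p]`` are modelled as

    y[a, p] ~ Poisson(n[a, p] * lambda[a, p])
    log lambda[a, p] = mu + alpha_a + beta_p + gamma_c(a, p)

with age effects ``alpha`` (second-order random-walk prior: a smooth age
curve), period effects ``beta`` (first-order random walk with an explicit
drift, which carries the calendar trend forward in projections) and
birth-cohort effects ``gamma`` (first-order random walk, no drift).
Innovation standard deviations get half-normal hyperpriors; the intercept
and drift get diffuse normals.

Identifiability.  The lattice identity cohort = period - age makes one
linear trend unidentifiable.  The model fixes the allocation with hard
constraints: ``alpha``, ``beta`` and ``gamma`` each sum to zero, and
``gamma`` additionally has zero linear component, so the whole net drift
lives on the period axis.  Sampling happens directly in the constrained
subspace (orthonormal null-space bases), which removes the APC ridge.

Projection.  Future period and cohort effects are simulated per posterior
draw from their random-walk dynamics (drift plus innovation noise), so the
95% prediction intervals widen with the projection horizon.  Posterior
predictive counts are Poisson draws around rate x person-years.

Inference is ensemble MCMC (emcee), initialised at the posterior mode;
rank-normalised split R-hat and effective sample sizes are computed with
arviz, treating walkers as chains, and non-convergence is flagged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy import optimize

from .registry_data import AgeBand, CountTable, PopulationTable

__all__ = [
    "APCSpec",
    "APCDesign",
    "APCPosterior",
    "EffectCurve",
    "ProjectedCounts",
    "build_design",
    "fit_apc",
    "project_counts",
    "extract_relative_effects",
    "decompose_surface",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class APCSpec:
    """Model and sampler settings for one APC fit.

    Prior scales are on the log-rate scale: ``sigma_age_scale`` governs the
    half-normal prior on the SD of second differences of the age curve,
    ``sigma_period_scale`` the SD of annual period-effect innovations, and
    ``sigma_cohort_scale`` the SD of innovations per (5-year) cohort step.
    ``include_period`` / ``include_cohort`` clamp the corresponding effects
    to zero (used for oracle checks against pure age-rate estimates).
    """

    projection_years: tuple[int, int] | None = None
    cohort_grid: int = 5
    include_period: bool = True
    include_cohort: bool = True
    sigma_age_scale: float = 0.5
    sigma_period_scale: float = 0.05
    sigma_cohort_scale: float = 0.1
    intercept_sd: float = 10.0
    drift_sd: float = 1.0
    n_walkers: int | None = None
    n_burn: int = 4000
    n_steps: int = 4000
    thin: int = 10
    n_keep: int = 2000
    rhat_threshold: float = 1.01
    seed: int = 0


# ---------------------------------------------------------------------------
# Design: the (age, period, cohort) lattice and constrained bases
# ---------------------------------------------------------------------------

def _cohort_bucket(year: int, midpoint: float, grid: int) -> int:
    """Birth-cohort bucket (start year on the ``grid``-year grid) of a cell:
    cohort year = calendar year minus the band midpoint rounded down."""
    birth = year - int(midpoint)
    return grid * int(np.floor(birth / grid))


def _sum_zero_basis(k: int) -> np.ndarray:
    """Orthonormal basis of the sum-to-zero subspace of R^k, shape (k, k-1)."""
    from scipy.linalg import null_space

    return null_space(np.ones((1, k)))


def _sum_zero_detrended_basis(values: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the subspace orthogonal to {1, linear(values)}."""
    from scipy.linalg import null_space

    k = values.size
    constraints = np.vstack([np.ones(k), values - values.mean()])
    return null_space(constraints)


@dataclass(frozen=True)
class APCDesign:
    """Index maps and constrained bases for one band x year lattice."""

    bands: tuple[AgeBand, ...]
    observed_years: tuple[int, ...]
    projection_years: tuple[int, ...]
    midpoints: np.ndarray
    cohorts: tuple[int, ...]            # bucket start years, observed lattice
    cohorts_all: tuple[int, ...]        # including projection-only buckets
    a_idx: np.ndarray                   # flat observed-cell indices
    p_idx: np.ndarray
    k_idx: np.ndarray
    k_grid_all: np.ndarray              # (n_bands, n_years_all) cohort index
    Q_alpha: np.ndarray
    Q_beta: np.ndarray
    Q_gamma: np.ndarray

    @property
    def years_all(self) -> tuple[int, ...]:
        return self.observed_years + self.projection_years

    @property
    def n_cells(self) -> int:
        return self.a_idx.size

    def cohort_label(self, bucket: int) -> str:
        grid = self.cohorts[1] - self.cohorts[0] if len(self.cohorts) > 1 else 5
        return f"{bucket}-{bucket + grid - 1}"


def build_design(
    counts: CountTable, population: PopulationTable, spec: APCSpec
) -> APCDesign:
    """Build the APC lattice index maps for a count/population pair.

    Each cell ``(band, year)`` is assigned the cohort bucket of ``year``
    minus the band midpoint (floored), on the spec's cohort grid; the
    observed buckets must form a contiguous sequence.
    """
    if not counts.same_grid(population):
        raise ValueError("count and population tables are on different grids")
    bands = counts.bands
    observed_years = counts.years
    if spec.projection_years is not None:
        start, end = spec.projection_years
        if start != observed_years[-1] + 1:
            raise ValueError(
                f"projection years must start at {observed_years[-1] + 1}, "
                f"got {start}"
            )
        projection_years = tuple(range(start, end + 1))
    else:
        projection_years = ()

    grid = spec.cohort_grid
    mids = np.array([b.midpoint(open_width=grid) for b in bands])
    years_all = observed_years + projection_years

    bucket_grid = np.array(
        [[_cohort_bucket(y, m, grid) for y in years_all] for m in mids]
    )
    n_obs = len(observed_years)
    obs_buckets = np.unique(bucket_grid[:, :n_obs])
    if np.any(np.diff(obs_buckets) != grid):
        raise ValueError("cohort buckets on the observed lattice have gaps")
    all_buckets = np.unique(bucket_grid)
    if np.any(np.diff(all_buckets) != grid):
        raise ValueError("cohort buckets on the full lattice have gaps")
    if not set(obs_buckets) <= set(all_buckets[: len(obs_buckets)]):
        raise ValueError("projection introduced cohorts before the observed range")

    lookup = {b: i for i, b in enumerate(all_buckets)}
    k_grid_all = np.vectorize(lookup.get)(bucket_grid).astype(int)

    na, npod = len(bands), n_obs
    a_idx, p_idx = np.meshgrid(np.arange(na), np.arange(npod), indexing="ij")
    a_idx, p_idx = a_idx.ravel(), p_idx.ravel()
    k_idx = k_grid_all[:, :n_obs].ravel()

    nc = len(obs_buckets)
    Q_alpha = _sum_zero_basis(na)
    Q_beta = _sum_zero_basis(npod)
    Q_gamma = (
        _sum_zero_detrended_basis(obs_buckets.astype(float))
        if nc >= 3
        else np.zeros((nc, 0))
    )
    return APCDesign(
        bands=bands,
        observed_years=observed_years,
        projection_years=projection_years,
        midpoints=mids,
        cohorts=tuple(int(b) for b in obs_buckets),
        cohorts_all=tuple(int(b) for b in all_buckets),
        a_idx=a_idx,
        p_idx=p_idx,
        k_idx=k_idx,
        k_grid_all=k_grid_all,
        Q_alpha=Q_alpha,
        Q_beta=Q_beta,
        Q_gamma=Q_gamma,
    )


# ---------------------------------------------------------------------------
# Log posterior over the constrained parameter vector
# ---------------------------------------------------------------------------

class _Parameterization:
    """Slices of the flat parameter vector and the (vectorised) log posterior.

    The random-walk effects are parameterised non-centredly: the free
    coordinates are standardised innovations (iid standard normal a priori)
    which are scaled by the innovation SDs and integrated into effect
    vectors inside the density.  This removes the funnel between effects
    and their hyperparameters that cripples samplers in the centred form.

    theta = [mu, age_slope, e_alpha,
             (drift, e_beta, log sigma_beta)?,
             (e_gamma, log sigma_gamma)?, log sigma_alpha]

    with alpha = centre(double-integral of sigma_a * e_alpha, slope
    age_slope), b = centre(cumsum of sigma_b * e_beta), beta = drift *
    (p - p_mean) + b, gamma = detrend(centre(cumsum of sigma_g * e_gamma)).
    """

    def __init__(self, design: APCDesign, spec: APCSpec,
                 y: np.ndarray, log_n: np.ndarray):
        self.design = design
        self.spec = spec
        self.y = y
        self.log_n = log_n
        na = len(design.bands)
        npod = len(design.observed_years)
        nc = len(design.cohorts)
        self.na, self.npod, self.nc = na, npod, nc
        self.nea = max(na - 2, 0)
        self.neb = npod - 1 if spec.include_period else 0
        self.neg = max(nc - 1, 0) if spec.include_cohort else 0
        self.p_centered = np.arange(npod) - (npod - 1) / 2.0

        # projection onto {sum gamma = 0, linear trend of gamma = 0}
        c = np.asarray(design.cohorts, dtype=float)
        V = np.column_stack([np.ones(nc), c - c.mean()])
        self.P_gamma = np.eye(nc) - V @ np.linalg.solve(V.T @ V, V.T)

        idx = 0
        self.s_mu = idx; idx += 1
        self.s_slope = idx; idx += 1
        self.s_ea = slice(idx, idx + self.nea); idx += self.nea
        if spec.include_period:
            self.s_drift = idx; idx += 1
            self.s_eb = slice(idx, idx + self.neb); idx += self.neb
            self.s_lsb = idx; idx += 1
        if spec.include_cohort:
            self.s_eg = slice(idx, idx + self.neg); idx += self.neg
            self.s_lsg = idx; idx += 1
        self.s_lsa = idx; idx += 1
        self.ndim = idx

    # -- unpacking -----------------------------------------------------
    def effects(self, theta: np.ndarray):
        """Map (W, ndim) parameters to per-walker effect vectors."""
        theta = np.atleast_2d(theta)
        spec = self.spec
        W = theta.shape[0]
        mu = theta[:, self.s_mu]
        sa, sb, sg = self.sigmas(theta)

        # age: second differences sigma_a * e, explicit free slope, centred
        slope = theta[:, self.s_slope]
        d2 = sa[:, None] * theta[:, self.s_ea]
        alpha_raw = np.zeros((W, self.na))
        alpha_raw[:, 1] = slope
        curv = np.cumsum(np.cumsum(d2, axis=1), axis=1)
        alpha_raw[:, 2:] = (
            slope[:, None] * np.arange(2, self.na)[None, :] + curv
        )
        alpha = alpha_raw - alpha_raw.mean(axis=1, keepdims=True)

        if spec.include_period:
            drift = theta[:, self.s_drift]
            b_raw = np.concatenate(
                [np.zeros((W, 1)), np.cumsum(sb[:, None] * theta[:, self.s_eb], axis=1)],
                axis=1,
            )
            b = b_raw - b_raw.mean(axis=1, keepdims=True)
            beta = drift[:, None] * self.p_centered[None, :] + b
        else:
            drift = np.zeros(W)
            b = beta = np.zeros((W, self.npod))

        if spec.include_cohort and self.neg > 0:
            g_raw = np.concatenate(
                [np.zeros((W, 1)), np.cumsum(sg[:, None] * theta[:, self.s_eg], axis=1)],
                axis=1,
            )
            gamma = g_raw @ self.P_gamma.T
        else:
            gamma = np.zeros((W, self.nc))
        return mu, alpha, drift, b, beta, gamma

    def sigmas(self, theta: np.ndarray):
        theta = np.atleast_2d(theta)
        sa = np.exp(theta[:, self.s_lsa])
        sb = np.exp(theta[:, self.s_lsb]) if self.spec.include_period else None
        sg = np.exp(theta[:, self.s_lsg]) if self.spec.include_cohort else None
        return sa, sb, sg

    # -- density -------------------------------------------------------
    def log_posterior(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        d, spec = self.design, self.spec
        mu, alpha, drift, b, beta, gamma = self.effects(theta)
        sa, sb, sg = self.sigmas(theta)

        eta = (
            mu[:, None]
            + alpha[:, d.a_idx]
            + beta[:, d.p_idx]
            + gamma[:, d.k_idx]
            + self.log_n[None, :]
        )
        eta = np.clip(eta, -700, 700)
        lp = (self.y[None, :] * eta - np.exp(eta)).sum(axis=1)

        # standardised innovations ~ N(0, 1)
        lp += -0.5 * (theta[:, self.s_ea] ** 2).sum(axis=1)
        # half-normal hyperprior on sigma_alpha + log-sigma Jacobian
        lp += -0.5 * (sa / spec.sigma_age_scale) ** 2 + np.log(sa)
        # weakly informative prior on the free age slope
        lp += -0.5 * (theta[:, self.s_slope] / spec.intercept_sd) ** 2

        if spec.include_period:
            lp += -0.5 * (theta[:, self.s_eb] ** 2).sum(axis=1)
            lp += -0.5 * (sb / spec.sigma_period_scale) ** 2 + np.log(sb)
            lp += -0.5 * (drift / spec.drift_sd) ** 2
        if spec.include_cohort and self.neg > 0:
            lp += -0.5 * (theta[:, self.s_eg] ** 2).sum(axis=1)
            lp += -0.5 * (sg / spec.sigma_cohort_scale) ** 2 + np.log(sg)

        lp += -0.5 * (mu / spec.intercept_sd) ** 2
        return np.where(np.isfinite(lp), lp, -np.inf)

    def initial_point(self, y_total: float, n_total: float) -> np.ndarray:
        x0 = np.zeros(self.ndim)
        x0[self.s_mu] = np.log(max(y_total, 0.5) / n_total)
        x0[self.s_lsa] = np.log(self.spec.sigma_age_scale / 2)
        if self.spec.include_period:
            x0[self.s_lsb] = np.log(self.spec.sigma_period_scale / 2)
        if self.spec.include_cohort:
            x0[self.s_lsg] = np.log(self.spec.sigma_cohort_scale / 2)
        return x0

    def parameter_names(self) -> list[str]:
        names = ["mu", "age_slope"] + [f"e_alpha[{i}]" for i in range(self.nea)]
        if self.spec.include_period:
            names += ["drift"] + [f"e_beta[{i}]" for i in range(self.neb)]
            names += ["log_sigma_beta"]
        if self.spec.include_cohort:
            names += [f"e_gamma[{i}]" for i in range(self.neg)]
            names += ["log_sigma_gamma"]
        names += ["log_sigma_alpha"]
        return names


# ---------------------------------------------------------------------------
# Posterior container
# ---------------------------------------------------------------------------

@dataclass
class APCPosterior:
    """Posterior draws of an APC fit, including forward-simulated period and
    cohort effects over the projection range and posterior-predictive counts
    for the observed years."""

    design: APCDesign
    spec: APCSpec
    intercept_draws: np.ndarray          # (n_draws,)
    age_effect_draws: np.ndarray         # (n_draws, n_bands)
    period_effect_draws: np.ndarray      # (n_draws, n_years_all)
    cohort_effect_draws: np.ndarray      # (n_draws, n_cohorts_all)
    drift_draws: np.ndarray
    sigma_draws: dict[str, np.ndarray]
    rate_draws: np.ndarray               # (n_draws, n_bands, n_years_all)
    predictive_count_draws: np.ndarray   # (n_draws, n_bands, n_years_obs[+proj])
    diagnostics: dict[str, float | bool | dict]

    @property
    def n_draws(self) -> int:
        return self.intercept_draws.size

    def rate_summary(self, level: float = 0.95) -> pd.DataFrame:
        lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
        med = np.median(self.rate_draws, axis=0)
        lower = np.quantile(self.rate_draws, lo, axis=0)
        upper = np.quantile(self.rate_draws, hi, axis=0)
        rows = []
        for i, band in enumerate(self.design.bands):
            for j, year in enumerate(self.design.years_all):
                rows.append(
                    (band.label, year, med[i, j], lower[i, j], upper[i, j])
                )
        return pd.DataFrame(
            rows, columns=["age_band", "year", "rate", "lower95", "upper95"]
        )

    def draws_frame(self) -> pd.DataFrame:
        """Long-format export of the effect draws (parameter, index, draw,
        value)."""
        rows = []
        def emit(name, labels, mat):
            for j, lab in enumerate(labels):
                for t in range(mat.shape[0]):
                    rows.append((name, str(lab), t, mat[t, j]))
        emit("mu", ["-"], self.intercept_draws[:, None])
        emit("alpha", [b.label for b in self.design.bands], self.age_effect_draws)
        emit("beta", list(self.design.years_all), self.period_effect_draws)
        emit("gamma", list(self.design.cohorts_all), self.cohort_effect_draws)
        return pd.DataFrame(rows, columns=["parameter", "index", "draw", "value"])


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_apc(
    counts: CountTable,
    population: PopulationTable,
    spec: APCSpec,
    population_future: PopulationTable | None = None,
) -> APCPosterior:
    """Fit the Bayesian APC model by ensemble MCMC and forward-simulate the
    projection range.

    Requires at least 3 age bands and 8 observed years and at least one
    observed event.  The sampler is initialised at the posterior mode and is
    reproducible draw-for-draw for a fixed ``spec.seed``.  If
    ``population_future`` is given (projection bands x years), posterior-
    predictive count draws cover observed and projected years; otherwise
    observed years only.
    """
    design = build_design(counts, population, spec)
    if len(design.bands) < 3:
        raise ValueError("APC fit requires at least 3 age bands")
    if len(design.observed_years) < 8:
        raise ValueError("APC fit requires at least 8 observed years")
    y = counts.counts.ravel()
    if y.sum() == 0:
        raise ValueError("all counts are zero; nothing to fit")
    n = population.persons.ravel()
    par = _Parameterization(design, spec, y, np.log(n))

    ss = np.random.SeedSequence(spec.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4)]

    # posterior mode for initialisation
    x0 = par.initial_point(y.sum(), n.sum())
    res = optimize.minimize(
        lambda t: -float(par.log_posterior(t)[0]),
        x0,
        method="L-BFGS-B",
        options={"maxiter": 1000, "maxfun": 200_000},
    )
    x_map = res.x if np.isfinite(res.fun) else x0

    ndim = par.ndim
    n_walkers = spec.n_walkers or max(2 * ndim + 2, 64)
    n_walkers += n_walkers % 2
    rng_init = np.random.default_rng(seeds[0])
    p0 = x_map[None, :] + 0.01 * rng_init.standard_normal((n_walkers, ndim))

    sampler = emcee.EnsembleSampler(
        n_walkers,
        ndim,
        par.log_posterior,
        vectorize=True,
        moves=[
            (emcee.moves.DEMove(), 0.8),
            (emcee.moves.DESnookerMove(), 0.2),
        ],
    )
    state = emcee.State(p0, random_state=np.random.RandomState(seeds[1]).get_state())
    sampler.run_mcmc(state, spec.n_burn + spec.n_steps, progress=False)
    chain = sampler.get_chain(discard=spec.n_burn, thin=spec.thin)  # (T, W, ndim)

    diagnostics = _diagnostics(chain, par, spec)
    if not diagnostics["converged"]:
        warnings.warn(
            "APC MCMC convergence flag raised: max rank-normalised R-hat "
            f"{diagnostics['max_rhat']:.3f} exceeds {spec.rhat_threshold}",
            stacklevel=2,
        )
        logger.warning("APC fit convergence flag: %s", diagnostics)

    flat = chain.reshape(-1, ndim)
    rng_sel = np.random.default_rng(seeds[2])
    if flat.shape[0] > spec.n_keep:
        sel = rng_sel.choice(flat.shape[0], size=spec.n_keep, replace=False)
        sel.sort()
        flat = flat[sel]

    mu, alpha, drift, b, beta_obs, gamma_obs = par.effects(flat)
    mu = mu.ravel()
    sa, sb, sg = par.sigmas(flat)

    rng_fwd = np.random.default_rng(seeds[3])
    beta_all, gamma_all = _simulate_forward(
        design, spec, drift, b, beta_obs, gamma_obs, sb, sg, rng_fwd, par
    )

    log_rate = (
        mu[:, None, None]
        + alpha[:, :, None]
        + beta_all[:, None, :]
        + gamma_all[:, design.k_grid_all]
    )
    rate_draws = np.exp(np.clip(log_rate, -700, 700))

    n_obs_years = len(design.observed_years)
    mean_obs = rate_draws[:, :, :n_obs_years] * population.persons[None, :, :]
    pred = rng_fwd.poisson(mean_obs).astype(np.int64)
    if population_future is not None and design.projection_years:
        _check_future_population(design, population_future)
        mean_fut = (
            rate_draws[:, :, n_obs_years:] * population_future.persons[None, :, :]
        )
        pred = np.concatenate(
            [pred, rng_fwd.poisson(mean_fut).astype(np.int64)], axis=2
        )

    sigma_draws = {"sigma_age": sa}
    if sb is not None:
        sigma_draws["sigma_period"] = sb
    if sg is not None:
        sigma_draws["sigma_cohort"] = sg

    return APCPosterior(
        design=design,
        spec=spec,
        intercept_draws=mu,
        age_effect_draws=alpha,
        period_effect_draws=beta_all,
        cohort_effect_draws=gamma_all,
        drift_draws=drift.ravel(),
        sigma_draws=sigma_draws,
        rate_draws=rate_draws,
        predictive_count_draws=pred,
        diagnostics=diagnostics,
    )


def _diagnostics(chain: np.ndarray, par: _Parameterization, spec: APCSpec) -> dict:
    # arviz expects (chain, draw); emcee walkers serve as chains
    data = {
        name: chain[:, :, i].T for i, name in enumerate(par.parameter_names())
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.convert_to_dataset(data)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    max_rhat = float(max(rhat[v].values.max() for v in rhat.data_vars))
    min_ess = float(min(ess[v].values.min() for v in ess.data_vars))
    return {
        "max_rhat": max_rhat,
        "min_ess": min_ess,
        "converged": bool(max_rhat <= spec.rhat_threshold),
        "n_parameters": par.ndim,
    }


def _simulate_forward(design, spec, drift, b, beta_obs, gamma_obs, sb, sg, rng, par):
    """Forward-simulate period and cohort random walks over the projection
    range, per draw."""
    n_draws = beta_obs.shape[0]
    n_proj = len(design.projection_years)
    if n_proj == 0:
        return beta_obs, gamma_obs
    # period: RW1 with drift continued from the last observed deviation
    steps = rng.standard_normal((n_draws, n_proj)) * (
        sb[:, None] if sb is not None else 0.0
    )
    b_future = b[:, -1][:, None] + np.cumsum(steps, axis=1)
    p_future = par.p_centered[-1] + np.arange(1, n_proj + 1)
    beta_future = drift[:, None] * p_future[None, :] + b_future
    beta_all = np.concatenate([beta_obs, beta_future], axis=1)

    n_new = len(design.cohorts_all) - len(design.cohorts)
    if n_new > 0:
        steps_g = rng.standard_normal((n_draws, n_new)) * (
            sg[:, None] if sg is not None else 0.0
        )
        gamma_future = gamma_obs[:, -1][:, None] + np.cumsum(steps_g, axis=1)
        gamma_all = np.concatenate([gamma_obs, gamma_future], axis=1)
    else:
        gamma_all = gamma_obs
    return beta_all, gamma_all


def _check_future_population(design: APCDesign, population_future: PopulationTable):
    if population_future.bands != design.bands:
        raise ValueError("future population bands do not match the model grid")
    if tuple(population_future.years) != design.projection_years:
        raise ValueError(
            "future population years must equal the projection years "
            f"{design.projection_years[0]}-{design.projection_years[-1]}"
        )


# ---------------------------------------------------------------------------
# Projection summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProjectedCounts:
    """Per-cell posterior-predictive median and central interval of projected
    counts."""

    bands: tuple[AgeBand, ...]
    years: tuple[int, ...]
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    mean: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, band in enumerate(self.bands):
            for j, year in enumerate(self.years):
                rows.append(
                    (
                        band.label,
                        year,
                        self.median[i, j],
                        self.lower[i, j],
                        self.upper[i, j],
                        self.mean[i, j],
                    )
                )
        return pd.DataFrame(
            rows,
            columns=["age_band", "year", "median", "lower95", "upper95", "mean"],
        )


def project_counts(
    posterior: APCPosterior,
    population_future: PopulationTable | np.ndarray,
    level: float = 0.95,
) -> ProjectedCounts:
    """Posterior-predictive projected counts per (band, year).

    Counts are Poisson draws around per-draw rate x future person-years;
    the central ``level`` interval therefore includes both parameter and
    sampling (Poisson) uncertainty.  ``population_future`` is a
    :class:`PopulationTable` on the projection grid, or a raw array of
    person-years (bands x projection years; zeros allowed, giving zero
    counts).
    """
    design = posterior.design
    if not design.projection_years:
        raise ValueError("posterior has no projection years")
    if isinstance(population_future, PopulationTable):
        _check_future_population(design, population_future)
        persons = population_future.persons
    else:
        persons = np.asarray(population_future, dtype=float)
        expected = (len(design.bands), len(design.projection_years))
        if persons.shape != expected:
            raise ValueError(
                f"future person-years shape {persons.shape} != {expected}"
            )
        if np.any(persons < 0) or np.any(~np.isfinite(persons)):
            raise ValueError("future person-years must be finite and >= 0")

    n_obs = len(design.observed_years)
    mean_draws = posterior.rate_draws[:, :, n_obs:] * persons[None, :, :]
    seed = int(
        np.random.SeedSequence([posterior.spec.seed, 777]).generate_state(1)[0]
        % (2**31 - 1)
    )
    rng = np.random.default_rng(seed)
    count_draws = rng.poisson(mean_draws)
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    return ProjectedCounts(
        bands=design.bands,
        years=design.projection_years,
        median=np.median(count_draws, axis=0),
        lower=np.quantile(count_draws, lo, axis=0),
        upper=np.quantile(count_draws, hi, axis=0),
        level=level,
        mean=mean_draws.mean(axis=0),
    )


# ---------------------------------------------------------------------------
# Relative-risk curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectCurve:
    """Relative-risk curve along the cohort or period axis, relative to the
    average of rates across the observed labels."""

    axis: Literal["cohort", "period"]
    labels: tuple[str, ...]
    relative_risk: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    observed_mask: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": list(self.labels),
                "relative_risk": self.relative_risk,
                "lower95": self.lower95,
                "upper95": self.upper95,
                "observed": self.observed_mask,
            }
        )


def extract_relative_effects(
    posterior: APCPosterior, axis: Literal["cohort", "period"]
) -> EffectCurve:
    """Relative risks along one APC axis.

    Per draw, RR = exp(effect - mean effect over observed labels); the
    summarised median curve is renormalised so its geometric mean over the
    observed labels is exactly 1.
    """
    design = posterior.design
    if axis == "period":
        draws = posterior.period_effect_draws
        labels = tuple(str(y) for y in design.years_all)
        n_observed = len(design.observed_years)
    elif axis == "cohort":
        draws = posterior.cohort_effect_draws
        labels = tuple(design.cohort_label(c) for c in design.cohorts_all)
        n_observed = len(design.cohorts)
    else:
        raise ValueError(f"axis must be 'cohort' or 'period', got {axis!r}")

    centered = draws - draws[:, :n_observed].mean(axis=1, keepdims=True)
    rr = np.exp(centered)
    median = np.median(rr, axis=0)
    lower = np.quantile(rr, 0.025, axis=0)
    upper = np.quantile(rr, 0.975, axis=0)
    gm = np.exp(np.mean(np.log(median[:n_observed])))
    mask = np.zeros(len(labels), dtype=bool)
    mask[:n_observed] = True
    return EffectCurve(
        axis=axis,
        labels=labels,
        relative_risk=median / gm,
        lower95=lower / gm,
        upper95=upper / gm,
        observed_mask=mask,
    )


# ---------------------------------------------------------------------------
# Constrained decomposition of a known log-rate surface
# ---------------------------------------------------------------------------

def decompose_surface(
    log_rate: np.ndarray,
    bands: Sequence[AgeBand],
    years: Sequence[int],
    cohort_grid: int = 5,
):
    """Project a log-rate surface onto the model's constrained APC
    parameterisation (least squares over the lattice).

    Returns ``(mu, alpha, beta, gamma, cohort_buckets)`` with the same
    identifiability convention as :func:`fit_apc` (all effects sum to zero,
    gamma linearly detrended, drift on the period axis).  Used to express a
    known simulation truth in the model's coordinates, and to check that
    equivalent reparameterisations of a surface yield identical constrained
    effects.
    """
    bands = tuple(bands)
    years = tuple(int(y) for y in years)
    log_rate = np.asarray(log_rate, dtype=float)
    if log_rate.shape != (len(bands), len(years)):
        raise ValueError("surface shape does not match bands x years")
    mids = np.array([b.midpoint(open_width=cohort_grid) for b in bands])
    buckets = np.array(
        [[_cohort_bucket(y, m, cohort_grid) for y in years] for m in mids]
    )
    all_b = np.unique(buckets)
    lookup = {b: i for i, b in enumerate(all_b)}
    k_grid = np.vectorize(lookup.get)(buckets).astype(int)

    na, npod, nc = len(bands), len(years), len(all_b)
    Qa = _sum_zero_basis(na)
    Qb = _sum_zero_basis(npod)
    Qg = _sum_zero_detrended_basis(all_b.astype(float)) if nc >= 3 else np.zeros((nc, 0))

    a_idx, p_idx = np.meshgrid(np.arange(na), np.arange(npod), indexing="ij")
    a_idx, p_idx = a_idx.ravel(), p_idx.ravel()
    k_idx = k_grid.ravel()
    X = np.hstack(
        [
            np.ones((a_idx.size, 1)),
            Qa[a_idx],
            Qb[p_idx],
            Qg[k_idx] if Qg.shape[1] else np.zeros((a_idx.size, 0)),
        ]
    )
    coef, *_ = np.linalg.lstsq(X, log_rate.ravel(), rcond=None)
    mu = coef[0]
    alpha = Qa @ coef[1 : 1 + Qa.shape[1]]
    beta = Qb @ coef[1 + Qa.shape[1] : 1 + Qa.shape[1] + Qb.shape[1]]
    gamma = Qg @ coef[1 + Qa.shape[1] + Qb.shape[1] :] if Qg.shape[1] else np.zeros(nc)
    return mu, alpha, beta, gamma, tuple(int(b) for b in all_b)
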