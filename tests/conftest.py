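"""Shared fixtures: small registry tables and (session-scoped) MCMC fits.

The fits are deliberately reduced in grid size and chain length so the whole
suite runs in a few minutes on one CPU; they are shared across test modules
to avoid refitting.
"""

import dataclasses
import warnings

import numpy as np
import pytest

import ocburden as ob
from ocburden.apc_model import APCSpec


@pytest.fixture()
def small_counts():
    bands = tuple(ob.parse_band_label(s) for s in ("45-49", "50-54", "55-59"))
    return ob.CountTable(
        bands=bands,
        years=(2000, 2001, 2002),
        values=np.array([[1.0, 2, 3], [4, 5, 6], [7, 8, 9]]),
    )


@pytest.fixture()
def small_population(small_counts):
    return ob.PopulationTable(
        bands=small_counts.bands,
        years=small_counts.years,
        values=np.full((3, 3), 1e4),
    )


@pytest.fixture(scope="session")
def scenario():
    return ob.catalonia_like_scenario()


@pytest.fixture(scope="session")
def scenario_truth(scenario):
    return ob.generate_truth(scenario)


@pytest.fixture(scope="session")
def small_scenario(scenario):
    """5-band, 2000-2017 variant (observed through 2011) for cheap fits."""
    return dataclasses.replace(
        scenario,
        band_labels=scenario.band_labels[:5],
        age_curve=scenario.age_curve[:5],
        base_population=scenario.base_population[:5],
        years=(2000, 2017),
        observed_through=2011,
    )


def _quiet_fit(counts, population, spec, population_future=None):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ob.fit_apc(counts, population, spec, population_future=population_future)


@pytest.fixture(scope="session")
def flat_fit():
    """Full APC model fitted to constant-rate data with large person-years."""
    bands = tuple(ob.parse_band_label(s) for s in ("45-49", "50-54", "55-59"))
    years = tuple(range(2000, 2012))
    persons = np.full((3, 12), 5e5)
    pop = ob.PopulationTable(bands=bands, years=years, values=persons)
    rng = np.random.default_rng(42)
    counts = ob.CountTable(
        bands=bands, years=years, values=rng.poisson(20e-5 * persons).astype(float)
    )
    spec = APCSpec(n_burn=2000, n_steps=2000, thin=10, seed=7)
    post = _quiet_fit(counts, pop, spec)
    return counts, pop, post


@pytest.fixture(scope="session")
def age_only_fit():
    """Period and cohort effects clamped to zero: a pure age-rate model."""
    bands = tuple(ob.parse_band_label(s) for s in ("45-49", "50-54", "55-59"))
    years = tuple(range(2000, 2010))
    persons = np.full((3, 10), 5e5)
    pop = ob.PopulationTable(bands=bands, years=years, values=persons)
    rng = np.random.default_rng(11)
    rates = np.array([10e-5, 20e-5, 40e-5])[:, None]
    counts = ob.CountTable(
        bands=bands, years=years, values=rng.poisson(rates * persons).astype(float)
    )
    spec = APCSpec(
        include_period=False, include_cohort=False,
        n_burn=1200, n_steps=1200, thin=6, seed=9,
    )
    post = _quiet_fit(counts, pop, spec)
    return counts, pop, post


@pytest.fixture(scope="session")
def scenario_fit(scenario_truth):
    """Reduced-chain fit of the full 9-band scenario, observed 1994-2017,
    projected 2018-2030, with the true future person-years attached."""
    truth = scenario_truth
    pop_obs = truth.population_observed()
    cols = [truth.years.index(y) for y in pop_obs.years]
    counts = ob.sample_counts(truth.rates[:, cols], pop_obs, seed=77)
    spec = APCSpec(
        projection_years=(2018, 2030), n_burn=2000, n_steps=2000, thin=10, seed=3
    )
    post = _quiet_fit(
        counts, pop_obs, spec, population_future=truth.population_projection()
    )
    return counts, pop_obs, post


@pytest.fixture(scope="session")
def bump_fit(scenario_truth):
    """Fit with the full 1994-2030 range treated as observed, so the 1980s
    cohort bump lies inside the fitted cohort range."""
    truth = scenario_truth
    pop_all = truth.population
    counts = ob.sample_counts(truth.rates, pop_all, seed=99)
    spec = APCSpec(n_burn=2000, n_steps=2000, thin=10, seed=13)
    post = _quiet_fit(counts, pop_all, spec)
    return counts, pop_all, post
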