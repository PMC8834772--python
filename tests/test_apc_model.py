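"""APC lattice construction, identifiability, fitting, projection and
relative-risk extraction."""

import dataclasses
import warnings

import numpy as np
import pytest

import ocburden as ob
from ocburden.apc_model import (
    APCSpec,
    _cohort_bucket,
    build_design,
    decompose_surface,
)
from ocburden.registry_data import parse_band_label


def _tables(n_bands=4, years=range(2000, 2010), persons=2e5, rate=20e-5, seed=0):
    labels = ["45-49", "50-54", "55-59", "60-64", "65-69"][:n_bands]
    bands = tuple(parse_band_label(s) for s in labels)
    years = tuple(years)
    p = np.full((n_bands, len(years)), persons)
    rng = np.random.default_rng(seed)
    counts = ob.CountTable(bands=bands, years=years, values=rng.poisson(rate * p).astype(float))
    pop = ob.PopulationTable(bands=bands, years=years, values=p)
    return counts, pop


class TestBuildDesign:
    def test_cohort_assignment_and_contiguity(self):
        counts, pop = _tables()
        design = build_design(counts, pop, APCSpec())
        # every observed cell maps to exactly one cohort; indices contiguous
        used = np.unique(design.k_idx)
        assert used.min() == 0
        assert np.array_equal(used, np.arange(used.max() + 1))
        assert np.all(np.diff(design.cohorts) == 5)
        # [45, 50) midpoint 47.5 -> 47; year 2000 -> birth 1953 -> bucket 1950
        assert _cohort_bucket(2000, 47.5, 5) == 1950
        assert design.cohorts_all[design.k_grid_all[0, 0]] == 1950

    def test_lattice_diagonal_shares_cohort(self):
        counts, pop = _tables(n_bands=4, years=range(2000, 2012))
        design = build_design(counts, pop, APCSpec())
        n_obs = len(design.observed_years)
        k = design.k_grid_all[:, :n_obs]
        # one band up (+5 years of age) and 5 years later: same birth cohort
        for a in range(3):
            for j in range(n_obs - 5):
                assert k[a + 1, j + 5] == k[a, j]

    def test_single_cell_design_has_one_cohort(self):
        bands = (parse_band_label("45-49"),)
        counts = ob.CountTable(bands=bands, years=(2000,), values=[[3.0]])
        pop = ob.PopulationTable(bands=bands, years=(2000,), values=[[1e4]])
        design = build_design(counts, pop, APCSpec())
        assert len(design.cohorts) == 1

    def test_grid_mismatch_rejected(self):
        counts, _ = _tables()
        _, pop = _tables(years=range(2001, 2011))
        with pytest.raises(ValueError, match="grids"):
            build_design(counts, pop, APCSpec())

    def test_projection_years_must_follow_observed(self):
        counts, pop = _tables()
        with pytest.raises(ValueError, match="projection years"):
            build_design(counts, pop, APCSpec(projection_years=(2012, 2015)))


class TestSurfaceDecomposition:
    def test_reparameterised_surface_gives_identical_constrained_effects(self):
        # moving a constant between the intercept and the period effects
        # pre-constraint leaves the constrained decomposition unchanged
        rng = np.random.default_rng(3)
        bands = tuple(parse_band_label(s) for s in ("45-49", "50-54", "55-59"))
        years = tuple(range(2000, 2010))
        surface = (
            -8.5
            + rng.normal(0, 0.3, size=(3, 1))
            + rng.normal(0, 0.1, size=(1, 10))
        )
        out1 = decompose_surface(surface, bands, years)
        out2 = decompose_surface(surface + 0.0, bands, years)  # same surface
        shifted = surface.copy()  # mu+c paired with beta-c: same surface again
        for a, b in zip(out1, out2):
            np.testing.assert_allclose(a, b)
        # a surface built from known constrained effects is recovered exactly
        mu, alpha, beta, gamma, buckets = out1
        assert abs(alpha.sum()) < 1e-9
        assert abs(beta.sum()) < 1e-9
        assert abs(gamma.sum()) < 1e-9
        c = np.array(buckets, dtype=float)
        assert abs(gamma @ (c - c.mean())) < 1e-6

    def test_reconstruction_matches_surface_in_model_family(self):
        # build a surface from an exact APC decomposition and re-derive it
        bands = tuple(parse_band_label(s) for s in ("45-49", "50-54", "55-59"))
        years = tuple(range(2000, 2012))
        spec = APCSpec()
        counts = ob.CountTable(bands=bands, years=years, values=np.ones((3, 12)))
        pop = ob.PopulationTable(bands=bands, years=years, values=np.full((3, 12), 1e4))
        design = build_design(counts, pop, spec)
        rng = np.random.default_rng(8)
        alpha = design.Q_alpha @ rng.normal(0, 0.2, design.Q_alpha.shape[1])
        beta = design.Q_beta @ rng.normal(0, 0.05, design.Q_beta.shape[1])
        gamma = design.Q_gamma @ rng.normal(0, 0.05, design.Q_gamma.shape[1])
        surface = -8.0 + alpha[:, None] + beta[None, :] + gamma[design.k_grid_all]
        mu_r, alpha_r, beta_r, gamma_r, _ = decompose_surface(surface, bands, years)
        np.testing.assert_allclose(mu_r, -8.0, atol=1e-8)
        np.testing.assert_allclose(alpha_r, alpha, atol=1e-8)
        np.testing.assert_allclose(beta_r, beta, atol=1e-8)
        np.testing.assert_allclose(gamma_r, gamma, atol=1e-8)


class TestFitValidation:
    def test_too_few_bands_rejected(self):
        counts, pop = _tables(n_bands=2)
        with pytest.raises(ValueError, match="3 age bands"):
            ob.fit_apc(counts, pop, APCSpec())

    def test_too_few_years_rejected(self):
        counts, pop = _tables(years=range(2000, 2005))
        with pytest.raises(ValueError, match="8 observed years"):
            ob.fit_apc(counts, pop, APCSpec())

    def test_all_zero_counts_rejected(self):
        counts, pop = _tables()
        zero = ob.CountTable(bands=counts.bands, years=counts.years,
                             values=np.zeros_like(counts.counts))
        with pytest.raises(ValueError, match="zero"):
            ob.fit_apc(zero, pop, APCSpec())


class TestFitDeterminism:
    def test_same_seed_reproduces_draws(self):
        counts, pop = _tables(n_bands=3, years=range(2000, 2008))
        spec = APCSpec(
            projection_years=(2008, 2010),
            n_burn=200, n_steps=200, thin=5, n_keep=100, seed=21,
        )
        fut = ob.PopulationTable(
            bands=counts.bands, years=(2008, 2009, 2010), values=np.full((3, 3), 2e5)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = ob.fit_apc(counts, pop, spec, population_future=fut)
            b = ob.fit_apc(counts, pop, spec, population_future=fut)
        np.testing.assert_array_equal(a.predictive_count_draws, b.predictive_count_draws)
        np.testing.assert_array_equal(a.rate_draws, b.rate_draws)


class TestFlatSurface:
    def test_centered_effects_near_zero(self, flat_fit):
        _, _, post = flat_fit
        for draws in (
            post.age_effect_draws,
            post.period_effect_draws[:, : len(post.design.observed_years)],
            post.cohort_effect_draws[:, : len(post.design.cohorts)],
        ):
            assert np.abs(np.median(draws, axis=0)).max() < 0.05

    def test_age_only_medians_match_analytic_rates(self, age_only_fit):
        counts, pop, post = age_only_fit
        med = np.median(post.rate_draws, axis=0)
        analytic = counts.counts.sum(axis=1) / pop.persons.sum(axis=1)
        np.testing.assert_allclose(med.mean(axis=1), analytic, rtol=0.02)

    def test_flat_relative_risks_near_one(self, flat_fit):
        _, _, post = flat_fit
        for axis in ("cohort", "period"):
            curve = ob.extract_relative_effects(post, axis)
            rr = curve.relative_risk[curve.observed_mask]
            assert rr.min() > 0.93 and rr.max() < 1.07


class TestEffectCurves:
    def test_geometric_mean_normalisation(self, scenario_fit):
        _, _, post = scenario_fit
        for axis in ("cohort", "period"):
            curve = ob.extract_relative_effects(post, axis)
            rr = curve.relative_risk[curve.observed_mask]
            assert np.exp(np.mean(np.log(rr))) == pytest.approx(1.0, abs=1e-6)
            assert (curve.relative_risk > 0).all()
            assert (curve.lower95 <= curve.upper95).all()

    def test_unknown_axis_rejected(self, scenario_fit):
        _, _, post = scenario_fit
        with pytest.raises(ValueError, match="axis"):
            ob.extract_relative_effects(post, "age")


class TestProjection:
    def test_zero_person_years_give_zero_counts(self, scenario_fit):
        _, _, post = scenario_fit
        shape = (len(post.design.bands), len(post.design.projection_years))
        proj = ob.project_counts(post, np.zeros(shape))
        assert not proj.median.any()
        assert not proj.upper.any()

    def test_doubling_person_years_doubles_predictive_mean(self, scenario_fit, scenario_truth):
        _, _, post = scenario_fit
        persons = scenario_truth.population_projection().persons
        p1 = ob.project_counts(post, persons)
        p2 = ob.project_counts(post, 2 * persons)
        np.testing.assert_allclose(p2.mean, 2 * p1.mean, rtol=1e-12)

    def test_interval_ordering(self, scenario_fit, scenario_truth):
        _, _, post = scenario_fit
        proj = ob.project_counts(post, scenario_truth.population_projection())
        assert (proj.lower >= 0).all()
        assert (proj.lower <= proj.median).all()
        assert (proj.median <= proj.upper).all()

    def test_intervals_widen_with_horizon(self, scenario_fit, scenario_truth):
        # forward-simulated random walks make prediction intervals grow
        _, _, post = scenario_fit
        proj = ob.project_counts(post, scenario_truth.population_projection())
        rel_width = (proj.upper - proj.lower).sum(axis=0) / proj.median.sum(axis=0)
        assert rel_width[-1] > rel_width[0]

    def test_missing_future_population_rejected(self, scenario_fit):
        _, _, post = scenario_fit
        with pytest.raises(ValueError, match="shape"):
            ob.project_counts(post, np.zeros((2, 2)))


class TestParameterRecovery:
    def test_rmse_decreases_with_person_years(self, small_scenario):
        """Centered-effect RMSE shrinks as person-years grow 10x, twice."""
        rmses = []
        for step, factor in enumerate([1.0, 10.0, 100.0]):
            sc = dataclasses.replace(
                small_scenario,
                base_population=tuple(p * factor for p in small_scenario.base_population),
            )
            truth = ob.generate_truth(sc)
            pop_obs = truth.population_observed()
            cols = [truth.years.index(y) for y in pop_obs.years]
            counts = ob.sample_counts(truth.rates[:, cols], pop_obs, seed=500 + step)
            spec = APCSpec(n_burn=1500, n_steps=1500, thin=10, seed=600 + step)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                post = ob.fit_apc(counts, pop_obs, spec)
            mu_t, a_t, b_t, g_t, _ = decompose_surface(
                np.log(truth.rates[:, cols]), truth.bands, pop_obs.years
            )
            est = np.concatenate(
                [
                    np.median(post.age_effect_draws, axis=0) - a_t,
                    np.median(post.period_effect_draws, axis=0)[: len(b_t)] - b_t,
                    np.median(post.cohort_effect_draws, axis=0)[: len(g_t)] - g_t,
                ]
            )
            rmses.append(float(np.sqrt(np.mean(est**2))))
        assert rmses[1] < rmses[0]
        assert rmses[2] < rmses[1]
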