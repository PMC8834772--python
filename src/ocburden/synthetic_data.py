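"""Synthetic registry-like datasets with known APC structure.

Every other module is testable without external data: the generator emits a
noiseless rate surface built from a configured age curve, log-linear period
and cohort drifts and an optional Gaussian-shaped cohort "bump" (a localized
generational excess risk), a demography with growth and gradual aging, and
Poisson-sampled count tables.  The bundled Catalonia-like scenario emulates
a registry series for a declining gynaecological cancer: 9 five-year bands
from 45-49 to 85+, annual years 1994-2030 (observed through 2017), falling
period and cohort trends and a rebound for cohorts born in the early 1980s.

The true log-rate surface is

    log lambda[a, p] = mu0 + age_curve[a]
                       + period_drift * (p - p0)
                       + cohort_drift * (c - c_ref) + bump(c)

where ``c`` is the birth-cohort bucket of the cell on the model's 5-year
cohort grid, so the truth lies exactly in the APC model family and the
"true" constrained effects are well defined (via the same least-squares
projection the model uses for its identifiability convention).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import yaml

from .apc_model import _cohort_bucket, decompose_surface
from .registry_data import AgeBand, CountTable, PopulationTable, parse_band_label

__all__ = [
    "ScenarioConfig",
    "SyntheticTruth",
    "generate_truth",
    "sample_counts",
    "catalonia_like_scenario",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Generating parameters of one synthetic registry scenario.

    ``age_curve`` is the log rate (per person-year) per band at the first
    year for the reference cohort; ``period_drift`` and ``cohort_drift`` are
    log-linear changes per calendar year and per birth year; ``cohort_bump``
    is ``(center_birth_year, width_years, log_rr_amplitude)`` or ``None``;
    ``base_population`` is person-years per band in the first year;
    ``population_growth`` an annual multiplicative factor; ``aging_shift``
    an annual multiplicative tilt moving person-years toward older bands.
    """

    band_labels: tuple[str, ...]
    age_curve: tuple[float, ...]
    period_drift: float
    cohort_drift: float
    cohort_bump: tuple[float, float, float] | None
    base_population: tuple[float, ...]
    population_growth: float
    aging_shift: float
    years: tuple[int, int]
    observed_through: int
    seed: int = 12345
    cohort_grid: int = 5

    def __post_init__(self) -> None:
        if len(self.age_curve) != len(self.band_labels):
            raise ValueError("age_curve must have one entry per band")
        if len(self.base_population) != len(self.band_labels):
            raise ValueError("base_population must have one entry per band")
        if any(p <= 0 for p in self.base_population):
            raise ValueError("base person-years must be positive")
        if self.population_growth <= 0 or self.aging_shift <= 0:
            raise ValueError("population factors must be positive")
        if not all(np.isfinite(self.age_curve)):
            raise ValueError("age curve log-rates must be finite")
        y0, y1 = self.years
        if y1 < y0:
            raise ValueError("year range is empty")
        if not (y0 <= self.observed_through <= y1):
            raise ValueError("observed_through must lie inside the year range")
        if self.cohort_bump is not None and len(self.cohort_bump) != 3:
            raise ValueError("cohort_bump must be (center, width, amplitude)")

    @property
    def bands(self) -> tuple[AgeBand, ...]:
        return tuple(parse_band_label(s) for s in self.band_labels)

    @property
    def all_years(self) -> tuple[int, ...]:
        return tuple(range(self.years[0], self.years[1] + 1))

    @property
    def observed_years(self) -> tuple[int, ...]:
        return tuple(range(self.years[0], self.observed_through + 1))

    @property
    def projection_years(self) -> tuple[int, ...]:
        return tuple(range(self.observed_through + 1, self.years[1] + 1))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_curve"] = [float(v) for v in self.age_curve]
        d["base_population"] = [float(v) for v in self.base_population]
        d["band_labels"] = list(self.band_labels)
        d["years"] = [int(y) for y in self.years]
        d["cohort_bump"] = (
            [float(v) for v in self.cohort_bump] if self.cohort_bump else None
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for key in ("band_labels", "age_curve", "base_population"):
            d[key] = tuple(d[key])
        d["years"] = tuple(d["years"])
        if d.get("cohort_bump") is not None:
            d["cohort_bump"] = tuple(d["cohort_bump"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class SyntheticTruth:
    """Noiseless scenario truth: rate surface, demography and the generating
    effects expressed in the model's constrained coordinates."""

    config: ScenarioConfig
    rates: np.ndarray                  # (bands, all years), per person-year
    population: PopulationTable        # all years
    mu: float
    alpha: np.ndarray
    beta: np.ndarray                   # over all years
    gamma: np.ndarray                  # over all cohort buckets
    cohort_buckets: tuple[int, ...]

    @property
    def bands(self) -> tuple[AgeBand, ...]:
        return self.config.bands

    @property
    def years(self) -> tuple[int, ...]:
        return self.config.all_years

    def population_observed(self) -> PopulationTable:
        return self.population.subset_years(self.config.observed_years)

    def population_projection(self) -> PopulationTable:
        return self.population.subset_years(self.config.projection_years)

    def mean_counts(self) -> np.ndarray:
        return self.rates * self.population.persons


def generate_truth(config: ScenarioConfig) -> SyntheticTruth:
    """Evaluate the noiseless scenario: rate surface, person-years and true
    constrained effects.

    The returned ``(mu, alpha, beta, gamma)`` are centred with the package's
    identifiability convention (sum-to-zero effects, cohort effects linearly
    detrended with the net drift allocated to the period axis) by projecting
    the exact log-rate surface onto the constrained APC basis.
    """
    bands = config.bands
    years = np.array(config.all_years)
    mids = np.array([b.midpoint(open_width=config.cohort_grid) for b in bands])

    buckets = np.array(
        [[_cohort_bucket(int(y), m, config.cohort_grid) for y in years] for m in mids]
    )
    # the drift part of the cohort trend is linear in the exact birth year
    # (year - band midpoint) and therefore decomposes exactly into linear
    # period and age components; only the bump is a genuine (bucketed)
    # cohort effect, so the truth surface lies in the APC model family
    birth_year = years[None, :] - np.floor(mids)[:, None]
    c_ref = float(birth_year.min())
    log_rate = (
        np.asarray(config.age_curve, dtype=float)[:, None]
        + config.period_drift * (years - years[0])[None, :]
        + config.cohort_drift * (birth_year - c_ref)
    )
    if config.cohort_bump is not None:
        center, width, amplitude = config.cohort_bump
        bucket_mid = buckets + (config.cohort_grid - 1) / 2.0
        log_rate = log_rate + amplitude * np.exp(
            -0.5 * ((bucket_mid - center) / width) ** 2
        )
    rates = np.exp(log_rate)

    t = years - years[0]
    tilt = np.arange(len(bands)) - (len(bands) - 1) / 2.0
    persons = (
        np.asarray(config.base_population, dtype=float)[:, None]
        * config.population_growth ** t[None, :]
        * config.aging_shift ** (t[None, :] * tilt[:, None])
    )
    population = PopulationTable(bands=bands, years=tuple(int(y) for y in years),
                                 values=persons)

    mu, alpha, beta, gamma, cohort_buckets = decompose_surface(
        log_rate, bands, years, cohort_grid=config.cohort_grid
    )
    return SyntheticTruth(
        config=config,
        rates=rates,
        population=population,
        mu=float(mu),
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        cohort_buckets=cohort_buckets,
    )


def sample_counts(
    truth: SyntheticTruth | np.ndarray,
    population: PopulationTable,
    seed: int,
    years: Sequence[int] | None = None,
    outcome: str = "incidence",
) -> CountTable:
    """Poisson observation of a (noiseless) rate surface.

    Draws independent ``Poisson(rate * person-years)`` counts per cell on
    ``population``'s grid.  ``truth`` may be a :class:`SyntheticTruth` (its
    rate surface is aligned to ``population.years``) or a raw rate matrix
    already on that grid.  A fixed seed gives a bitwise-identical table.
    """
    if isinstance(truth, SyntheticTruth):
        cols = [truth.years.index(int(y)) for y in population.years]
        rates = truth.rates[:, cols]
        bands = truth.bands
        if bands != population.bands:
            raise ValueError("population bands do not match the truth bands")
    else:
        rates = np.asarray(truth, dtype=float)
        bands = population.bands
        if rates.shape != population.persons.shape:
            raise ValueError("rate surface shape does not match population grid")
    del years  # grid comes from the population table
    mean = rates * population.persons
    rng = np.random.default_rng(seed)
    counts = rng.poisson(mean)
    return CountTable(
        bands=bands,
        years=population.years,
        values=counts.astype(float),
        outcome=outcome,  # type: ignore[arg-type]
    )


def catalonia_like_scenario(seed: int = 12345) -> ScenarioConfig:
    """The bundled default scenario emulating the study region.

    Nine 5-year bands (45-49 ... 85+) over 1994-2030 with data observed
    through 2017; an ovarian-cancer-like age curve peaking around ages
    75-84 (rates of order 15-35 per 100,000); declining period (-1%/year)
    and birth-cohort (-1.5%/birth-year) trends, so the age-standardised
    rate falls by roughly 2.5%/year; a +0.3 log-RR Gaussian rebound centred
    on cohorts born in the early 1980s; and a slowly growing, gradually
    aging female population of ~1.5 million over the modelled ages.  Its
    noiseless 2015-2030 burden change is a net decrease dominated by the
    falling risk component, with a positive aging component.
    """
    rates_per_1e5 = np.array([15.0, 18.0, 22.0, 26.0, 30.0, 32.0, 33.0, 32.0, 28.0])
    return ScenarioConfig(
        band_labels=(
            "45-49", "50-54", "55-59", "60-64", "65-69",
            "70-74", "75-79", "80-84", "85+",
        ),
        age_curve=tuple(float(v) for v in np.log(rates_per_1e5 / 1e5)),
        period_drift=-0.010,
        cohort_drift=-0.015,
        cohort_bump=(1982.0, 2.0, 0.3),
        base_population=(
            250e3, 240e3, 220e3, 200e3, 180e3, 160e3, 130e3, 90e3, 60e3,
        ),
        population_growth=1.003,
        aging_shift=1.004,
        years=(1994, 2030),
        observed_through=2017,
        seed=seed,
    )
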