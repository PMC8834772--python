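"""Rate arithmetic: age-specific rates, truncated age-standardised rates
(ASR) to the European Standard Population, annual average percent change
(AAPC), burden-table formatting, and the transfer of registry rates onto a
target population.

Rates are per 100,000 person-years throughout.  The truncated ASR for year
``p`` is the weighted mean of the age-specific rates over the included
bands,

    ASR_p = sum_a w~_a * rate_{a,p},

with standard weights ``w~`` renormalised to sum to one over the included
(e.g. >= 45-year) bands, so a constant-rate surface has ASR equal to that
constant under any standard.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .registry_data import (
    AgeBand,
    CountTable,
    PopulationTable,
    parse_band_label,
)

__all__ = [
    "StandardPopulation",
    "RateSeries",
    "load_standard_population",
    "estimate_counts_from_rates",
    "age_specific_rates",
    "asr",
    "aapc",
    "burden_table",
]

PER = 100_000.0


@dataclass(frozen=True)
class StandardPopulation:
    """A standard age distribution used for direct age standardisation."""

    name: str
    bands: tuple[AgeBand, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("standard population weights must be positive")
        object.__setattr__(self, "bands", tuple(self.bands))
        object.__setattr__(self, "weights", w)

    def weights_for(self, bands: Sequence[AgeBand]) -> np.ndarray:
        """Aggregate the standard's weights onto a (coarser) band grid.

        Each target band receives the summed weight of the standard bands it
        fully contains; a target band the standard does not cover raises.
        """
        out = np.zeros(len(bands))
        for i, tgt in enumerate(bands):
            for src, w in zip(self.bands, self.weights):
                if src.lower >= tgt.lower and (
                    tgt.upper is None
                    or (src.upper is not None and src.upper <= tgt.upper)
                ):
                    out[i] += w
            if out[i] <= 0:
                raise ValueError(
                    f"standard population {self.name!r} does not cover band "
                    f"{tgt.label!r}"
                )
        return out


def load_standard_population(name: Literal["esp2013", "esp1976"] = "esp2013") -> StandardPopulation:
    """Load a bundled European Standard Population (2013 default, 1976
    alternative).  Weights sum to 100,000."""
    ref = resources.files("ocburden.data").joinpath(f"{name}.csv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    bands = tuple(parse_band_label(s) for s in df["age_band"])
    return StandardPopulation(name=name, bands=bands, weights=df["weight"].to_numpy(float))


@dataclass(frozen=True)
class RateSeries:
    """Per-year (age-standardised) rates per 100,000 person-years, with
    optional 95% interval bounds, truncated to ages >= ``truncated_from``."""

    years: tuple[int, ...]
    asr: np.ndarray
    lower95: np.ndarray | None = None
    upper95: np.ndarray | None = None
    truncated_from: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", tuple(int(y) for y in self.years))
        rate = np.asarray(self.asr, dtype=float)
        object.__setattr__(self, "asr", rate)
        if len(self.years) != rate.size:
            raise ValueError("years and asr lengths differ")
        if np.any(rate < 0):
            raise ValueError("rates must be non-negative")
        for attr in ("lower95", "upper95"):
            bound = getattr(self, attr)
            if bound is not None:
                object.__setattr__(self, attr, np.asarray(bound, dtype=float))
        if self.lower95 is not None and np.any(self.lower95 > rate + 1e-9):
            raise ValueError("lower95 exceeds the rate")
        if self.upper95 is not None and np.any(self.upper95 < rate - 1e-9):
            raise ValueError("upper95 is below the rate")

    def at(self, year: int) -> float:
        return float(self.asr[self.years.index(int(year))])

    def to_frame(self) -> pd.DataFrame:
        data = {"year": list(self.years), "asr": self.asr}
        if self.lower95 is not None:
            data["lower95"] = self.lower95
        if self.upper95 is not None:
            data["upper95"] = self.upper95
        return pd.DataFrame(data)


def estimate_counts_from_rates(
    registry_rates: np.ndarray,
    target_population: PopulationTable,
    outcome: Literal["incidence", "mortality"] = "incidence",
) -> CountTable:
    """Transfer per-band registry rates onto a target population.

    This is the rate-transfer step used when registry coverage is partial:
    age-specific rates observed in the covered area are applied to the whole
    territory's person-years, giving expected case counts, rounded to the
    nearest integer for downstream Poisson modelling.

    ``registry_rates`` is per 100,000 person-years, either one value per band
    (constant over years) or a full band x year matrix.
    """
    rates = np.asarray(registry_rates, dtype=float)
    n_bands = len(target_population.bands)
    if rates.ndim == 1:
        if rates.size != n_bands:
            raise ValueError(
                f"rate vector has {rates.size} bands, population has {n_bands}"
            )
        rates = rates[:, None]
    if rates.shape[0] != n_bands:
        raise ValueError(
            f"rate matrix has {rates.shape[0]} bands, population has {n_bands}"
        )
    expected = rates / PER * target_population.persons
    counts = np.rint(expected)
    return CountTable(
        bands=target_population.bands,
        years=target_population.years,
        values=counts,
        outcome=outcome,
    )


def age_specific_rates(counts: CountTable, population: PopulationTable) -> np.ndarray:
    """Per-band, per-year rates per 100,000 person-years."""
    if not counts.same_grid(population):
        raise ValueError("count and population tables are on different grids")
    return PER * counts.counts / population.persons


def asr(
    counts: CountTable,
    population: PopulationTable,
    standard: StandardPopulation,
    truncate_from: int = 45,
) -> RateSeries:
    """Truncated direct age-standardised rate series.

    Bands starting at or above ``truncate_from`` are included; the standard's
    weights over those bands are renormalised to sum to one.
    """
    rates = age_specific_rates(counts, population)
    keep = [i for i, b in enumerate(counts.bands) if b.lower >= truncate_from]
    if not keep:
        raise ValueError(f"no bands at or above age {truncate_from}")
    bands = [counts.bands[i] for i in keep]
    w = standard.weights_for(bands)
    w = w / w.sum()
    series = w @ rates[keep]
    return RateSeries(years=counts.years, asr=series, truncated_from=truncate_from)


def weighted_asr(
    rates: np.ndarray,
    bands: Sequence[AgeBand],
    standard: StandardPopulation,
    truncate_from: int = 45,
) -> np.ndarray:
    """ASR of an already-computed rate matrix (bands x years) — the same
    renormalised-weight convention as :func:`asr`, usable on posterior draws."""
    rates = np.asarray(rates, dtype=float)
    keep = [i for i, b in enumerate(bands) if b.lower >= truncate_from]
    if not keep:
        raise ValueError(f"no bands at or above age {truncate_from}")
    w = standard.weights_for([bands[i] for i in keep])
    w = w / w.sum()
    return np.tensordot(w, rates[..., keep, :], axes=([0], [-2]))


def aapc(
    series: RateSeries,
    from_year: int,
    to_year: int,
    method: Literal["endpoint_geometric", "loglinear_regression"] = "endpoint_geometric",
) -> float:
    """Annual average percent change of a rate series, in %/year.

    ``endpoint_geometric`` uses only the two endpoint rates:
    ``100 * ((r_to / r_from)**(1/(to - from)) - 1)``.
    ``loglinear_regression`` regresses log rate on year over
    ``[from_year, to_year]`` and returns ``100 * (exp(slope) - 1)``.
    Both agree exactly on an exactly exponential series.
    """
    if to_year <= from_year:
        raise ValueError("to_year must be after from_year")
    if method == "endpoint_geometric":
        r0, r1 = series.at(from_year), series.at(to_year)
        if r0 <= 0 or r1 <= 0:
            raise ValueError("endpoint rates must be positive for the geometric AAPC")
        return 100.0 * ((r1 / r0) ** (1.0 / (to_year - from_year)) - 1.0)
    if method == "loglinear_regression":
        mask = [(from_year <= y <= to_year) for y in series.years]
        years = np.asarray(series.years, dtype=float)[mask]
        rates = series.asr[mask]
        if rates.size < 2:
            raise ValueError("need at least two years inside the AAPC window")
        if np.any(rates <= 0):
            raise ValueError("rates must be positive for the log-linear AAPC")
        slope = np.polyfit(years, np.log(rates), 1)[0]
        return 100.0 * (np.exp(slope) - 1.0)
    raise ValueError(f"unknown AAPC method {method!r}")


def burden_table(
    counts_by_reportband,
    reference_years: tuple[int, int],
    asr_values: dict[int, float] | None = None,
    band_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Burden table for two reference years on reporting bands.

    One row per reference year with, per band, the case count N and the row
    percentage ``100 * N_band / N_total`` (1 d.p.), plus the total, the net
    change in totals between the two years (2 d.p.) on the later row, and the
    ASR (1 d.p.) where supplied.  Mirrors the layout of published burden
    tables.

    ``counts_by_reportband`` is a :class:`CountTable` containing both
    reference years, or (since reference years are rarely adjacent) a plain
    mapping ``{year: per-band counts}`` with ``band_labels`` given.
    """
    from .decomposition import net_change_pct

    y0, y1 = reference_years
    if isinstance(counts_by_reportband, CountTable):
        labels = counts_by_reportband.band_labels
        columns = {
            year: counts_by_reportband.counts[:, counts_by_reportband.year_index(year)]
            for year in (y0, y1)
        }
    else:
        if band_labels is None:
            raise ValueError("band_labels is required with a {year: counts} mapping")
        labels = list(band_labels)
        columns = {year: np.asarray(counts_by_reportband[year], dtype=float)
                   for year in (y0, y1)}

    rows = []
    totals = {}
    for year in (y0, y1):
        col = columns[year]
        if col.size != len(labels):
            raise ValueError(f"{year}: {col.size} counts for {len(labels)} bands")
        total = col.sum()
        if total <= 0:
            raise ValueError(f"zero total count in reference year {year}")
        totals[year] = total
        row: dict[str, object] = {"year": year}
        for label, n in zip(labels, col):
            row[f"N {label}"] = int(n)
            row[f"% {label}"] = round(100.0 * n / total, 1)
        row["N total"] = int(total)
        row["net_change_pct"] = np.nan
        row["asr"] = (
            round(asr_values[year], 1) if asr_values and year in asr_values else np.nan
        )
        rows.append(row)
    rows[1]["net_change_pct"] = round(net_change_pct(totals[y0], totals[y1]), 2)
    return pd.DataFrame(rows)
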