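"""Registry-style count and population tables.

Cancer registries publish event counts (incident cases or deaths) and
person-years at risk aggregated by 5-year age band and calendar year.  This
module provides the two table containers used throughout the package, the
age-band label grammar (``"<45"``, ``"45-49"``, ``"85+"``), CSV round-trip
I/O in long and wide layouts, and band aggregation (5-year modelling bands
onto coarser reporting bands).

Age bands are half-open ``[lower, upper)`` in integer years: the label
``"45-49"`` denotes ``[45, 50)``.  Bands within a table must be sorted,
non-overlapping and contiguous.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "AgeBand",
    "CountTable",
    "PopulationTable",
    "parse_band_label",
    "read_table",
    "write_table",
    "aggregate_bands",
]

_BAND_RE_RANGE = re.compile(r"^(\d+)-(\d+)$")
_BAND_RE_OPEN_TOP = re.compile(r"^(\d+)\+$")
_BAND_RE_OPEN_BOTTOM = re.compile(r"^<(\d+)$")


@dataclass(frozen=True, order=True)
class AgeBand:
    """Half-open age interval ``[lower, upper)`` in integer years.

    ``upper=None`` marks the open-ended top band (``"85+"``); ``lower=0``
    with a ``"<U"`` label is the open bottom band used for reporting the
    under-45 burden.
    """

    lower: int
    upper: int | None = field(compare=False, default=None)

    def __post_init__(self) -> None:
        if self.lower < 0:
            raise ValueError(f"age band lower bound must be >= 0, got {self.lower}")
        if self.upper is not None and not self.lower < self.upper:
            raise ValueError(
                f"age band requires lower < upper, got [{self.lower}, {self.upper})"
            )

    @property
    def label(self) -> str:
        if self.upper is None:
            return f"{self.lower}+"
        if self.lower == 0:
            return f"<{self.upper}"
        return f"{self.lower}-{self.upper - 1}"

    @property
    def width(self) -> int | None:
        return None if self.upper is None else self.upper - self.lower

    def midpoint(self, open_width: int = 5) -> float:
        """Band midpoint in years; the open top band is treated as
        ``open_width`` years wide for cohort indexing."""
        upper = self.lower + open_width if self.upper is None else self.upper
        return (self.lower + upper) / 2.0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def parse_band_label(label: str) -> AgeBand:
    """Parse an age-band label.

    The grammar is exactly ``"<U"`` (open bottom, ``[0, U)``), ``"L-U"``
    (closed 5-year-style band ``[L, U+1)``) and ``"L+"`` (open top).
    Anything else is rejected.
    """
    text = str(label).strip()
    m = _BAND_RE_RANGE.match(text)
    if m:
        lo, hi = int(m.group(1)), int(m.group(2))
        if hi < lo:
            raise ValueError(f"invalid age band label {label!r}: upper < lower")
        return AgeBand(lo, hi + 1)
    m = _BAND_RE_OPEN_TOP.match(text)
    if m:
        return AgeBand(int(m.group(1)), None)
    m = _BAND_RE_OPEN_BOTTOM.match(text)
    if m:
        hi = int(m.group(1))
        if hi == 0:
            raise ValueError(f"invalid age band label {label!r}")
        return AgeBand(0, hi)
    raise ValueError(
        f"invalid age band label {label!r}: expected '<U', 'L-U' or 'L+'"
    )


def _check_band_sequence(bands: Sequence[AgeBand]) -> None:
    if len(bands) == 0:
        raise ValueError("table must contain at least one age band")
    for prev, cur in zip(bands, bands[1:]):
        if prev.upper is None:
            raise ValueError(
                f"open-ended band {prev.label!r} must be the last band"
            )
        if cur.lower != prev.upper:
            raise ValueError(
                f"age bands must be contiguous and sorted: {prev.label!r} "
                f"is followed by {cur.label!r}"
            )


def _check_years(years: Sequence[int]) -> None:
    if len(years) == 0:
        raise ValueError("table must contain at least one year")
    y = np.asarray(years)
    if not np.array_equal(y, np.arange(y[0], y[0] + len(y))):
        raise ValueError(f"years must be consecutive annual values, got {list(years)}")


@dataclass(frozen=True)
class _GridTable:
    """Common band x year grid behaviour of count and population tables."""

    bands: tuple[AgeBand, ...]
    years: tuple[int, ...]
    values: np.ndarray  # shape (n_bands, n_years)

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", tuple(self.bands))
        object.__setattr__(self, "years", tuple(int(y) for y in self.years))
        _check_band_sequence(self.bands)
        _check_years(self.years)
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.bands), len(self.years)):
            raise ValueError(
                f"value matrix shape {vals.shape} does not match "
                f"{len(self.bands)} bands x {len(self.years)} years"
            )
        object.__setattr__(self, "values", vals)
        self._validate_values()

    def _validate_values(self) -> None:  # pragma: no cover - overridden
        raise NotImplementedError

    @property
    def band_labels(self) -> list[str]:
        return [b.label for b in self.bands]

    def year_index(self, year: int) -> int:
        try:
            return self.years.index(int(year))
        except ValueError:
            raise KeyError(f"year {year} not in table ({self.years[0]}-{self.years[-1]})")

    def subset_years(self, years: Sequence[int]) -> "_GridTable":
        idx = [self.year_index(y) for y in years]
        return replace(self, years=tuple(int(y) for y in years), values=self.values[:, idx])

    def subset_bands(self, bands: Sequence[AgeBand]) -> "_GridTable":
        positions = []
        for b in bands:
            if b not in self.bands:
                raise KeyError(f"band {b.label!r} not in table")
            positions.append(self.bands.index(b))
        return replace(self, bands=tuple(bands), values=self.values[positions])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.band_labels, columns=list(self.years))

    def same_grid(self, other: "_GridTable") -> bool:
        return self.bands == other.bands and self.years == other.years


@dataclass(frozen=True)
class CountTable(_GridTable):
    """Non-negative integer event counts on a band x year grid."""

    outcome: Literal["incidence", "mortality"] = "incidence"

    def _validate_values(self) -> None:
        v = self.values
        if np.any(~np.isfinite(v)):
            raise ValueError("counts contain missing or non-finite cells")
        if np.any(v < 0):
            b, y = np.argwhere(v < 0)[0]
            raise ValueError(
                f"negative count at ({self.bands[b].label!r}, {self.years[y]})"
            )
        if np.any(v != np.round(v)):
            b, y = np.argwhere(v != np.round(v))[0]
            raise ValueError(
                f"non-integer count at ({self.bands[b].label!r}, {self.years[y]})"
            )

    @property
    def counts(self) -> np.ndarray:
        return self.values

    def yearly_totals(self) -> np.ndarray:
        return self.values.sum(axis=0)


@dataclass(frozen=True)
class PopulationTable(_GridTable):
    """Positive person-years at risk on a band x year grid."""

    def _validate_values(self) -> None:
        v = self.values
        if np.any(~np.isfinite(v)):
            raise ValueError("person-years contain missing or non-finite cells")
        if np.any(v <= 0):
            b, y = np.argwhere(v <= 0)[0]
            raise ValueError(
                f"non-positive person-years at ({self.bands[b].label!r}, {self.years[y]})"
            )

    @property
    def persons(self) -> np.ndarray:
        return self.values


Table = Union[CountTable, PopulationTable]


# ---------------------------------------------------------------------------
# CSV I/O
#
# Long layout: header "age_band,year,value", one row per cell.
# Wide layout: first column "age_band", remaining columns are years.
# Both are comma-delimited UTF-8 with "." decimals; write_table emits long.
# ---------------------------------------------------------------------------

def _table_from_cells(cells: dict[tuple[str, int], float], schema: str) -> Table:
    band_labels = sorted({k[0] for k in cells}, key=lambda s: parse_band_label(s))
    years = sorted({k[1] for k in cells})
    bands = [parse_band_label(s) for s in band_labels]
    values = np.empty((len(bands), len(years)))
    for i, lab in enumerate(band_labels):
        for j, year in enumerate(years):
            if (lab, year) not in cells:
                raise ValueError(f"missing cell ({lab!r}, {year})")
            values[i, j] = cells[(lab, year)]
    if schema == "counts":
        return CountTable(bands=tuple(bands), years=tuple(years), values=values)
    return PopulationTable(bands=tuple(bands), years=tuple(years), values=values)


def read_table(path: str | Path, schema: Literal["counts", "population"]) -> Table:
    """Read a count or population table from CSV.

    Accepts the long layout (columns ``age_band, year, value``) or a wide
    age x year grid.  Validation is strict: duplicate keys, missing cells,
    negative values or (for counts) non-integer values are rejected with the
    offending ``(band, year)`` key named, rather than silently repaired.
    """
    if schema not in ("counts", "population"):
        raise ValueError(f"schema must be 'counts' or 'population', got {schema!r}")
    df = pd.read_csv(path, dtype={0: str})
    cols = [c.strip() for c in df.columns]
    cells: dict[tuple[str, int], float] = {}
    if cols[:3] == ["age_band", "year", "value"] and len(cols) == 3:
        for _, row in df.iterrows():
            key = (str(row["age_band"]).strip(), int(row["year"]))
            if key in cells:
                raise ValueError(f"duplicate cell ({key[0]!r}, {key[1]})")
            cells[key] = _parse_value(row["value"], key, schema)
    elif cols and cols[0] == "age_band":
        years = [int(c) for c in cols[1:]]
        for _, row in df.iterrows():
            lab = str(row["age_band"]).strip()
            for year, col in zip(years, df.columns[1:]):
                key = (lab, year)
                if key in cells:
                    raise ValueError(f"duplicate cell ({lab!r}, {year})")
                cells[key] = _parse_value(row[col], key, schema)
    else:
        raise ValueError(
            "unrecognised CSV layout: expected columns 'age_band,year,value' "
            f"or a wide grid starting with 'age_band', got {cols}"
        )
    if not cells:
        raise ValueError(f"no data rows in {path}")
    return _table_from_cells(cells, schema)


def _parse_value(raw: object, key: tuple[str, int], schema: str) -> float:
    value = float(raw)
    if not np.isfinite(value):
        raise ValueError(f"missing value at ({key[0]!r}, {key[1]})")
    if value < 0:
        raise ValueError(f"negative value at ({key[0]!r}, {key[1]})")
    if schema == "counts" and value != round(value):
        raise ValueError(f"non-integer count at ({key[0]!r}, {key[1]})")
    return value


def write_table(table: Table, path: str | Path) -> None:
    """Write a table as long-format CSV (``age_band,year,value``).

    ``read_table(write_table(t))`` reproduces every cell exactly; counts are
    written as integers so the round trip is bit-exact.
    """
    is_counts = isinstance(table, CountTable)
    rows = []
    for band, row in zip(table.bands, table.values):
        for year, value in zip(table.years, row):
            rows.append((band.label, year, int(value) if is_counts else value))
    pd.DataFrame(rows, columns=["age_band", "year", "value"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Band algebra
# ---------------------------------------------------------------------------

def aggregate_bands(table: Table, target_bands: Sequence[AgeBand]) -> Table:
    """Sum table values onto coarser bands.

    Every target band must be the union of consecutive source bands (e.g.
    5-year modelling bands onto 10-year reporting bands, or onto an open
    ``75+`` top band).  Per-year grand totals over the covered range are
    conserved exactly.
    """
    target_bands = tuple(target_bands)
    _check_band_sequence(target_bands)
    source = table.bands
    values = np.zeros((len(target_bands), len(table.years)))
    for i, tgt in enumerate(target_bands):
        members = [
            j
            for j, src in enumerate(source)
            if src.lower >= tgt.lower
            and (tgt.upper is None or (src.upper is not None and src.upper <= tgt.upper))
        ]
        if not members:
            raise ValueError(f"target band {tgt.label!r} covers no source bands")
        lowers = [source[j].lower for j in members]
        uppers = [source[j].upper for j in members]
        if min(lowers) != tgt.lower or (tgt.upper is not None and max(uppers) != tgt.upper):
            raise ValueError(
                f"target band {tgt.label!r} is not a union of consecutive "
                f"source bands"
            )
        if tgt.upper is None and source[-1].upper is not None:
            raise ValueError(
                f"open target band {tgt.label!r} requires an open source top band"
            )
        values[i] = table.values[members].sum(axis=0)
    new = replace(table, bands=target_bands, values=values)
    return new
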