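"""Core domain types for multi-environment trial analysis.

A *trial* is one location-year combination of a variety test. Trial data are
held long-format (:class:`TrialSet`), pivoted per year into a
genotype-by-environment matrix (:class:`GEMatrix`), and summarized across
years as a trials-by-locations table of Pearson correlations
(:class:`CorrelationTable`) — the input of the location-grouping (LG) biplot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import EmptySelectionError, IntegrityError, LabelError


def trial_label(location: str, year: int) -> str:
    """Label a trial as ``<LOCATION>_<2-digit year>``, e.g. ``OTT_10``."""
    return f"{location}_{year % 100:02d}"


def parse_trial_label(label: str) -> tuple[str, int]:
    """Split a trial label on its final underscore into (location, 2-digit year)."""
    loc, _, yy = label.rpartition("_")
    if not loc or not yy.isdigit():
        raise LabelError(f"trial label {label!r} does not parse as LOCATION_YY")
    return loc, int(yy)


@dataclass(frozen=True)
class TrialRecord:
    """One trait observation: genotype x location x year."""

    genotype: str
    location: str
    year: int
    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise IntegrityError(
                f"non-finite value for ({self.genotype}, {self.location}, "
                f"{self.year}); missing observations must be absent records"
            )


@dataclass
class TrialSet:
    """A collection of trial records; every (location, year) pair is a trial."""

    records: list[TrialRecord]
    trait_name: str = "yield"

    def __post_init__(self) -> None:
        if not self.records:
            raise IntegrityError("a TrialSet needs at least one record")
        seen: set[tuple[str, str, int]] = set()
        for r in self.records:
            key = (r.genotype, r.location, r.year)
            if key in seen:
                raise IntegrityError(f"duplicate record for {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialSet):
            return NotImplemented
        return (self.trait_name == other.trait_name
                and sorted(self.records, key=_record_key)
                == sorted(other.records, key=_record_key))

    def years(self) -> list[int]:
        return sorted({r.year for r in self.records})

    def locations(self) -> list[str]:
        return sorted({r.location for r in self.records})

    def trials(self) -> list[tuple[str, int]]:
        """All (location, year) pairs present."""
        return sorted({(r.location, r.year) for r in self.records})

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.genotype, r.location, r.year, r.value) for r in self.records],
            columns=["genotype", "location", "year", "value"],
        )


def _record_key(r: TrialRecord) -> tuple[str, str, int]:
    return (r.genotype, r.location, r.year)


@dataclass
class GEMatrix:
    """Genotype-by-environment value matrix; NaN marks a missing cell.

    ``data`` is a float DataFrame with genotype row index and environment
    column index (locations for a yearly matrix).
    """

    data: pd.DataFrame
    year: int | None = None

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise IntegrityError("duplicate row or column identifiers")
        with np.errstate(invalid="ignore"):
            if np.isinf(self.data.to_numpy()).any():
                raise IntegrityError("infinite cell values are not allowed")

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().sum().sum())

    def is_complete(self) -> bool:
        return self.n_missing == 0


def to_ge_matrix(trials: TrialSet, year: int) -> GEMatrix:
    """Pivot one year of a TrialSet into a genotype x location matrix.

    Rows are the genotypes tested that year and columns the locations with at
    least one record, both sorted; genotype-location combinations without a
    record are missing (NaN).
    """
    rows = [r for r in trials.records if r.year == year]
    if not rows:
        raise EmptySelectionError(
            f"no records for year {year}; available years: {trials.years()}"
        )
    df = pd.DataFrame(
        [(r.genotype, r.location, r.value) for r in rows],
        columns=["genotype", "location", "value"],
    )
    wide = df.pivot(index="genotype", columns="location", values="value")
    wide = wide.sort_index(axis=0).sort_index(axis=1)
    wide.index.name = None
    wide.columns.name = None
    return GEMatrix(wide, year=year)


@dataclass
class CorrelationTable:
    """Trials-by-locations table of Pearson correlations (the LG table).

    Rows are trials labelled ``<LOCATION>_<YY>``; columns are locations.
    ``meta`` maps each trial label to its (location, year). Cells under
    locations untested in a trial's year are structurally missing; a cell may
    additionally be missing where a correlation could not be computed (or, in
    the packaged fixture, could not be read from the source).
    """

    data: pd.DataFrame
    meta: Mapping[str, tuple[str, int]] = field(default_factory=dict)
    #: True once missing cells have been filled by imputation; estimated
    #: cells then legitimately sit under locations untested in a trial's
    #: year, so the structural-missingness check no longer applies.
    imputed: bool = False

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        if self.data.index.has_duplicates:
            raise IntegrityError("duplicate trial labels")
        if self.data.columns.has_duplicates:
            raise IntegrityError("duplicate location columns")
        if not self.meta:
            self.meta = {t: parse_trial_label(t) for t in self.data.index}
        self.validate()

    def validate(self) -> None:
        cols = set(self.data.columns)
        vals = self.data.to_numpy()
        present = ~np.isnan(vals)
        if (np.abs(vals[present]) > 1.0 + 1e-12).any():
            raise IntegrityError("correlation cells must lie in [-1, 1]")
        # locations tested in a year = locations with a trial row that year
        tested: dict[int, set[str]] = {}
        for trial, (loc, year) in self.meta.items():
            tested.setdefault(year, set()).add(loc)
        for trial in self.data.index:
            loc, year = self.meta[trial]
            if loc not in cols:
                raise IntegrityError(
                    f"trial {trial!r} refers to location {loc!r} "
                    "absent from the columns"
                )
            row = self.data.loc[trial]
            own = row[loc]
            if not np.isnan(own) and abs(own - 1.0) > 1e-12:
                raise IntegrityError(
                    f"self-correlation of trial {trial!r} is {own}, expected 1"
                )
            # present => tested that year (structural missingness)
            if not self.imputed:
                for col in self.data.columns:
                    if not np.isnan(row[col]) and col not in tested[year]:
                        raise IntegrityError(
                            f"trial {trial!r} has a value under {col!r}, "
                            f"untested in {year}"
                        )

    @property
    def trial_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def location_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().sum().sum())

    def is_complete(self) -> bool:
        return self.n_missing == 0

    def years(self) -> list[int]:
        return sorted({year for _, year in self.meta.values()})

    def trial_location(self, trial: str) -> str:
        return self.meta[trial][0]
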