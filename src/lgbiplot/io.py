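"""Readers and writers for delimited trial data and correlation tables.

Trial data are exchanged as CSV with columns ``genotype, location, year,
value`` (names configurable). Correlation tables are CSV with the trial label
in the first column, one column per location, and empty cells for missing
values. A transcription of the published 2006-2010 Quebec oat trial
correlation table ships with the package (:func:`load_table1_fixture`).
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import CorrelationTable, TrialRecord, TrialSet
from .errors import ConfigurationError, ParseError

#: Cells of the packaged fixture that are blank in the published table even
#: though both locations were tested that year (could not be transcribed).
TABLE1_UNTRANSCRIBED = [("NORM3_10", "OTT"), ("OTT_10", "NORM3")]


def read_trials(
    path: str | Path,
    delimiter: str = ",",
    columns: tuple[str, str, str, str] = ("genotype", "location", "year", "value"),
    trait_name: str = "yield",
) -> TrialSet:
    """Read long-format trial records from a delimited text file.

    Raises
    ------
    ConfigurationError
        If a required column is absent from the header.
    ParseError
        If a year or value field is not numeric (the message names the line).
    IntegrityError
        If a (genotype, location, year) key occurs twice.
    """
    path = Path(path)
    gcol, lcol, ycol, vcol = columns
    records: list[TrialRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [c for c in columns if c not in header]
        if missing:
            raise ConfigurationError(
                f"{path}: missing required column(s) {missing}; header is {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                year = int(row[ycol])
                value = float(row[vcol])
            except (TypeError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: cannot parse record: {exc}") from exc
            records.append(TrialRecord(row[gcol], row[lcol], year, value))
    if not records:
        raise ParseError(f"{path}: no data rows")
    return TrialSet(records, trait_name=trait_name)


def write_trials(trials: TrialSet, path: str | Path, delimiter: str = ",") -> Path:
    """Write a TrialSet as delimited text (CSV by default)."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["genotype", "location", "year", "value"])
        for r in sorted(trials.records, key=lambda r: (r.year, r.location, r.genotype)):
            writer.writerow([r.genotype, r.location, r.year, _fmt(r.value)])
    return path


def _fmt(x: float) -> str:
    # repr round-trips floats exactly; integers stay compact
    return repr(float(x))


def read_correlation_table(path: str | Path, delimiter: str = ",") -> CorrelationTable:
    """Read a trials-by-locations correlation table from delimited text."""
    df = pd.read_csv(path, index_col=0, sep=delimiter)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns.name = None
    return CorrelationTable(df.astype(float))


def write_correlation_table(
    table: CorrelationTable, path: str | Path, delimiter: str = ","
) -> Path:
    """Write a correlation table as delimited text; missing cells are empty."""
    path = Path(path)
    table.data.to_csv(path, sep=delimiter, index_label="trial", na_rep="")
    return path


def load_table1_fixture() -> CorrelationTable:
    """The published 2006-2010 Quebec oat yearly location-correlation table.

    39 trials (7 in 2006, 7 in 2007, 8 in 2008, 8 in 2009, 9 in 2010) over 11
    locations spanning the three Quebec ecological zones plus Ottawa. Cells
    under locations untested in a trial's year are structurally missing; the
    two cells in :data:`TABLE1_UNTRANSCRIBED` are blank in the source.
    """
    ref = resources.files("lgbiplot.data") / "table1_correlations.csv"
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, index_col=0)
    df.index.name = None
    meta = {}
    for label in df.index:
        loc, _, yy = label.rpartition("_")
        meta[label] = (loc, 2000 + int(yy))
    return CorrelationTable(df.astype(float), meta=meta)


def write_biplot_report(model, path: str | Path) -> Path:
    """Serialize a biplot model to a small delimited text report.

    Sections: settings codes, singular values with goodness of fit, then row
    and column coordinates.
    """
    path = Path(path)
    s = model.settings
    lines = [
        f"# Scaling = {s.scaling}, Centering = {s.centering}, SVP = {s.svp}",
        f"# d = {model.d:.6g}",
        f"# goodness_of_fit = {model.gof:.6f}",
        "# singular_values = " + ",".join(f"{v:.6g}" for v in model.singular_values),
        "axis,id,PC1,PC2",
    ]
    for rid, (x, y) in zip(model.row_ids, model.row_coords):
        lines.append(f"row,{rid},{x:.6f},{y:.6f}")
    for cid, (x, y) in zip(model.col_ids, model.col_coords):
        lines.append(f"col,{cid},{x:.6f},{y:.6f}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_partition_report(partition, spread, path: str | Path) -> Path:
    """Write the mega-environment partition as CSV.

    Columns: location, group, PC1, PC2, spread (mean distance of the
    location's trials from its mean placement; NaN if not supplied).
    """
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["location", "group", "PC1", "PC2", "spread"])
        for loc in partition.placements.index:
            x, y = partition.placements.loc[loc]
            sp = np.nan if spread is None else spread.get(loc, np.nan)
            writer.writerow(
                [loc, partition.groups[loc], f"{x:.6f}", f"{y:.6f}", f"{sp:.6f}"]
            )
    return path
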