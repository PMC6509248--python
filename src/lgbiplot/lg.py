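"""The location-grouping (LG) biplot pipeline.

Multi-year variety-trial data are highly unbalanced: each year tests its own
genotype set, so yields cannot be pooled across years directly. What *can* be
stacked across years are the yearly Pearson correlations between test
locations across the genotypes they share. The pipeline is:

1. per year, correlate locations across genotypes (pairwise-complete);
2. stack the yearly matrices into one trials-by-locations table, with a
   structural missing cell wherever a column location was untested that year;
3. impute missing cells by iterative rank-2 SVD;
4. biplot the table without scaling or centering (the LG biplot; its inner
   products approximate the correlations) or after grand-mean centering (the
   LG1 variant, which accentuates dissimilarities);
5. place each location at the mean coordinates of its trials and cluster the
   placements (average linkage on cosine dissimilarity) into k
   mega-environments.

Between-group differences that persist across years are repeatable
genotype-by-environment interaction — the basis for mega-environment
delineation; the year-to-year scatter of one location's trials around its
mean placement measures the unrepeatable part.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .datamodel import (
    CorrelationTable,
    GEMatrix,
    TrialSet,
    to_ge_matrix,
    trial_label,
)
from .errors import (
    DegeneratePlacementError,
    DimensionError,
    IntegrityError,
    LabelError,
    MissingCellsError,
    UnimputableError,
)
from .gge import BiplotModel, ModelSettings, svd_biplot

#: Minimum genotypes observed at both locations for a yearly correlation.
MIN_SHARED_GENOTYPES = 3


@dataclass
class MegaEnvPartition:
    """Location groups with their mean biplot placements.

    ``groups`` maps each location to a label in 1..k; ``placements`` is a
    DataFrame (location x [PC1, PC2]); ``linkage_height`` holds the merge
    heights of the hierarchical clustering, in merge order.
    """

    placements: pd.DataFrame
    groups: dict[str, int]
    k: int
    linkage_height: np.ndarray = field(default_factory=lambda: np.array([]))

    def members(self, label: int) -> list[str]:
        return sorted(loc for loc, g in self.groups.items() if g == label)

    def group_of(self, location: str) -> int:
        return self.groups[location]


def yearly_correlations(matrix: GEMatrix) -> pd.DataFrame:
    """Pearson correlations among locations across genotypes, for one year.

    Pairwise-complete: each location pair uses the genotypes observed at
    both, and needs at least :data:`MIN_SHARED_GENOTYPES` of them (a
    correlation from two points is always +/-1 and carries no information).
    A location with fewer than 3 observations overall gets an all-missing
    row/column, with a warning.
    """
    df = matrix.data
    corr = df.corr(method="pearson", min_periods=MIN_SHARED_GENOTYPES)
    sparse = df.notna().sum(axis=0) < MIN_SHARED_GENOTYPES
    if sparse.any():
        bad = list(df.columns[sparse])
        warnings.warn(
            f"location(s) {bad} have fewer than {MIN_SHARED_GENOTYPES} "
            "observations; their correlations are undefined",
            stacklevel=2,
        )
        corr.loc[bad, :] = np.nan
        corr.loc[:, bad] = np.nan
    else:
        np.fill_diagonal(corr.values, 1.0)
    corr.index.name = None
    corr.columns.name = None
    return corr


def assemble_lg_table(
    yearly: Mapping[int, pd.DataFrame],
) -> CorrelationTable:
    """Stack per-year location-correlation matrices into the LG table.

    Rows are trials (location-year, labelled ``LOC_YY``), columns the union
    of locations over years. Cell (A_Y, B) holds the year-Y correlation of A
    with B when B was tested in year Y, and is missing otherwise; each
    trial's cell under its own location is 1 by definition.
    """
    if len(yearly) < 2:
        raise DimensionError("need correlation matrices from at least 2 years")
    locations = sorted({loc for m in yearly.values() for loc in m.columns})
    rows, labels, meta = [], [], {}
    for year in sorted(yearly):
        m = yearly[year]
        if list(m.index) != list(m.columns):
            raise IntegrityError(f"year {year}: correlation matrix is not square")
        for loc in m.index:
            label = trial_label(loc, year)
            if label in meta:
                raise IntegrityError(f"duplicate trial label {label!r}")
            row = pd.Series(np.nan, index=locations, dtype=float)
            row[list(m.columns)] = m.loc[loc].to_numpy()
            row[loc] = 1.0
            rows.append(row)
            labels.append(label)
            meta[label] = (loc, year)
    data = pd.DataFrame(rows, index=labels, columns=locations)
    return CorrelationTable(data, meta=meta)


def trials_to_lg_table(trials: TrialSet) -> CorrelationTable:
    """Convenience: yearly correlations + assembly, straight from trial data."""
    yearly = {y: yearly_correlations(to_ge_matrix(trials, y)) for y in trials.years()}
    return assemble_lg_table(yearly)


def _em_impute_run(
    x0: np.ndarray,
    mask: np.ndarray,
    fill: np.ndarray | float,
    ranks: list[int],
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, float, float]:
    """One EM run from a given fill of the missing cells.

    Iterates rank-r truncated SVD / missing-cell replacement for each rank in
    ``ranks`` in turn (earlier, lower ranks act as a warm start). Returns the
    completed matrix, the Frobenius residual of the final rank-r model on the
    *observed* cells (the fitting objective), and the last update size.
    """
    x = x0.copy()
    x[mask] = fill
    delta = np.inf
    r = ranks[-1]
    for r in ranks:
        for _ in range(max_iter):
            u, s, vt = np.linalg.svd(x, full_matrices=False)
            recon = (u[:, :r] * s[:r]) @ vt[:r]
            new = recon[mask]
            delta = float(np.max(np.abs(new - x[mask])))
            x[mask] = new
            if delta < tol:
                break
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    recon = (u[:, :r] * s[:r]) @ vt[:r]
    resid = float(np.linalg.norm((recon - x)[~mask]))
    return x, resid, delta


def iterative_svd_impute(
    df: pd.DataFrame,
    rank: int = 2,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> pd.DataFrame:
    """EM-style low-rank imputation of the NaN cells of a numeric frame.

    Each EM run fills the missing cells, then alternates a rank-``rank``
    truncated SVD of the filled matrix with replacement of the missing cells
    by their reconstruction, until the largest change falls below ``tol``.
    The iteration is non-convex: from an unlucky start it can creep toward a
    completion with inflated missing entries instead of the generating
    low-rank structure. Four deterministic starts are therefore run —
    column-mean fill (the reference), column-mean with a rank-ramped warm
    start (rank 1 first, then 2, ...), row-mean fill and zero fill — and the
    completion whose final rank-``rank`` model best fits the *observed*
    cells is kept (ties favor the reference start). Observed cells are never
    modified. Exactly rank-``rank`` matrices with at least 2 observed cells
    in every row and column are recovered essentially exactly.
    """
    mask = df.isna().to_numpy()
    if not mask.any():
        return df.copy()
    if df.notna().sum(axis=1).min() == 0 or df.notna().sum(axis=0).min() == 0:
        raise UnimputableError("a row or column has no observed cells")

    x0 = df.to_numpy(dtype=float)
    rows, cols = np.nonzero(mask)
    col_fill = np.take(np.nanmean(x0, axis=0), cols)
    row_fill = np.take(np.nanmean(x0, axis=1), rows)
    ramp = list(range(1, rank)) + [rank]
    starts = [
        (col_fill, [rank]),
        (col_fill, ramp),
        (row_fill, [rank]),
        (0.0, [rank]),
    ]
    best = None
    for fill, ranks in starts:
        run = _em_impute_run(x0, mask, fill, ranks, tol, max_iter)
        if best is None or run[1] < best[1]:
            best = run
    x, _, delta = best
    if delta >= tol:
        warnings.warn(
            f"imputation did not converge in {max_iter} iterations "
            f"(last change {delta:.3g})",
            stacklevel=3,
        )
    return pd.DataFrame(x, index=df.index, columns=df.columns)


def impute_missing(
    table: CorrelationTable,
    rank: int = 2,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> CorrelationTable:
    """Fill the missing cells of an LG table by :func:`iterative_svd_impute`.

    Observed correlations are never modified; imputed cells are clipped to
    [-1, 1]. A complete table is returned unchanged.
    """
    df = table.data
    mask = df.isna().to_numpy()
    if not mask.any():
        return table
    x = iterative_svd_impute(df, rank=rank, tol=tol, max_iter=max_iter).to_numpy()
    x[mask] = np.clip(x[mask], -1.0, 1.0)
    out = pd.DataFrame(x, index=df.index, columns=df.columns)
    return CorrelationTable(out, meta=dict(table.meta), imputed=True)


def lg_biplot(table: CorrelationTable, variant: str = "LG") -> BiplotModel:
    """Biplot of the (complete) LG table.

    LG uses no scaling and no centering, so inner products approximate the
    correlations themselves; LG1 first subtracts the grand mean, trading that
    interpretation for better separation of locations. In both, singular
    values are partitioned entirely to the trial (location-year) vectors
    (SVP = 2 in the location x trial orientation of the underlying model).
    """
    if variant not in ("LG", "LG1"):
        raise ValueError(f"variant must be 'LG' or 'LG1', got {variant!r}")
    if not table.is_complete():
        raise MissingCellsError(
            f"LG table has {table.n_missing} missing cell(s); impute first"
        )
    if len(table.location_ids) < 4:
        warnings.warn(
            "fewer than 4 locations: the self-correlation cells (fixed at 1) "
            "may create an artifact suggesting each location is a "
            "mega-environment by itself",
            stacklevel=2,
        )
    settings = ModelSettings(scaling=0, centering=0 if variant == "LG" else 1, svp=2)
    # SVP=2 assigns singular values to columns; run in the locations x trials
    # orientation so the trial vectors carry them, then present trials as rows.
    model = svd_biplot(table.data.T, settings)
    return model.transposed()


def mean_placements(model: BiplotModel) -> pd.DataFrame:
    """Mean (PC1, PC2) of each location's trial markers.

    Model rows must be trial labels of the form ``LOC_YY``; the placement of
    a location is the arithmetic mean of the coordinates of all trials
    conducted there.
    """
    locs = []
    for label in model.row_ids:
        loc, _, yy = label.rpartition("_")
        if not loc or not yy.isdigit():
            raise LabelError(f"row label {label!r} does not parse as LOCATION_YY")
        locs.append(loc)
    coords = pd.DataFrame(model.row_coords, columns=["PC1", "PC2"])
    coords["location"] = locs
    out = coords.groupby("location", sort=True).mean()
    out.index.name = None
    return out


def partition_locations(placements: pd.DataFrame, k: int = 2) -> MegaEnvPartition:
    """Cluster mean placements into k groups by their biplot angles.

    Average-linkage hierarchical clustering on cosine dissimilarity
    (1 - cos of the angle between placement vectors), cut at k clusters —
    the biplot's own similarity semantics, since angles between markers of an
    uncentered correlation biplot reflect correlation. Deterministic: input
    locations are processed in lexicographic order and group labels 1..k are
    assigned in order of first appearance among sorted locations.
    """
    placements = placements.sort_index()
    n = len(placements)
    if k < 1 or k > n:
        raise DimensionError(f"k={k} incompatible with {n} locations")
    x = placements.to_numpy(dtype=float)
    norms = np.linalg.norm(x, axis=1)
    if (norms == 0).any():
        bad = list(placements.index[norms == 0])
        raise DegeneratePlacementError(
            f"zero-length placement vector(s) for {bad}; no direction to cluster"
        )
    if n == 1:
        return MegaEnvPartition(placements, {placements.index[0]: 1}, 1)
    dist = pdist(x, metric="cosine")  # 1 - cosine similarity
    z = linkage(dist, method="average")
    raw = fcluster(z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    groups: dict[str, int] = {}
    for loc, g in zip(placements.index, raw):
        if g not in relabel:
            relabel[g] = len(relabel) + 1
        groups[loc] = relabel[g]
    return MegaEnvPartition(placements, groups, k=len(relabel), linkage_height=z[:, 2])


def within_location_spread(model: BiplotModel, placements: pd.DataFrame) -> pd.Series:
    """Mean distance of each location's trial markers from its mean placement.

    A scalar index of the unrepeatable genotype-by-environment interaction at
    that location: large spread means the location correlates differently
    with the others from year to year.
    """
    coords = pd.DataFrame(model.row_coords, columns=["PC1", "PC2"])
    locs = []
    for label in model.row_ids:
        loc, _, yy = label.rpartition("_")
        if not loc or not yy.isdigit():
            raise LabelError(f"row label {label!r} does not parse as LOCATION_YY")
        locs.append(loc)
    coords["location"] = locs
    out = {}
    for loc, sub in coords.groupby("location"):
        center = placements.loc[loc].to_numpy(dtype=float)
        d = np.linalg.norm(sub[["PC1", "PC2"]].to_numpy() - center, axis=1)
        out[loc] = float(d.mean())
    return pd.Series(out).sort_index()


@dataclass
class LGResult:
    """All artifacts of one end-to-end LG analysis."""

    table: CorrelationTable
    imputed: CorrelationTable
    model: BiplotModel
    placements: pd.DataFrame
    partition: MegaEnvPartition
    spread: pd.Series


def run_lg_pipeline(
    source: TrialSet | CorrelationTable,
    variant: str = "LG",
    k: int = 2,
    rank: int = 2,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> LGResult:
    """End-to-end LG analysis from raw trials or a pre-built table."""
    table = source if isinstance(source, CorrelationTable) else trials_to_lg_table(source)
    imputed = impute_missing(table, rank=rank, tol=tol, max_iter=max_iter)
    model = lg_biplot(imputed, variant=variant)
    placements = mean_placements(model)
    partition = partition_locations(placements, k=k)
    spread = within_location_spread(model, placements)
    return LGResult(table, imputed, model, placements, partition, spread)
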