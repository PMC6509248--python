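"""Rank-2 SVD biplot with standardization codes and singular-value partitioning.

The biplot model approximates a (preprocessed) two-way table P by the first
two terms of its singular value decomposition,

    P_ij ~ (d lam_1^a z_i1)(lam_1^(1-a) t_1j / d)
         + (d lam_2^a z_i2)(lam_2^(1-a) t_2j / d),

where z and t are the left/right singular vectors, lam_k the singular values,
``a`` the singular-value partitioning (SVP) exponent and ``d`` a scalar that
equalizes the longest row and column vectors so both sets of markers occupy a
comparable range of the plot. Inner products between a row marker and a
column marker reproduce the rank-2 approximation of P regardless of SVP and d.

Preprocessing follows the standard coding: Scaling 0/1 = none / divide each
column by its standard deviation; Centering 0/1/2 = none / subtract the grand
mean / subtract column means. "Scaling = 1, Centering = 2" turns columns into
z-scores, after which the cosine of the angle between two column markers of a
column-focused (SVP = 2) biplot approximates their Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CorrelationTable, GEMatrix
from .errors import (
    DegenerateAxisError,
    DegenerateColumnError,
    DimensionError,
    MissingCellsError,
    PreconditionError,
)


@dataclass(frozen=True)
class ModelSettings:
    """Preprocessing and partitioning codes of a biplot model.

    scaling: 0 = none, 1 = divide by column standard deviation (n-1).
    centering: 0 = none, 1 = subtract grand mean, 2 = subtract column means.
    svp: 1 = row-focused (a = 1), 2 = column-focused (a = 0).
    """

    scaling: int = 0
    centering: int = 2
    svp: int = 2

    def __post_init__(self) -> None:
        if self.scaling not in (0, 1):
            raise PreconditionError(f"scaling code must be 0 or 1, got {self.scaling}")
        if self.centering not in (0, 1, 2):
            raise PreconditionError(
                f"centering code must be 0, 1 or 2, got {self.centering}"
            )
        if self.svp not in (1, 2):
            raise PreconditionError(f"svp code must be 1 or 2, got {self.svp}")

    @property
    def alpha(self) -> float:
        """SVP exponent: 1 partitions singular values to rows, 0 to columns."""
        return 1.0 if self.svp == 1 else 0.0


@dataclass
class BiplotModel:
    """Two-PC coordinates of rows and columns plus the full spectrum."""

    row_ids: list[str]
    col_ids: list[str]
    row_coords: np.ndarray  # (n_rows, 2)
    col_coords: np.ndarray  # (n_cols, 2)
    singular_values: np.ndarray  # full spectrum, non-increasing
    d: float
    gof: float
    settings: ModelSettings

    def variance_fractions(self) -> np.ndarray:
        """Fraction of total sum of squares captured by each PC."""
        ss = self.singular_values**2
        total = ss.sum()
        return ss / total if total > 0 else np.zeros_like(ss)

    def scores(self) -> pd.DataFrame:
        """Inner-product reconstruction: the rank-2 approximation of P."""
        return pd.DataFrame(
            self.row_coords @ self.col_coords.T,
            index=self.row_ids,
            columns=self.col_ids,
        )

    def transposed(self) -> "BiplotModel":
        """The same model with the row and column roles swapped."""
        return BiplotModel(
            row_ids=list(self.col_ids),
            col_ids=list(self.row_ids),
            row_coords=self.col_coords.copy(),
            col_coords=self.row_coords.copy(),
            singular_values=self.singular_values.copy(),
            d=self.d,
            gof=self.gof,
            settings=self.settings,
        )


@dataclass
class AEAStats:
    """Mean-vs-stability statistics along the average-environment axis."""

    aea_direction: np.ndarray  # unit 2-vector
    mean_score: pd.Series  # projection of each row on the AEA
    instability: pd.Series  # |orthogonal deviation| from the AEA


def _frame_of(matrix) -> pd.DataFrame:
    if isinstance(matrix, (GEMatrix, CorrelationTable)):
        return matrix.data
    if isinstance(matrix, pd.DataFrame):
        return matrix
    raise TypeError(f"expected GEMatrix, CorrelationTable or DataFrame, got {type(matrix)}")


def _preprocess(df: pd.DataFrame, settings: ModelSettings) -> pd.DataFrame:
    out = df.copy()
    if settings.centering == 2:
        out = out - out.mean(axis=0, skipna=True)
    elif settings.centering == 1:
        out = out - np.nanmean(out.to_numpy())
    if settings.scaling == 1:
        counts = df.notna().sum(axis=0)
        sd = df.std(axis=0, ddof=1, skipna=True)
        bad = counts < 2
        degenerate = (~bad) & ((sd == 0) | sd.isna())
        if bad.any() or degenerate.any():
            cols = list(df.columns[bad | degenerate])
            raise DegenerateColumnError(
                f"column(s) {cols} cannot be scaled: need >= 2 values and "
                "non-zero standard deviation"
            )
        out = out / sd
    return out


def standardize(matrix: GEMatrix, settings: ModelSettings) -> GEMatrix:
    """Apply the Scaling/Centering codes to a genotype-by-environment matrix.

    Column means and standard deviations (n-1 denominator) are computed over
    present cells only; missing cells pass through unchanged.
    """
    return GEMatrix(_preprocess(_frame_of(matrix), settings), year=matrix.year)


def svd_biplot(matrix, settings: ModelSettings) -> BiplotModel:
    """Fit the rank-2 biplot model to a complete two-way table.

    The matrix is preprocessed per ``settings``, decomposed by full SVD, and
    the first two components turned into row/column coordinates with the SVP
    exponent and the d-balancing scalar. A deterministic sign convention is
    applied: each PC is flipped so its largest-magnitude column loading is
    positive (first such column wins ties).
    """
    df = _preprocess(_frame_of(matrix), settings)
    if df.isna().any().any():
        raise MissingCellsError(
            f"matrix has {int(df.isna().sum().sum())} missing cell(s); impute first"
        )
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise DimensionError(f"need at least 2 rows and 2 columns, got {df.shape}")

    x = df.to_numpy(dtype=float)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    for k in range(min(2, len(s))):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0

    alpha = settings.alpha
    lam = s[:2]
    # guard: a rank-1 (or zero) table has lam_2 = 0; 0**0 must act as 1 * 0
    row_raw = u[:, :2] * np.where(lam > 0, lam**alpha, 0.0)
    col_raw = vt[:2].T * np.where(lam > 0, lam ** (1.0 - alpha), 0.0)

    max_row = float(np.max(np.linalg.norm(row_raw, axis=1)))
    max_col = float(np.max(np.linalg.norm(col_raw, axis=1)))
    d = float(np.sqrt(max_col / max_row)) if max_row > 0 and max_col > 0 else 1.0

    total_ss = float(np.sum(s**2))
    gof = float(np.sum(lam**2) / total_ss) if total_ss > 0 else 1.0

    return BiplotModel(
        row_ids=[str(i) for i in df.index],
        col_ids=[str(c) for c in df.columns],
        row_coords=row_raw * d,
        col_coords=col_raw / d,
        singular_values=s.copy(),
        d=d,
        gof=gof,
        settings=settings,
    )


def column_correlation_cosine_check(model: BiplotModel, original) -> pd.DataFrame:
    """Compare column-marker angles with Pearson correlations, pair by pair.

    Valid only for a column-metric-preserving model of column-standardized
    data (scaling=1, centering=2, svp=2), where the cosine of the angle
    between two column vectors approximates their correlation across rows.
    Returns a tidy frame with columns col_a, col_b, cosine, pearson_r.
    """
    s = model.settings
    if (s.scaling, s.centering, s.svp) != (1, 2, 2):
        raise PreconditionError(
            "cosine-correlation check requires scaling=1, centering=2, svp=2; "
            f"model has scaling={s.scaling}, centering={s.centering}, svp={s.svp}"
        )
    df = _frame_of(original)
    if list(df.columns) != model.col_ids:
        raise PreconditionError("original matrix columns do not match the model")
    rows = []
    coords = model.col_coords
    for i in range(len(model.col_ids)):
        for j in range(i + 1, len(model.col_ids)):
            a, b = coords[i], coords[j]
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            cos = float(a @ b / (na * nb)) if na > 0 and nb > 0 else np.nan
            pair = df.iloc[:, [i, j]].dropna()
            r = (
                float(np.corrcoef(pair.iloc[:, 0], pair.iloc[:, 1])[0, 1])
                if len(pair) >= 2
                else np.nan
            )
            rows.append((model.col_ids[i], model.col_ids[j], cos, r))
    return pd.DataFrame(rows, columns=["col_a", "col_b", "cosine", "pearson_r"])


def aea_stats(model: BiplotModel) -> AEAStats:
    """Project rows on the average-environment axis (AEA).

    The AEA points from the origin through the mean of the column markers;
    a row's projection on it is its mean performance over columns (up to the
    biplot scaling) and its orthogonal deviation its instability.
    """
    mean_col = model.col_coords.mean(axis=0)
    norm = float(np.linalg.norm(mean_col))
    if norm == 0.0:
        raise DegenerateAxisError("mean column vector is zero; AEA undefined")
    direction = mean_col / norm
    perp = np.array([-direction[1], direction[0]])
    mean_score = pd.Series(model.row_coords @ direction, index=model.row_ids)
    instability = pd.Series(np.abs(model.row_coords @ perp), index=model.row_ids)
    return AEAStats(aea_direction=direction, mean_score=mean_score, instability=instability)
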