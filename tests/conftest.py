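import numpy as np
import pandas as pd
import pytest

from lgbiplot import (
    GEMatrix,
    TrialRecord,
    TrialSet,
    load_table1_fixture,
)


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture
def small_trials():
    """Three genotypes at two locations over two years, one cell absent."""
    recs = [
        TrialRecord("G1", "L1", 2006, 5.0),
        TrialRecord("G1", "L2", 2006, 7.0),
        TrialRecord("G2", "L1", 2006, 6.0),
        TrialRecord("G2", "L2", 2006, 6.5),
        TrialRecord("G3", "L1", 2006, 4.0),
        TrialRecord("G1", "L1", 2007, 5.5),
        TrialRecord("G1", "L2", 2007, 7.5),
        TrialRecord("G2", "L1", 2007, 6.1),
        TrialRecord("G2", "L2", 2007, 6.4),
        TrialRecord("G3", "L1", 2007, 4.2),
        TrialRecord("G3", "L2", 2007, 5.0),
    ]
    return TrialSet(recs, trait_name="yield")


def random_ge_matrix(rng, n_rows, n_cols, year=None):
    df = pd.DataFrame(
        rng.normal(size=(n_rows, n_cols)),
        index=[f"G{i:03d}" for i in range(n_rows)],
        columns=[f"L{j:02d}" for j in range(n_cols)],
    )
    return GEMatrix(df, year=year)


def near_rank2_standardizable(rng, n_rows=100, n_cols=6, sigma=0.12):
    """Genotype scores in a 2-D latent space, unit-norm column loadings,
    small residual noise: a matrix whose column-standardized biplot captures
    almost all variation (high goodness of fit)."""
    t = rng.normal(size=(n_rows, 2))
    theta = rng.uniform(0, 2 * np.pi, size=n_cols)
    a = np.c_[np.cos(theta), np.sin(theta)]
    x = t @ a.T + rng.normal(0, sigma, size=(n_rows, n_cols))
    return GEMatrix(
        pd.DataFrame(
            x,
            index=[f"G{i:03d}" for i in range(n_rows)],
            columns=[f"L{j:02d}" for j in range(n_cols)],
        )
    )


def rank2_table_with_holes(rng, n_rows=10, n_cols=8, frac_missing=0.15):
    """Exact rank-2 matrix scaled into [-1, 1] with a random identifiable
    missing pattern (every row and column keeps >= 2 observed cells)."""
    u = rng.normal(size=(n_rows, 2))
    v = rng.normal(size=(n_cols, 2))
    x = u @ v.T
    x = x / np.abs(x).max()
    n = x.size
    k = int(round(frac_missing * n))
    while True:
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=k, replace=False)] = True
        mask = mask.reshape(x.shape)
        obs = ~mask
        if obs.sum(axis=0).min() >= 2 and obs.sum(axis=1).min() >= 2:
            break
    holed = pd.DataFrame(x.copy())
    holed.values[mask] = np.nan
    return pd.DataFrame(x), holed, mask
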