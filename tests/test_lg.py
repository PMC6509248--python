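import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from lgbiplot import (
    CorrelationTable,
    GEMatrix,
    ModelSettings,
    assemble_lg_table,
    impute_missing,
    lg_biplot,
    mean_placements,
    partition_locations,
    run_lg_pipeline,
    svd_biplot,
    within_location_spread,
    yearly_correlations,
)
from lgbiplot.errors import (
    DegeneratePlacementError,
    DimensionError,
    MissingCellsError,
    UnimputableError,
)
from lgbiplot.lg import iterative_svd_impute
from .conftest import rank2_table_with_holes


def corr_matrix(values, locs):
    return pd.DataFrame(np.asarray(values, float), index=locs, columns=locs)


class TestYearlyCorrelations:
    def test_proportional_columns_correlate_perfectly(self):
        x = np.arange(1.0, 6.0)
        m = GEMatrix(pd.DataFrame({"A": x, "B": 2 * x}))
        c = yearly_correlations(m)
        assert c.loc["A", "B"] == pytest.approx(1.0)
        assert np.allclose(np.diag(c), 1.0)

    def test_reversed_linear_ranks_give_minus_one(self):
        x = np.arange(1.0, 6.0)
        m = GEMatrix(pd.DataFrame({"A": x, "B": 10 - x}))
        c = yearly_correlations(m)
        assert c.loc["A", "B"] == pytest.approx(-1.0)

    def test_matches_pairwise_pearson_oracle(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(10, 3)), columns=["A", "B", "C"])
        df.iloc[2, 0] = np.nan  # force pairwise-complete computation
        c = yearly_correlations(GEMatrix(df))
        for a in df.columns:
            for b in df.columns:
                if a == b:
                    continue
                pair = df[[a, b]].dropna()
                expected = pearsonr(pair[a], pair[b]).statistic
                assert c.loc[a, b] == pytest.approx(expected, abs=1e-12)

    def test_pairs_with_too_few_shared_genotypes_are_missing(self):
        df = pd.DataFrame({"A": [1.0, 2, 3, 4], "B": [2.0, 1, np.nan, np.nan]})
        c = yearly_correlations(GEMatrix(df))
        assert np.isnan(c.loc["A", "B"])  # only 2 shared genotypes

    def test_sparse_location_warns_and_blanks_row(self):
        df = pd.DataFrame({"A": [1.0, 2, 3, 4], "B": [2.0, np.nan, np.nan, np.nan]})
        with pytest.warns(UserWarning, match="fewer than 3"):
            c = yearly_correlations(GEMatrix(df))
        assert c.loc["B"].isna().all() and c["B"].isna().all()


class TestAssembleLGTable:
    def two_year_tables(self):
        locs = ["A", "B", "C"]
        y1 = corr_matrix([[1, .5, .2], [.5, 1, .1], [.2, .1, 1]], locs)
        y2 = corr_matrix([[1, .4, .3], [.4, 1, .0], [.3, .0, 1]], locs)
        return {2006: y1, 2007: y2}

    def test_complete_design_has_no_missing_cells(self):
        t = assemble_lg_table(self.two_year_tables())
        assert t.data.shape == (6, 3)
        assert t.n_missing == 0
        assert t.trial_ids == ["A_06", "B_06", "C_06", "A_07", "B_07", "C_07"]
        assert t.data.loc["A_06", "B"] == pytest.approx(0.5)
        assert t.data.loc["A_06", "A"] == 1.0

    def test_untested_location_yields_structural_missing(self):
        tables = self.two_year_tables()
        tables[2007] = tables[2007].loc[["A", "B"], ["A", "B"]]
        t = assemble_lg_table(tables)
        assert np.isnan(t.data.loc["A_07", "C"])
        assert not np.isnan(t.data.loc["A_06", "C"])

    def test_single_year_rejected(self):
        with pytest.raises(DimensionError):
            assemble_lg_table({2006: self.two_year_tables()[2006]})

    def test_fixture_cells_reachable_through_assembly_convention(self, table1):
        # the packaged table follows the same labelling convention
        assert table1.data.loc["HEBE3_06", "NORM3"] == pytest.approx(0.870)
        assert table1.data.loc["HEBE3_06", "HEBE3"] == 1.0


class TestImputation:
    def test_complete_table_returned_unchanged(self):
        locs = ["A", "B"]
        data = pd.DataFrame([[1.0, .5], [.5, 1.0]], index=["A_06", "B_06"],
                            columns=locs)
        t = CorrelationTable(data)
        assert impute_missing(t) is t

    def test_exact_rank2_cells_recovered(self):
        rng = np.random.default_rng(1)
        truth, holed, mask = rank2_table_with_holes(rng, 7, 5, frac_missing=0.12)
        out = iterative_svd_impute(holed, rank=2, tol=1e-10, max_iter=2000)
        assert np.abs(out.to_numpy()[mask] - truth.to_numpy()[mask]).max() < 1e-6

    def test_observed_cells_never_modified(self):
        rng = np.random.default_rng(2)
        _, holed, mask = rank2_table_with_holes(rng, 8, 6)
        out = iterative_svd_impute(holed, rank=2)
        obs = ~mask
        assert np.array_equal(out.to_numpy()[obs], holed.to_numpy()[obs])

    def test_imputed_cells_clipped_to_unit_interval(self, table1):
        out = impute_missing(table1)
        assert out.data.to_numpy().min() >= -1.0
        assert out.data.to_numpy().max() <= 1.0
        # observed fixture cells untouched
        obs = table1.data.notna()
        pd.testing.assert_frame_equal(out.data[obs], table1.data[obs])

    def test_empty_row_is_unimputable(self):
        df = pd.DataFrame([[np.nan, np.nan], [0.3, 1.0]])
        with pytest.raises(UnimputableError):
            iterative_svd_impute(df)

    def test_nonconvergence_warns_with_final_delta(self):
        rng = np.random.default_rng(3)
        _, holed, _ = rank2_table_with_holes(rng, 10, 8)
        with pytest.warns(UserWarning, match="did not converge"):
            iterative_svd_impute(holed, rank=2, tol=1e-16, max_iter=3)


class TestLGBiplot:
    def all_ones_table(self, n_locs=3):
        locs = [f"L{j}" for j in range(n_locs)]
        trials = [f"L{j}_{yy}" for yy in ("06", "07") for j in range(n_locs)]
        data = pd.DataFrame(1.0, index=trials, columns=locs)
        return CorrelationTable(data)

    def test_all_ones_table_is_rank_one(self):
        t = self.all_ones_table()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # < 4 locations pitfall warning
            model = lg_biplot(t, variant="LG")
        n, m = t.data.shape
        assert model.singular_values[0] == pytest.approx(np.sqrt(n * m))
        assert model.singular_values[1:] == pytest.approx(0.0, abs=1e-12)
        assert model.gof == pytest.approx(1.0)

    def test_grand_mean_centering_annihilates_constant_table(self):
        t = self.all_ones_table()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = lg_biplot(t, variant="LG1")
        assert np.allclose(model.singular_values, 0.0, atol=1e-12)

    def test_missing_cells_refused(self, table1):
        with pytest.raises(MissingCellsError):
            lg_biplot(table1)

    def test_few_locations_triggers_artifact_warning(self):
        t = self.all_ones_table()
        with pytest.warns(UserWarning, match="artifact"):
            lg_biplot(t, variant="LG")

    def test_settings_echo_matches_variant(self, table1):
        imp = impute_missing(table1)
        lg = lg_biplot(imp, variant="LG")
        lg1 = lg_biplot(imp, variant="LG1")
        assert (lg.settings.scaling, lg.settings.centering, lg.settings.svp) == (0, 0, 2)
        assert (lg1.settings.scaling, lg1.settings.centering, lg1.settings.svp) == (0, 1, 2)

    def test_singular_values_carried_by_trial_vectors(self, table1):
        # trial (row) coordinates are the singular-value-scaled side: their
        # total squared norm equals lam1^2 + lam2^2 up to the d balancing
        imp = impute_missing(table1)
        model = lg_biplot(imp)
        lam = model.singular_values[:2]
        ss_rows = (model.row_coords ** 2).sum(axis=0) * model.d ** 2
        assert np.allclose(ss_rows, lam ** 2, rtol=1e-9)

    def test_inner_products_equal_oracle_rank2_truncation(self, table1):
        imp = impute_missing(table1)
        model = lg_biplot(imp)
        x = imp.data.to_numpy()
        u, s, vt = np.linalg.svd(x)
        oracle = (u[:, :2] * s[:2]) @ vt[:2]
        approx = model.scores().loc[imp.trial_ids, imp.location_ids].to_numpy()
        assert np.abs(approx - oracle).max() < 1e-9

    def test_lg1_equals_lg_of_grand_mean_centered_table(self, table1):
        imp = impute_missing(table1)
        lg1 = lg_biplot(imp, variant="LG1")
        centered = imp.data - imp.data.to_numpy().mean()
        direct = svd_biplot(centered.T, ModelSettings(0, 0, 2)).transposed()
        assert np.allclose(lg1.row_coords, direct.row_coords)
        assert np.allclose(lg1.col_coords, direct.col_coords)


class TestPlacementsAndPartition:
    def model_from(self, coords, labels):
        from lgbiplot.gge import BiplotModel
        n = len(labels)
        return BiplotModel(
            row_ids=labels, col_ids=["X", "Y"],
            row_coords=np.asarray(coords, float),
            col_coords=np.eye(2),
            singular_values=np.array([1.0, 1.0]),
            d=1.0, gof=1.0, settings=ModelSettings(0, 0, 2),
        )

    def test_single_trial_location_placed_at_its_trial(self):
        m = self.model_from([[1.5, -0.5]], ["OTT_08"])
        p = mean_placements(m)
        assert p.loc["OTT"].tolist() == [1.5, -0.5]

    def test_mean_of_two_trials(self):
        m = self.model_from([[1.0, 0.0], [3.0, 2.0]], ["OTT_08", "OTT_09"])
        p = mean_placements(m)
        assert p.loc["OTT"].tolist() == [2.0, 1.0]

    def test_fixture_ott_placement_is_mean_of_its_three_trials(self, table1):
        res = run_lg_pipeline(table1)
        model = res.model
        idx = [model.row_ids.index(t) for t in ("OTT_08", "OTT_09", "OTT_10")]
        expected = model.row_coords[idx].mean(axis=0)
        assert np.allclose(res.placements.loc["OTT"], expected)
        ott_trials = [t for t in model.row_ids if t.startswith("OTT_")]
        assert sorted(ott_trials) == ["OTT_08", "OTT_09", "OTT_10"]

    def test_antipodal_placements_split_into_two_groups(self):
        placements = pd.DataFrame(
            [[1, 0], [0.9, 0.1], [-1, 0], [-0.9, -0.1]],
            index=["A", "B", "C", "D"], columns=["PC1", "PC2"], dtype=float,
        )
        part = partition_locations(placements, k=2)
        assert part.members(part.group_of("A")) == ["A", "B"]
        assert part.members(part.group_of("C")) == ["C", "D"]

    def test_k_equal_n_gives_singletons(self):
        placements = pd.DataFrame(
            [[1, 0], [0, 1], [-1, 0]], index=["A", "B", "C"],
            columns=["PC1", "PC2"], dtype=float,
        )
        part = partition_locations(placements, k=3)
        assert sorted(part.groups.values()) == [1, 2, 3]

    def test_zero_vector_is_degenerate(self):
        placements = pd.DataFrame([[0.0, 0.0], [1.0, 0.0]], index=["A", "B"],
                                  columns=["PC1", "PC2"])
        with pytest.raises(DegeneratePlacementError, match="A"):
            partition_locations(placements, k=2)

    def test_k_larger_than_n_rejected(self):
        placements = pd.DataFrame([[1.0, 0.0]], index=["A"], columns=["PC1", "PC2"])
        with pytest.raises(DimensionError):
            partition_locations(placements, k=2)

    def test_group_labels_are_one_to_k_in_lexicographic_first_appearance(self):
        placements = pd.DataFrame(
            [[-1, 0], [1, 0], [-0.9, 0.1], [0.9, -0.1]],
            index=["Z", "A", "Y", "B"], columns=["PC1", "PC2"], dtype=float,
        )
        part = partition_locations(placements, k=2)
        assert part.group_of("A") == 1  # first sorted location defines group 1
        assert part.group_of("B") == 1
        assert part.group_of("Y") == 2 and part.group_of("Z") == 2


class TestSpread:
    def test_single_trial_location_has_zero_spread(self, table1):
        res = run_lg_pipeline(table1)
        singles = [loc for loc in res.placements.index
                   if sum(t.startswith(f"{loc}_") for t in res.model.row_ids) == 1]
        for loc in singles:
            assert res.spread[loc] == pytest.approx(0.0)

    def test_two_trial_spread_is_mean_distance(self):
        from lgbiplot.gge import BiplotModel
        model = BiplotModel(
            row_ids=["A_06", "A_07"], col_ids=["X", "Y"],
            row_coords=np.array([[0.0, 0.0], [2.0, 0.0]]),
            col_coords=np.eye(2), singular_values=np.array([1.0, 1.0]),
            d=1.0, gof=1.0, settings=ModelSettings(0, 0, 2),
        )
        placements = mean_placements(model)
        spread = within_location_spread(model, placements)
        assert spread["A"] == pytest.approx(1.0)


class TestPipelineDeterminism:
    def test_identical_inputs_give_bit_identical_partitions(self, table1):
        a = run_lg_pipeline(table1)
        b = run_lg_pipeline(table1)
        assert a.partition.groups == b.partition.groups
        assert np.array_equal(a.model.row_coords, b.model.row_coords)
        assert np.array_equal(a.placements.to_numpy(), b.placements.to_numpy())

    def test_noop_imputation_leaves_complete_table_pipeline_unchanged(self):
        locs = [f"L{j}" for j in range(5)]
        rng = np.random.default_rng(4)
        base = rng.normal(size=(5, 2))
        corr = np.corrcoef(np.c_[base, base @ rng.normal(size=(2, 3))].T)[:5, :5]
        data = {}
        for year in (2006, 2007):
            for i, loc in enumerate(locs):
                data[f"{loc}_{year % 100:02d}"] = corr[i]
        df = pd.DataFrame(data, index=locs).T
        t = CorrelationTable(df)
        assert t.is_complete()
        direct = lg_biplot(t)
        via_impute = lg_biplot(impute_missing(t))
        assert np.array_equal(direct.row_coords, via_impute.row_coords)
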