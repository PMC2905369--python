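import numpy as np
import pandas as pd
import pytest

from svdppcs import (
    collapse_probes,
    filter_missing,
    fold_change_filter,
    knn_impute,
    two_way_polish,
)

from conftest import make_matrix


class TestFilterMissing:
    def test_threshold_counts(self, rng):
        # genes with 0,1,3,4,5 missing cells out of 10 arrays
        values = rng.normal(size=(5, 10))
        for i, n_miss in enumerate([0, 1, 3, 4, 5]):
            values[i, :n_miss] = np.nan
        mat = make_matrix(values)
        kept = filter_missing(mat, max_missing=3)
        assert kept.gene_ids == ["g0", "g1", "g2"]

    def test_fraction_variant_matches_count(self, rng):
        values = rng.normal(size=(4, 10))
        values[0, :4] = np.nan
        mat = make_matrix(values)
        by_count = filter_missing(mat, max_missing=3)
        by_frac = filter_missing(mat, max_missing=None, max_missing_frac=0.3)
        assert by_count.gene_ids == by_frac.gene_ids == ["g1", "g2", "g3"]

    def test_all_removed_raises(self):
        values = np.full((2, 4), np.nan)
        values[:, 0] = 1.0
        with pytest.raises(ValueError, match="every gene"):
            filter_missing(make_matrix(values), max_missing=1)

    def test_output_is_row_subset(self, rng):
        values = rng.normal(size=(6, 5))
        values[1, :3] = np.nan
        mat = make_matrix(values)
        kept = filter_missing(mat, max_missing=2)
        assert set(kept.gene_ids) <= set(mat.gene_ids)
        np.testing.assert_array_equal(kept.values, mat.values[[0, 2, 3, 4, 5]])


class TestKnnImpute:
    def test_exact_neighbors(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        values = np.vstack([base, base, base, base])
        values[0, 2] = np.nan
        mat = make_matrix(values)
        out = knn_impute(mat, k=3)
        assert out.values[0, 2] == pytest.approx(3.0)

    def test_single_gene_falls_back_to_row_mean(self):
        mat = make_matrix(np.array([[1.0, np.nan, 3.0]]))
        with pytest.warns(UserWarning, match="row-mean"):
            out = knn_impute(mat, k=2)
        assert out.values[0, 1] == pytest.approx(2.0)

    def test_brute_force_oracle(self, rng):
        values = rng.normal(size=(6, 4))
        values[0, 1] = np.nan
        mat = make_matrix(values)
        out = knn_impute(mat, k=2)
        # oracle: exhaustive distances from gene 0 (observed columns) to the
        # complete rows, plain mean of the 2 closest at the missing column
        obs = [0, 2, 3]
        dists = {i: np.sqrt(((values[i, obs] - values[0, obs]) ** 2).sum()) for i in range(1, 6)}
        nearest = sorted(dists, key=dists.get)[:2]
        expected = values[nearest, 1].mean()
        assert out.values[0, 1] == pytest.approx(expected)

    def test_observed_cells_bit_identical(self, rng):
        values = rng.normal(size=(12, 6))
        mask = rng.random((12, 6)) < 0.15
        mask[:, 0] = False  # keep every row partly observed
        values[mask] = np.nan
        mat = make_matrix(values)
        out = knn_impute(mat, k=3)
        assert not np.isnan(out.values).any()
        np.testing.assert_array_equal(out.values[~mask], values[~mask])


class TestCollapseProbes:
    def test_mean_of_two_probes(self):
        mat = make_matrix(np.array([[1.0, 5.0], [3.0, 7.0]]), gene_ids=["p1", "p2"])
        out = collapse_probes(mat, {"p1": "GENE", "p2": "GENE"})
        assert out.gene_ids == ["GENE"]
        np.testing.assert_allclose(out.values, [[2.0, 6.0]])

    def test_unique_probe_unchanged(self, rng):
        values = rng.normal(size=(2, 3))
        mat = make_matrix(values, gene_ids=["p1", "p2"])
        out = collapse_probes(mat, {"p1": "A", "p2": "B"})
        np.testing.assert_array_equal(out.values, values)

    def test_group_mean_oracle(self, rng):
        values = rng.normal(size=(5, 4))
        mapping = {"p0": "A", "p1": "B", "p2": "A", "p3": "C", "p4": "B"}
        mat = make_matrix(values, gene_ids=list(mapping))
        out = collapse_probes(mat, mapping)
        oracle = pd.DataFrame(values, index=[mapping[p] for p in mapping]).groupby(level=0).mean()
        for g in out.gene_ids:
            np.testing.assert_allclose(
                out.values[out.gene_ids.index(g)], oracle.loc[g].to_numpy()
            )
        assert out.array_labels == mat.array_labels

    def test_unmapped_probe_policies(self, rng):
        mat = make_matrix(rng.normal(size=(2, 3)), gene_ids=["p1", "zzz"])
        with pytest.warns(UserWarning, match="not in mapping"):
            kept = collapse_probes(mat, {"p1": "A"}, unmapped="keep")
        assert kept.gene_ids == ["A", "zzz"]
        dropped = collapse_probes(mat, {"p1": "A"}, unmapped="drop")
        assert dropped.gene_ids == ["A"]


class TestFoldChangeFilter:
    def test_log2_ranges(self, rng):
        # ranges in log2 units: 0.5, 1.0, 1.7 -> two genes reach 2-fold
        rows = [np.linspace(0, r, 6) for r in (0.5, 1.0, 1.7)]
        mat = make_matrix(np.array(rows))
        out = fold_change_filter(mat, min_fold=2.0)
        assert out.gene_ids == ["g1", "g2"]

    def test_constant_gene_removed(self):
        values = np.vstack([np.zeros(5), np.linspace(0, 3, 5)])
        out = fold_change_filter(make_matrix(values), min_fold=2.0)
        assert out.gene_ids == ["g1"]


class TestTwoWayPolish:
    def test_postconditions(self, rng):
        mat = make_matrix(rng.normal(size=(10, 5)))
        out = two_way_polish(mat, iterations=2)
        assert out.polished
        np.testing.assert_allclose(out.values.sum(axis=1), 0.0, atol=1e-8)
        np.testing.assert_allclose((out.values**2).sum(axis=1), 1.0, atol=1e-8)

    def test_single_iteration_matches_sweep_oracle(self, rng):
        values = rng.normal(size=(4, 3))
        out = two_way_polish(make_matrix(values), iterations=1)
        # independent step-by-step computation of the two sweeps
        x = values.copy()
        for j in range(3):
            col = x[:, j]
            x[:, j] = (col - col.mean()) / col.std(ddof=1)
        for i in range(4):
            row = x[i] - x[i].mean()
            x[i] = row / np.sqrt((row**2).sum())
        np.testing.assert_allclose(out.values, x, atol=1e-12)

    def test_near_idempotent_at_convergence(self, rng):
        mat = make_matrix(rng.normal(size=(50, 10)))
        converged = two_way_polish(mat, iterations=30)
        again = two_way_polish(converged, iterations=1)
        assert np.abs(again.values - converged.values).max() < 1e-6

    def test_zero_variance_column_is_named(self, rng):
        values = rng.normal(size=(5, 4))
        values[:, 2] = 7.0
        with pytest.raises(ValueError, match="a2"):
            two_way_polish(make_matrix(values))

    def test_requires_complete_matrix(self, rng):
        values = rng.normal(size=(5, 4))
        values[0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            two_way_polish(make_matrix(values))
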