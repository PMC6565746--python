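"""QC filtering, variable genes, PCA, marker typing and DE counting."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from ploidykit.scrna import (
    QCParams,
    assign_cell_types,
    count_degs,
    differential_expression,
    log_normalize,
    pca_embed,
    qc_filter,
    select_variable_genes,
)
from ploidykit.synth import CountMatrix, CountsSimParams, simulate_counts


def make_matrix(counts, genes=None, barcodes=None, groups=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    barcodes = barcodes or [f"c{i}" for i in range(counts.shape[1])]
    return CountMatrix(
        counts=sparse.csr_matrix(counts), genes=genes, barcodes=barcodes,
        groups=None if groups is None else pd.Series(groups),
    )


def qc_fixture_100_cells():
    """100 cells and 1500 genes built directly against the thresholds:
    10 planted low-gene cells, 5 planted high-mito cells, disjoint."""
    rng = np.random.default_rng(0)
    n_genes, n_cells = 1500, 100
    genes = [f"mt-G{i}" for i in range(10)] + [f"g{i}" for i in range(n_genes - 10)]
    X = np.zeros((n_genes, n_cells), dtype=np.int64)
    for c in range(n_cells):
        if c < 10:  # low-gene: 400 genes detected
            detected = rng.choice(np.arange(10, n_genes), size=400, replace=False)
        else:  # normal: 1200 non-mito genes detected
            detected = rng.choice(np.arange(10, n_genes), size=1200, replace=False)
        X[detected, c] = 1
        total = X[:, c].sum()
        if 10 <= c < 15:  # high-mito: mito share 25 % > 10 %
            X[0, c] = total // 3
        else:  # benign mito share ~2 %
            X[0, c] = max(total // 50, 1)
    return make_matrix(X, genes=genes)


class TestQCFilter:
    def test_all_pass_unchanged(self):
        X = np.ones((6, 5), dtype=int) * 3
        mat = make_matrix(X, genes=["mt-a", "b", "c", "d", "e", "f"])
        filtered, report = qc_filter(
            mat, QCParams(min_genes_per_cell=2, max_mito_fraction=0.5,
                          min_cells_per_gene=2)
        )
        assert filtered.shape == mat.shape
        assert report.n_cells_kept == 5 and report.n_genes_kept == 6

    def test_constructed_fixture_keeps_85(self):
        filtered, report = qc_filter(qc_fixture_100_cells())
        assert report.n_cells_in == 100
        assert report.n_cells_kept == 85
        reasons = report.cell_fail_reasons
        assert reasons["low_genes"].sum() == 10
        assert reasons["high_mito"].sum() == 5
        assert not (reasons["low_genes"] & reasons["high_mito"]).any()

    def test_planted_failures_are_exactly_the_filtered_cells(self):
        mat, truth = simulate_counts(CountsSimParams(n_cells=600, seed=8))
        filtered, report = qc_filter(mat)
        kept = set(filtered.barcodes)
        planted_ok = set(truth.loc[truth["planted_fail"] == "none", "barcode"])
        assert kept == planted_ok

    def test_order_stability_under_cell_permutation(self):
        mat, _ = simulate_counts(CountsSimParams(n_cells=200, seed=9))
        rng = np.random.default_rng(0)
        perm = rng.permutation(mat.shape[1])
        permuted = CountMatrix(
            counts=mat.counts[:, perm],
            genes=mat.genes,
            barcodes=[mat.barcodes[i] for i in perm],
        )
        kept_a, _ = qc_filter(mat)
        kept_b, _ = qc_filter(permuted)
        assert set(kept_a.barcodes) == set(kept_b.barcodes)

    def test_iterative_variant_reaches_fixpoint(self):
        mat, _ = simulate_counts(CountsSimParams(n_cells=200, seed=13))
        single, _ = qc_filter(mat)
        fixed, report = qc_filter(mat, iterate=True)
        # re-applying the filter to the fixpoint changes nothing
        again, _ = qc_filter(fixed)
        assert again.shape == fixed.shape
        assert report.n_cells_kept == fixed.shape[1]
        assert set(fixed.barcodes) <= set(single.barcodes)

    def test_missing_mito_genes_warns_and_skips(self):
        X = np.ones((4, 3), dtype=int) * 5
        mat = make_matrix(X)
        with pytest.warns(UserWarning, match="mitochondrial"):
            _, report = qc_filter(
                mat, QCParams(min_genes_per_cell=2, min_cells_per_gene=1)
            )
        assert report.n_cells_kept == 3


class TestVariableGenes:
    def test_planted_high_variance_recovered(self):
        """Planted bimodal genes against a single-type NB background (a
        clean oracle: no marker/program structure competing for top spots)."""
        params = CountsSimParams(
            n_cells=800, n_variable_planted=50, lowq_fraction=0.0,
            type_proportions={"fibroblast": 1.0, "endothelial": 0.0, "lymphocyte": 0.0},
            seed=10,
        )
        mat, truth = simulate_counts(params)
        # target fraction mirrors a typical droplet workflow (~an eighth of
        # the genome treated as variable)
        top = select_variable_genes(mat, target_count=1000)
        planted = set(truth.attrs["planted_variable_genes"])
        assert len(planted & set(top)) / len(planted) >= 0.95

    def test_constant_genes_never_precede_variable_ones(self):
        rng = np.random.default_rng(1)
        const = np.full((5, 60), 4)
        variable = np.where(rng.random((5, 60)) < 0.5, 1, 20)
        # filler keeps per-cell depth constant so constant genes stay
        # constant after depth normalisation
        filler = 120 - variable.sum(axis=0, keepdims=True)
        mat = make_matrix(np.vstack([const, variable, filler]))
        top = select_variable_genes(mat, target_count=5)
        assert set(top).isdisjoint({f"g{i}" for i in range(5)})

    def test_target_exceeding_genes_warns_and_returns_all(self):
        mat = make_matrix(np.arange(10).reshape(5, 2) + 1)
        with pytest.warns(UserWarning, match="target"):
            top = select_variable_genes(mat, target_count=10)
        assert len(top) == 5


class TestPCA:
    def test_identical_cells_identical_embedding(self):
        rng = np.random.default_rng(2)
        X = rng.poisson(5.0, (40, 30))
        X[:, 7] = X[:, 3]
        mat = make_matrix(X)
        scores, _ = pca_embed(mat, mat.genes, n_components=5)
        np.testing.assert_allclose(scores[3], scores[7], atol=1e-9)

    def test_variance_explained_nonincreasing(self, default_counts):
        (mat, _), _ = default_counts
        genes = select_variable_genes(mat, 300)
        _, pca = pca_embed(mat, genes, n_components=12)
        ev = pca.explained_variance_
        assert np.all(np.diff(ev) <= 1e-9)

    def test_rank_deficient_reduces_with_warning(self):
        X = np.ones((6, 4))
        X[0] = [1, 2, 3, 4]
        mat = make_matrix(X.astype(int))
        with pytest.warns(UserWarning, match="rank"):
            scores, _ = pca_embed(mat, mat.genes, n_components=12)
        assert scores.shape[1] <= 4

    def test_sign_convention_deterministic(self, default_counts):
        (mat, _), _ = default_counts
        genes = select_variable_genes(mat, 200)
        s1, p1 = pca_embed(mat, genes, n_components=6)
        s2, p2 = pca_embed(mat, genes, n_components=6)
        np.testing.assert_array_equal(s1, s2)
        for comp in p1.components_:
            assert comp[np.abs(comp).argmax()] > 0

    def test_embedding_separates_planted_types(self, default_counts):
        from sklearn.metrics import silhouette_score

        (mat, truth), _ = default_counts
        filtered, _ = qc_filter(mat)
        genes = select_variable_genes(filtered, 500)
        scores, _ = pca_embed(filtered, genes, n_components=12)
        types = truth.set_index("barcode").loc[filtered.barcodes, "cell_type"]
        assert silhouette_score(scores, types) > 0.3


class TestCellTyping:
    def test_cd3e_only_cell_is_lymphocyte(self):
        genes = ["Col3a1", "Cd36", "Cd3e", "other"]
        X = np.array([[0], [0], [5], [2]])
        res = assign_cell_types(make_matrix(X, genes=genes))
        assert res.assignments["cell_type"].item() == "lymphocyte"

    def test_all_zero_cell_unassigned(self):
        genes = ["Col3a1", "Cd36", "Cd3e"]
        X = np.array([[3, 0], [0, 0], [0, 0]])
        res = assign_cell_types(make_matrix(X, genes=genes))
        assert res.assignments["cell_type"].tolist() == ["fibroblast", "unassigned"]

    def test_missing_marker_errors(self):
        mat = make_matrix(np.ones((2, 2), dtype=int), genes=["a", "b"])
        with pytest.raises(KeyError, match="Col3a1"):
            assign_cell_types(mat)

    def test_proportions_sum_to_one_per_stratum(self, default_counts):
        (mat, truth), _ = default_counts
        filtered, _ = qc_filter(mat)
        filtered.groups = pd.Series(
            np.where(np.arange(filtered.shape[1]) % 2 == 0, "2N_F", "4N_F")
        )
        res = assign_cell_types(filtered)
        assert sum(res.proportions.values()) == pytest.approx(1.0, abs=1e-9)
        for g, props in res.proportions_by_group.items():
            assert sum(props.values()) == pytest.approx(1.0, abs=1e-9)

    def test_recovers_planted_type_labels(self, default_counts):
        (mat, truth), _ = default_counts
        filtered, _ = qc_filter(mat)
        res = assign_cell_types(filtered)
        planted = truth.set_index("barcode").loc[filtered.barcodes, "cell_type"]
        agree = (res.assignments["cell_type"].to_numpy() == planted.to_numpy()).mean()
        assert agree >= 0.97


class TestDifferentialExpression:
    def _nb_matrix(self, rng, means_a, means_b, n_per_group):
        a = rng.poisson(rng.gamma(2.0, means_a[:, None] / 2.0, (len(means_a), n_per_group)))
        b = rng.poisson(rng.gamma(2.0, means_b[:, None] / 2.0, (len(means_b), n_per_group)))
        X = np.hstack([a, b])
        mat = make_matrix(X)
        ca = mat.barcodes[:n_per_group]
        cb = mat.barcodes[n_per_group:]
        return mat, ca, cb

    def test_null_false_positive_rate(self):
        """Identical distributions in both groups: <= 1 % of genes reach
        adjusted significance (null-simulation oracle)."""
        rng = np.random.default_rng(3)
        means = rng.gamma(2.0, 2.0, 400) + 0.2
        mat, ca, cb = self._nb_matrix(rng, means, means, 200)
        table = differential_expression(mat, ca, cb)
        fp = ((table["p_adj"] < 0.05) & (table["log_fc"].abs() > 0.25)).mean()
        assert fp <= 0.01

    def test_planted_twofold_genes_detected(self):
        rng = np.random.default_rng(4)
        means_a = rng.gamma(2.0, 3.0, 300) + 1.0
        means_b = means_a.copy()
        means_b[:30] *= 2.0
        mat, ca, cb = self._nb_matrix(rng, means_a, means_b, 300)
        table = differential_expression(mat, cb, ca).set_index("gene")
        planted = [f"g{i}" for i in range(30)]
        detected = table.loc[planted, "significant_up_a"].mean()
        assert detected >= 0.90

    def test_constant_gene_p_is_one(self):
        X = np.vstack([np.full(20, 3), np.arange(20)])
        mat = make_matrix(X)
        table = differential_expression(
            mat, mat.barcodes[:10], mat.barcodes[10:]
        ).set_index("gene")
        assert table.loc["g0", "p"] == 1.0

    def test_overlapping_groups_rejected(self):
        mat = make_matrix(np.ones((3, 6), dtype=int))
        with pytest.raises(ValueError, match="overlap"):
            differential_expression(mat, mat.barcodes[:4], mat.barcodes[3:])

    def test_pipeline_determinism(self):
        mat, _ = simulate_counts(CountsSimParams(n_cells=120, seed=12))
        mat.groups = pd.Series(["2N_F"] * 60 + ["4N_F"] * 60)
        up_a1, up_b1, t1 = count_degs(mat, "2N_F", "4N_F")
        up_a2, up_b2, t2 = count_degs(mat, "2N_F", "4N_F")
        assert (up_a1, up_b1) == (up_a2, up_b2)
        pd.testing.assert_frame_equal(t1, t2)


def test_log_normalize_depth_invariance():
    X = np.array([[10, 20], [30, 60]])
    ln = log_normalize(make_matrix(X))
    np.testing.assert_allclose(ln[:, 0], ln[:, 1], rtol=1e-12)
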