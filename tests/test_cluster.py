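import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scortho.cluster import (
    ClusterLabels,
    build_knn_graph,
    cluster_graph,
    composite_composition,
    concat_datasets,
    run_pca,
    transition_table,
)
from scortho.preprocess import ExprMatrix, normalize_log, scale_regress

from conftest import make_counts


def make_expr(values, layer="scaled", gene_ids=None, barcodes=None):
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    gene_ids = gene_ids or [f"G{i}" for i in range(n_genes)]
    barcodes = barcodes or [f"BC{i}" for i in range(n_cells)]
    meta = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    return ExprMatrix(values=values, gene_ids=gene_ids, barcodes=barcodes,
                      cell_meta=meta, layer=layer)


class TestConcat:
    def test_column_concatenation(self):
        a = make_expr(np.ones((10, 5)), barcodes=[f"a{i}" for i in range(5)])
        b = make_expr(np.zeros((10, 5)), barcodes=[f"b{i}" for i in range(5)])
        out = concat_datasets([a, b])
        assert out.values.shape == (10, 10)

    def test_single_input_is_identity(self):
        a = make_expr(np.ones((3, 2)))
        assert concat_datasets([a]) is a

    def test_gene_axis_mismatch_rejected(self):
        a = make_expr(np.ones((2, 2)), gene_ids=["G0", "G1"])
        b = make_expr(np.ones((2, 2)), gene_ids=["G1", "G0"],
                      barcodes=["x0", "x1"])
        with pytest.raises(ValueError, match="gene axes"):
            concat_datasets([a, b])

    def test_barcode_collision_rejected(self):
        a = make_expr(np.ones((2, 2)))
        b = make_expr(np.ones((2, 2)))
        with pytest.raises(ValueError, match="collision"):
            concat_datasets([a, b])


class TestPca:
    def test_rank_one_data_concentrates_variance_in_pc1(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(20, 1))
        v = rng.normal(size=(1, 100))
        e = make_expr(u @ v + 1e-8 * rng.normal(size=(20, 100)))
        res = run_pca(e, 3)
        assert res.explained_variance_ratio[0] > 0.999

    def test_rotation_invariant_spectrum(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10, 60))
        q, _ = np.linalg.qr(rng.normal(size=(10, 10)))
        r1 = run_pca(make_expr(x), 5)
        r2 = run_pca(make_expr(q @ x), 5)
        np.testing.assert_allclose(
            r1.explained_variance_ratio, r2.explained_variance_ratio, atol=1e-8
        )

    def test_separated_blobs_resolved_in_two_pcs(self):
        rng = np.random.default_rng(2)
        centers = np.array([[0, 0], [10, 0], [0, 10]], dtype=float)
        pts = np.vstack([rng.normal(c, 1.0, size=(40, 2)) for c in centers])
        lift = rng.normal(size=(2, 8))
        x = (pts @ lift).T  # 8 genes x 120 cells
        res = run_pca(make_expr(x - x.mean(axis=1, keepdims=True)), 2)
        emb = res.embedding
        labels = np.repeat([0, 1, 2], 40)
        cent = np.array([emb[labels == k].mean(axis=0) for k in range(3)])
        assigned = np.argmin(
            ((emb[:, None, :] - cent[None]) ** 2).sum(-1), axis=1
        )
        assert (assigned == labels).mean() == 1.0

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(3)
        e = make_expr(rng.normal(size=(6, 30)))
        r1, r2 = run_pca(e, 4), run_pca(e, 4)
        np.testing.assert_array_equal(r1.embedding, r2.embedding)
        top = np.abs(r1.components).argmax(axis=1)
        assert (r1.components[np.arange(4), top] > 0).all()

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError, match="n_pcs"):
            run_pca(make_expr(np.ones((3, 4))), 5)


class TestKnnGraph:
    def test_far_blobs_remain_disconnected(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 0.1, size=(20, 3))
        b = rng.normal(50, 0.1, size=(20, 3))
        g = build_knn_graph(np.vstack([a, b]), k=5)
        for e in g.es:
            assert (e.source < 20) == (e.target < 20)

    def test_full_k_gives_complete_graph(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(10, 2))
        g = build_knn_graph(pts, k=9)
        assert g.ecount() == 45

    def test_identical_neighbor_lists_have_weight_one(self):
        from scortho.cluster import snn_jaccard

        assert snn_jaccard({1, 2, 3}, {1, 2, 3}) == 1.0
        assert snn_jaccard({1, 2}, {3, 4}) == 0.0
        assert snn_jaccard({1, 2, 3}, {2, 3, 4}) == pytest.approx(0.5)

    def test_edge_weights_match_neighbor_set_overlap(self):
        # collinear points: hand-checkable neighbor sets at k=2
        pts = np.array([[0.0], [1.0], [2.0], [3.0]])
        g = build_knn_graph(pts, k=2)
        w = {tuple(sorted((e.source, e.target))): e["weight"] for e in g.es}
        # N(0)={1,2}, N(1)={0,2}, N(2)={1,3}, N(3)={1,2} (ties -> lower index)
        assert w[(0, 1)] == pytest.approx(1 / 3)
        assert w[(2, 3)] == pytest.approx(1 / 3)
        # N(1) and N(2) share nothing: the zero-weight edge is pruned
        assert (1, 2) not in w

    def test_k_not_smaller_than_n_rejected(self):
        with pytest.raises(ValueError, match="k must be smaller"):
            build_knn_graph(np.zeros((3, 2)), k=3)


class TestClusterGraph:
    def test_disconnected_cliques_form_two_clusters(self):
        import igraph as ig

        g = ig.Graph.Full(5) + ig.Graph.Full(5)
        g.es["weight"] = [1.0] * g.ecount()
        g.vs["name"] = [f"c{i}" for i in range(10)]
        labels = cluster_graph(g, resolution=0.5, seed=0)
        assert labels.n_clusters == 2
        assert len(set(labels.labels[:5])) == 1
        assert len(set(labels.labels[5:])) == 1

    def test_same_seed_gives_identical_labels(self):
        rng = np.random.default_rng(6)
        pts = np.vstack([rng.normal(c, 1, size=(50, 4)) for c in (0, 8, 16)])
        g = build_knn_graph(pts, k=10)
        l1 = cluster_graph(g, 1.0, seed=3)
        l2 = cluster_graph(g, 1.0, seed=3)
        np.testing.assert_array_equal(l1.labels, l2.labels)

    def test_labels_ordered_by_cluster_size(self):
        import igraph as ig

        g = ig.Graph.Full(3) + ig.Graph.Full(7)
        g.es["weight"] = [1.0] * g.ecount()
        labels = cluster_graph(g, 0.5, seed=0)
        # larger clique gets label 0
        assert set(labels.labels[3:]) == {0}

    def test_empty_graph_rejected(self):
        import igraph as ig

        with pytest.raises(ValueError, match="empty"):
            cluster_graph(ig.Graph(), 1.0, 0)


class TestTransitionTable:
    def test_identity_labeling_is_purely_diagonal(self):
        labels = pd.Series(["x", "y", "x", "z"], index=list("abcd"))
        tm = transition_table(labels, labels)
        np.testing.assert_allclose(np.diag(tm.row_pct), 100.0)
        assert tm.counts.sum() == 4

    def test_hand_computed_split(self):
        a = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        b = pd.Series(["1", "1", "1", "2"], index=list("abcd"))
        tm = transition_table(a, b)
        rp = tm.row_pct_frame()
        assert rp.loc["x", "1"] == 100.0
        assert rp.loc["y", "1"] == 50.0 and rp.loc["y", "2"] == 50.0
        ap = pd.DataFrame(tm.all_pct, index=tm.source_classes, columns=tm.target_classes)
        assert ap.loc["y", "2"] == 25.0

    def test_single_source_class_row_equals_target_frequencies(self):
        a = pd.Series(["only"] * 6, index=list("abcdef"))
        b = pd.Series(["1", "1", "1", "2", "2", "3"], index=list("abcdef"))
        tm = transition_table(a, b)
        np.testing.assert_allclose(tm.row_pct[0], [50, 100 / 3, 100 / 6])

    def test_restricted_to_shared_barcodes(self):
        a = pd.Series(["x", "x"], index=["c1", "c2"])
        b = pd.Series(["1", "1"], index=["c2", "c3"])
        assert transition_table(a, b).counts.sum() == 1

    def test_no_shared_barcodes_rejected(self):
        a = pd.Series(["x"], index=["c1"])
        b = pd.Series(["1"], index=["c9"])
        with pytest.raises(ValueError, match="shared barcodes"):
            transition_table(a, b)

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(
        st.lists(
            st.tuples(st.integers(0, 5), st.integers(0, 5)),
            min_size=1, max_size=200,
        )
    )
    def test_conservation_and_row_sums(self, pairs):
        idx = [f"c{i}" for i in range(len(pairs))]
        a = pd.Series([str(p[0]) for p in pairs], index=idx)
        b = pd.Series([str(p[1]) for p in pairs], index=idx)
        tm = transition_table(a, b)
        assert tm.counts.sum() == len(pairs)
        np.testing.assert_allclose(tm.row_pct.sum(axis=1), 100.0, atol=1e-9)
        assert abs(tm.all_pct.sum() - 100.0) < 1e-9


class TestCompositeComposition:
    def _labels(self, labels):
        return ClusterLabels(
            barcodes=[f"c{i}" for i in range(len(labels))],
            labels=np.asarray(labels), resolution=0.5, seed=0,
        )

    def test_fully_mixed_clusters_give_100_percent(self):
        labels = self._labels([0, 0, 1, 1])
        species = pd.Series(["h", "z", "h", "z"], index=labels.barcodes)
        rep = composite_composition(labels, species)
        assert rep.pct_cells_in_composite == 100.0

    def test_single_species_cluster_excluded_from_percentage(self):
        n = 1000
        labels = self._labels([0] * 950 + [1] * 50)
        species = pd.Series(
            ["h"] * 475 + ["z"] * 475 + ["h"] * 50,
            index=[f"c{i}" for i in range(n)],
        )
        rep = composite_composition(labels, species)
        assert rep.pct_cells_in_composite == pytest.approx(95.0)
        assert not rep.per_cluster.loc[rep.per_cluster["cluster"] == 1, "composite"].item()

    def test_unreachable_threshold_gives_zero(self):
        labels = self._labels([0, 0, 1, 1])
        species = pd.Series(["h", "z", "h", "z"], index=labels.barcodes)
        rep = composite_composition(labels, species, min_cells_per_species=5)
        assert rep.pct_cells_in_composite == 0.0

    def test_single_species_dataset_warns(self):
        labels = self._labels([0, 0])
        species = pd.Series(["h", "h"], index=labels.barcodes)
        with pytest.warns(UserWarning, match="single-species"):
            rep = composite_composition(labels, species)
        assert rep.pct_cells_in_composite == 0.0

    def test_species_counts_sum_to_cluster_sizes(self):
        rng = np.random.default_rng(8)
        labs = rng.integers(0, 4, 200)
        labels = self._labels(labs)
        species = pd.Series(
            rng.choice(["h", "z"], 200), index=labels.barcodes
        )
        rep = composite_composition(labels, species)
        per = rep.per_cluster
        assert (per[["n_h", "n_z"]].sum(axis=1) == per["n_cells"]).all()
        assert per["fraction_of_cells"].sum() == pytest.approx(1.0)
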