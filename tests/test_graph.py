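import numpy as np
import pandas as pd
import pytest
from oracles import exact_svd_mnn_pairs

import cofembed as cf
from cofembed import CellFeatureMatrix, GenomicAnnotation


def _disc(dense, n_levels):
    m = CellFeatureMatrix.from_dense(dense, layer="discretized")
    m.meta["n_levels"] = n_levels
    return m


# ---------------------------------------------------------------------------
# RNA graph
# ---------------------------------------------------------------------------


def test_expression_level_relations_span_one_to_five():
    disc = _disc([[1, 0, 3], [5, 2, 4]], n_levels=5)
    g = cf.build_rna_graph(disc)
    weights = sorted(r.weight for r in g.relations.values())
    assert weights == [1.0, 2.0, 3.0, 4.0, 5.0]
    # zero entries contribute no edge
    assert g.n_edges == 5
    src, dst, w = g.edges("cell_expresses_gene_lv3")
    assert (src.tolist(), dst.tolist()) == ([0], [2])
    assert w.tolist() == [3.0]


def test_weighted_mode_uses_values_as_edge_weights():
    m = CellFeatureMatrix.from_dense([[0.5, 0.0], [1.25, 2.0]], layer="normalized")
    g = cf.build_rna_graph(m, add_edge_weights=True)
    assert len(g.relations) == 1
    (rel,) = g.relations.values()
    assert rel.weight == 1.0
    src, dst, w = g.edges(rel.name)
    assert len(src) == m.values.nnz
    assert sorted(w.tolist()) == [0.5, 1.25, 2.0]


def test_empty_matrix_is_rejected():
    with pytest.raises(ValueError, match="no non-zero"):
        cf.build_rna_graph(_disc(np.zeros((2, 2)), 5))


# ---------------------------------------------------------------------------
# ATAC graph
# ---------------------------------------------------------------------------


def _binary(dense, kind="peak"):
    return CellFeatureMatrix.from_dense(dense, feature_kind=kind, layer="binarized")


def test_accessibility_relation_weights_and_edge_counts():
    peaks = _binary([[1, 0, 1], [0, 1, 1]])
    kmers = CellFeatureMatrix(
        np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]),
        cell_ids=peaks.feature_ids,
        feature_ids=["AAA", "CCC"],
        feature_kind="kmer",
        layer="binarized",
    )
    motifs = CellFeatureMatrix(
        np.array([[1.0], [0.0], [0.0]]),
        cell_ids=peaks.feature_ids,
        feature_ids=["M1"],
        feature_kind="motif",
        layer="binarized",
    )
    g = cf.build_atac_graph(peaks, kmers=kmers, motifs=motifs)
    by_name = {r.name: r.weight for r in g.relations.values()}
    assert by_name["cell_open_peak"] == 1.0
    assert by_name["peak_contains_kmer"] == 0.02
    assert by_name["peak_contains_motif"] == 0.2
    assert g.n_edges == peaks.values.nnz + kmers.values.nnz + motifs.values.nnz


def test_sequence_matrix_with_unknown_peaks_is_rejected():
    peaks = _binary([[1, 1]])
    bad = CellFeatureMatrix(
        np.array([[1.0]]),
        cell_ids=["stranger"],
        feature_ids=["AAA"],
        feature_kind="kmer",
        layer="binarized",
    )
    with pytest.raises(ValueError, match="unknown peaks"):
        cf.build_atac_graph(peaks, kmers=bad)


def test_graph_without_sequences_has_two_entity_types():
    g = cf.build_atac_graph(_binary([[1, 0], [1, 1]]))
    assert set(g.entity_types) == {"cell", "peak"}


# ---------------------------------------------------------------------------
# combination
# ---------------------------------------------------------------------------


def test_batches_share_genes_but_not_cells():
    d1 = _disc([[1, 2]], 2)
    d2 = CellFeatureMatrix.from_dense(
        [[2, 1]], cell_ids=["other"], layer="discretized"
    )
    d2.meta["n_levels"] = 2
    g1 = cf.build_rna_graph(d1, cell_type_name="cell_batch0")
    g2 = cf.build_rna_graph(d2, cell_type_name="cell_batch1")
    combined = cf.combine_graphs(
        [g1, g2],
        link_edges=("cell_batch0", "cell_batch1", [("cell0", "other")]),
    )
    assert combined.n_entities("gene") == 2
    assert combined.n_entities("cell_batch0") == 1
    assert combined.n_entities("cell_batch1") == 1
    assert combined.n_edges == g1.n_edges + g2.n_edges + 1


def test_id_collision_across_types_is_rejected():
    d = _disc([[1]], 2)
    g1 = cf.build_rna_graph(d, cell_type_name="cellsA")
    g2 = cf.build_rna_graph(d, cell_type_name="cellsB")  # same cell ids, new type
    with pytest.raises(ValueError, match="appears in both"):
        cf.combine_graphs([g1, g2])


def test_multiome_combines_expression_and_accessibility_over_shared_cells():
    disc = _disc([[1, 2], [2, 0]], 2)
    peaks = CellFeatureMatrix.from_dense(
        [[1, 0, 1], [0, 1, 1]],
        feature_ids=["p1", "p2", "p3"],
        feature_kind="peak",
        layer="binarized",
    )
    g = cf.combine_graphs([cf.build_rna_graph(disc), cf.build_atac_graph(peaks)])
    assert set(g.entity_types) == {"cell", "gene", "peak"}
    assert g.n_entities("cell") == 2
    assert g.n_edges == 3 + 4


def test_serialization_round_trip(tmp_path):
    disc = _disc([[1, 2], [2, 1]], 2)
    g = cf.build_rna_graph(disc)
    g.save(tmp_path / "g")
    back = cf.MultiRelationGraph.load(tmp_path / "g")
    pd.testing.assert_frame_equal(
        g.edge_table().sort_values(["relation", "source_id", "dest_id"]).reset_index(drop=True),
        back.edge_table().sort_values(["relation", "source_id", "dest_id"]).reset_index(drop=True),
    )
    assert {t: et.is_fixed for t, et in back.entity_types.items()} == {
        t: et.is_fixed for t, et in g.entity_types.items()
    }


def test_hub_is_the_largest_batch():
    assert cf.hub_batch({"a": 10, "b": 30, "c": 20}) == "b"


# ---------------------------------------------------------------------------
# inferred cell-cell edges
# ---------------------------------------------------------------------------


def _clustered(rng, n, m, n_groups=4, scale=3.0):
    centers = rng.normal(0, scale, size=(n_groups, m))
    labels = np.arange(n) % n_groups  # balanced groups: robust margins
    return centers[labels] + rng.normal(0, 0.3, size=(n, m))


def test_identical_datasets_link_every_cell_to_itself():
    rng = np.random.default_rng(0)
    X = _clustered(rng, 30, 25)
    pairs = cf.infer_edges(X, X, d=10, k=5, seed=0)
    got = set(pairs)
    assert all((i, i) in got for i in range(30))


def test_mutuality_of_inferred_pairs():
    rng = np.random.default_rng(1)
    X1 = _clustered(rng, 40, 30)
    X2 = _clustered(rng, 35, 30)
    pairs = cf.infer_edges(X1, X2, d=10, k=8, seed=0)
    # recompute neighbor sets directly from the factorization oracle
    oracle = set(exact_svd_mnn_pairs(X1, X2, d=10, k=8))
    assert set(pairs) == oracle


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_randomized_factorization_matches_exact_oracle(seed):
    rng = np.random.default_rng(seed)
    X1 = _clustered(rng, 60, 40)
    X2 = _clustered(rng, 60, 40)
    pairs = cf.infer_edges(X1, X2, d=20, k=10, seed=seed)
    assert set(pairs) == set(exact_svd_mnn_pairs(X1, X2, d=20, k=10))


def test_inferred_pairs_are_invariant_to_row_order_of_second_dataset():
    rng = np.random.default_rng(9)
    X1 = _clustered(rng, 40, 30)
    X2 = _clustered(rng, 36, 30)
    perm = rng.permutation(36)
    base = set(cf.infer_edges(X1, X2, d=10, k=6, seed=0))
    shuffled = cf.infer_edges(X1, X2[perm], d=10, k=6, seed=0)
    relabeled = {(i, int(perm[j])) for i, j in shuffled}
    assert relabeled == base


def test_too_few_shared_features_advises_smaller_d():
    with pytest.raises(ValueError, match="smaller d"):
        cf.infer_edges(np.ones((5, 3)), np.ones((5, 3)), d=20)


def test_inferred_pairs_use_cell_ids_for_matrices(small_multiome):
    rna = small_multiome[0]
    norm = cf.normalize_rna(rna)
    pairs = cf.infer_edges(norm, norm, d=10, k=3, seed=0)
    ids = set(norm.cell_ids)
    assert all(a in ids and b in ids for a, b in pairs)


# ---------------------------------------------------------------------------
# gene activity scores
# ---------------------------------------------------------------------------


def _single_gene_ann(peaks, start=10_000, end=12_000, strand="+"):
    genes = pd.DataFrame(
        {
            "gene_id": ["g"],
            "chrom": ["chr1"],
            "start": [start],
            "end": [end],
            "strand": [strand],
        }
    )
    return GenomicAnnotation(genes=genes, peaks=pd.DataFrame(peaks))


def _peak_matrix(peak_ids, values):
    return CellFeatureMatrix(
        np.asarray(values, dtype=float),
        cell_ids=[f"c{i}" for i in range(np.asarray(values).shape[0])],
        feature_ids=peak_ids,
        feature_kind="peak",
        layer="binarized",
    )


def test_body_overlap_scores_exactly_one():
    ann = _single_gene_ann(
        {"peak_id": ["p"], "chrom": ["chr1"], "start": [11_000], "end": [11_200]}
    )
    scores = cf.gene_scores(_peak_matrix(["p"], [[1.0]]), ann)
    assert scores.to_dense()[0, 0] == pytest.approx(1.0, abs=1e-12)


def test_distance_decay_at_five_kilobases():
    # + strand gene, TSS at 10_000; peak midpoint at 15_000 (outside the
    # body [10_000, 12_000) and the upstream flank): weight e^{-1}
    ann = _single_gene_ann(
        {"peak_id": ["p"], "chrom": ["chr1"], "start": [14_900], "end": [15_100]}
    )
    scores = cf.gene_scores(_peak_matrix(["p"], [[1.0]]), ann)
    assert scores.to_dense()[0, 0] == pytest.approx(np.exp(-1.0), abs=1e-12)


def test_strand_aware_upstream_flank_scores_one():
    # - strand gene: upstream is to the right of the body
    ann = _single_gene_ann(
        {"peak_id": ["p"], "chrom": ["chr1"], "start": [12_100], "end": [12_300]},
        strand="-",
    )
    scores = cf.gene_scores(_peak_matrix(["p"], [[1.0]]), ann)
    assert scores.to_dense()[0, 0] == pytest.approx(1.0, abs=1e-12)


def test_peaks_beyond_the_window_contribute_nothing():
    ann = _single_gene_ann(
        {"peak_id": ["p"], "chrom": ["chr1"], "start": [159_000], "end": [161_000]}
    )
    scores = cf.gene_scores(_peak_matrix(["p"], [[1.0]]), ann)
    assert scores.to_dense()[0, 0] == 0.0


def test_scores_are_linear_in_peak_counts():
    ann = _single_gene_ann(
        {
            "peak_id": ["a", "b"],
            "chrom": ["chr1", "chr1"],
            "start": [11_000, 14_900],
            "end": [11_200, 15_100],
        }
    )
    m1 = _peak_matrix(["a", "b"], [[1.0, 0.0]])
    m2 = _peak_matrix(["a", "b"], [[0.0, 1.0]])
    both = _peak_matrix(["a", "b"], [[1.0, 1.0]])
    s1 = cf.gene_scores(m1, ann).to_dense()
    s2 = cf.gene_scores(m2, ann).to_dense()
    sb = cf.gene_scores(both, ann).to_dense()
    np.testing.assert_allclose(sb, s1 + s2, atol=1e-12)


def test_gene_size_scaling_divides_by_relative_body_length():
    genes = pd.DataFrame(
        {
            "gene_id": ["short", "long"],
            "chrom": ["chr1", "chr1"],
            "start": [10_000, 500_000],
            "end": [12_000, 508_000],
            "strand": ["+", "+"],
        }
    )
    peaks = pd.DataFrame(
        {
            "peak_id": ["pa", "pb"],
            "chrom": ["chr1", "chr1"],
            "start": [11_000, 501_000],
            "end": [11_200, 501_200],
        }
    )
    ann = GenomicAnnotation(genes=genes, peaks=peaks)
    m = _peak_matrix(["pa", "pb"], [[1.0, 1.0]])
    scores = cf.gene_scores(m, ann).to_dense()[0]
    # median body = 5000: short gene scaled up (1/0.4), long scaled down (1/1.6)
    assert scores[0] == pytest.approx(1 / (2000 / 5000), abs=1e-12)
    assert scores[1] == pytest.approx(1 / (8000 / 5000), abs=1e-12)


# ---------------------------------------------------------------------------
# null features
# ---------------------------------------------------------------------------


def test_null_nodes_preserve_the_degree_multiset(small_multiome):
    rna = small_multiome[0]
    disc, _ = cf.discretize(cf.normalize_rna(rna))
    g = cf.build_rna_graph(disc)
    out = cf.add_null_features(g, "gene", multiplier=3, seed=0)
    null_deg = out.degrees("null_gene")
    real_deg = g.degrees("gene")
    assert sorted(null_deg.tolist()) == sorted(np.tile(real_deg, 3).tolist())
    assert out.entity_types["null_gene"].is_fixed
    assert out.n_entities("null_gene") == 3 * g.n_entities("gene")
    # real cells and genes untouched
    np.testing.assert_array_equal(out.degrees("gene"), real_deg)


def test_fractional_multiplier_and_validation(small_multiome):
    rna = small_multiome[0]
    disc, _ = cf.discretize(cf.normalize_rna(rna))
    g = cf.build_rna_graph(disc)
    out = cf.add_null_features(g, "gene", multiplier=1.5, seed=1)
    assert out.n_entities("null_gene") == int(round(1.5 * g.n_entities("gene")))
    with pytest.raises(ValueError, match="multiplier"):
        cf.add_null_features(g, "gene", multiplier=0)
    with pytest.raises(ValueError, match="unknown entity type"):
        cf.add_null_features(g, "nope", multiplier=2)
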