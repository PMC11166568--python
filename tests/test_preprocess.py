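import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from oracles import optimal_1d_kmeans_assignments

import cofembed as cf
from cofembed import CellFeatureMatrix
from cofembed.preprocess import kmeans_1d, _knee_index


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def test_normalization_is_invariant_to_per_cell_scaling():
    rng = np.random.default_rng(0)
    base = rng.poisson(2.0, size=(1, 30)).astype(float) + 1
    m = CellFeatureMatrix.from_dense(np.vstack([base, 2 * base, 7 * base]))
    out = cf.normalize_rna(m)
    dense = out.to_dense()
    np.testing.assert_allclose(dense[0], dense[1], rtol=1e-12)
    np.testing.assert_allclose(dense[0], dense[2], rtol=1e-12)


def test_equal_totals_reduce_to_log1p():
    m = CellFeatureMatrix.from_dense([[1, 3], [2, 2], [0, 4]])
    out = cf.normalize_rna(m)
    np.testing.assert_allclose(out.to_dense(), np.log1p(m.to_dense()), rtol=1e-12)


def test_normalization_preserves_within_cell_rank_order():
    rng = np.random.default_rng(1)
    m = CellFeatureMatrix.from_dense(rng.poisson(3.0, size=(5, 40)) + 1.0)
    out = cf.normalize_rna(m)
    for raw_row, norm_row in zip(m.to_dense(), out.to_dense()):
        np.testing.assert_array_equal(np.argsort(raw_row), np.argsort(norm_row))


def test_zero_count_cell_is_named_in_error():
    m = CellFeatureMatrix.from_dense([[1, 2], [0, 0]], cell_ids=["good", "empty"])
    with pytest.raises(ValueError, match="empty"):
        cf.normalize_rna(m)


# ---------------------------------------------------------------------------
# low-presence filtering
# ---------------------------------------------------------------------------


def test_presence_filter_boundary_at_three_cells():
    # one gene seen in 2 cells, one in exactly 3: default threshold keeps only the latter
    dense = np.zeros((4, 2))
    dense[:2, 0] = 1.0
    dense[:3, 1] = 1.0
    m = CellFeatureMatrix.from_dense(dense, feature_ids=["twice", "thrice"])
    out = cf.filter_low_presence(m)
    assert list(out.feature_ids) == ["thrice"]
    assert out.n_cells == 4


def test_presence_filter_zero_threshold_is_identity():
    m = CellFeatureMatrix.from_dense(np.eye(3))
    assert cf.filter_low_presence(m, min_cells=0) is m
    with pytest.raises(ValueError, match="nothing left"):
        cf.filter_low_presence(m, min_cells=5)


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------


def test_two_well_separated_groups_split_cleanly():
    m = CellFeatureMatrix.from_dense([[1, 1, 1], [5, 5, 5]], layer="normalized")
    disc, model = cf.discretize(m, n_levels=2)
    np.testing.assert_array_equal(disc.to_dense(), [[1, 1, 1], [2, 2, 2]])
    np.testing.assert_allclose(model.centers, [1.0, 5.0])


def test_degenerate_input_suggests_fewer_levels():
    m = CellFeatureMatrix.from_dense([[2, 2], [2, 0]], layer="normalized")
    with pytest.raises(ValueError, match="n_levels"):
        cf.discretize(m, n_levels=2)


def test_default_uses_five_levels(small_multiome):
    rna = small_multiome[0]
    disc, model = cf.discretize(cf.normalize_rna(rna))
    assert model.n_levels == 5
    levels = np.unique(disc.values.data)
    assert levels.min() >= 1 and levels.max() == 5


def test_zeros_stay_zero_and_ties_go_to_lower_level():
    m = CellFeatureMatrix.from_dense([[0, 1, 2, 3, 4]], layer="normalized")
    disc, model = cf.discretize(m, n_levels=2)
    assert disc.to_dense()[0, 0] == 0
    # a value exactly on a boundary maps to the lower level
    b = model.boundaries[0]
    assert model.assign(np.array([b]))[0] == 1
    assert model.assign(np.array([np.nextafter(b, np.inf)]))[0] == 2


@pytest.mark.parametrize("n_levels", [2, 3, 5])
def test_discretization_is_optimal_against_naive_dp(n_levels):
    rng = np.random.default_rng(42)
    for _ in range(20):
        n = int(rng.integers(n_levels + 1, 120))
        values = np.round(rng.gamma(2.0, 2.0, size=n), 3) + 0.01
        if len(np.unique(values)) < n_levels:
            continue
        centers, boundaries = kmeans_1d(values, n_levels)
        model = cf.DiscretizationModel(n_levels, boundaries, centers)
        got = model.assign(values)
        expected = optimal_1d_kmeans_assignments(values, n_levels)
        np.testing.assert_array_equal(got, expected)


# ---------------------------------------------------------------------------
# variable features
# ---------------------------------------------------------------------------


def test_planted_high_variance_genes_dominate_selection():
    rng = np.random.default_rng(3)
    n_cells, flat, hot = 200, 500, 20
    # flat genes: constant within each gene (zero dispersion), varied means
    X = np.tile(rng.uniform(1.0, 10.0, size=flat + hot), (n_cells, 1))
    hot_cols = rng.choice(flat + hot, size=hot, replace=False)
    X[:, hot_cols] = np.abs(rng.normal(5.0, 3.0, size=(n_cells, hot)))
    m = CellFeatureMatrix.from_dense(X, layer="normalized")
    sel = cf.select_variable_genes(m, n_top=20)
    hot_ids = set(m.feature_ids[hot_cols])
    assert len(set(sel.selected_ids) & hot_ids) >= 18
    assert set(sel.selected_ids) <= set(m.feature_ids)


def test_constant_genes_are_never_selected():
    rng = np.random.default_rng(4)
    X = rng.random((50, 10))
    X[:, 0] = 3.0  # constant gene
    m = CellFeatureMatrix.from_dense(X, layer="normalized")
    sel = cf.select_variable_genes(m, n_top=10)
    assert m.feature_ids[0] not in set(sel.selected_ids)
    flat = CellFeatureMatrix.from_dense(np.full((5, 4), 2.0), layer="normalized")
    with pytest.warns(UserWarning, match="constant"):
        empty = cf.select_variable_genes(flat)
    assert len(empty.selected_ids) == 0


def test_variable_peak_selection_finds_dominant_loading():
    rng = np.random.default_rng(5)
    n_cells = 60
    X = (rng.random((n_cells, 30)) < 0.05).astype(float)
    # one peak perfectly tracks a two-group structure: dominant loading
    group = np.repeat([0.0, 1.0], n_cells // 2)
    X[:, 7] = group
    m = CellFeatureMatrix.from_dense(X, feature_kind="peak", layer="binarized")
    sel = cf.select_variable_peaks(m, seed=0)
    assert "feat7" in set(sel.selected_ids)
    assert sel.n_components_used >= 1
    assert len(sel.selected_ids) == len(set(sel.selected_ids))


def test_knee_of_flat_curve_is_undefined():
    assert _knee_index(np.full(10, 3.0)) is None
    # one dominant value: the knee sits right after it
    y = np.array([10.0, 0.1, 0.09, 0.08, 0.07, 0.06])
    assert _knee_index(y) == 1


def test_variable_selection_is_reproducible(small_multiome):
    rna = small_multiome[0]
    norm = cf.normalize_rna(rna)
    a = cf.select_variable_genes(norm, n_top=20)
    b = cf.select_variable_genes(norm, n_top=20)
    np.testing.assert_array_equal(a.selected_ids, b.selected_ids)
    atac = small_multiome[1]
    pa = cf.select_variable_peaks(cf.binarize(atac), seed=3)
    pb = cf.select_variable_peaks(cf.binarize(atac), seed=3)
    np.testing.assert_array_equal(pa.selected_ids, pb.selected_ids)


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_binarize_is_idempotent_and_preserves_support(seed):
    rng = np.random.default_rng(seed)
    m = CellFeatureMatrix.from_dense(rng.poisson(0.5, size=(6, 8)).astype(float))
    b = cf.binarize(m)
    assert set(np.unique(b.to_dense())) <= {0.0, 1.0}
    assert b.values.nnz == m.values.nnz
    np.testing.assert_array_equal(cf.binarize(b).to_dense(), b.to_dense())


# ---------------------------------------------------------------------------
# sequence features
# ---------------------------------------------------------------------------


def test_exact_kmer_match_single_column():
    kmers, motifs = cf.scan_sequence_features({"p1": "GATAAG"}, k=6)
    assert list(kmers.feature_ids) == ["GATAAG"]
    assert kmers.to_dense().tolist() == [[1.0]]
    assert motifs is None


def test_short_and_repeated_sequences():
    kmers, _ = cf.scan_sequence_features({"short": "ACGT", "rep": "ACACAC"}, k=6)
    assert kmers.to_dense()[0].sum() == 0  # shorter than k: zero row
    kmers2, _ = cf.scan_sequence_features({"rep": "GATAAGGATAAG"}, k=6)
    # presence, not count: the repeated k-mer is still a single 1
    assert kmers2.to_dense().max() == 1.0
    assert "GATAAG" in set(kmers2.feature_ids)


def test_non_acgt_windows_are_skipped():
    kmers, _ = cf.scan_sequence_features({"p": "GATNAGGGGGG"}, k=6)
    assert "GATNAG" not in set(kmers.feature_ids)
    assert "GGGGGG" in set(kmers.feature_ids)


def test_reverse_complement_merging():
    kmers, _ = cf.scan_sequence_features({"p": "GATAAG"}, k=6, include_revcomp=True)
    # canonical form is the lexicographic minimum of the pair
    assert list(kmers.feature_ids) == [min("GATAAG", "CTTATC")]


def test_pwm_scan_detects_planted_consensus():
    pwm = np.asarray(cf.consensus_pwm("GATAAG"))
    seqs = {"hit": "CCCCGATAAGCCCC", "miss": "CCCCCCCCCCCCCC"}
    _, motifs = cf.scan_sequence_features(seqs, k=6, pwms={"M1": pwm})
    assert motifs.to_dense().tolist() == [[1.0], [0.0]]
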