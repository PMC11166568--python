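import numpy as np
import pytest
from scipy.stats import spearmanr

import cofembed as cf
from cofembed import CellFeatureMatrix
from cofembed.embedding import (
    EmbeddingConfig,
    LossSample,
    edge_loss,
    evaluate_link_prediction,
    sample_negatives,
    split_edges,
)


def _rna_graph(dense, n_levels=2, **kw):
    m = CellFeatureMatrix.from_dense(dense, layer="discretized", **kw)
    m.meta["n_levels"] = n_levels
    return cf.build_rna_graph(m)


def _random_graph(rng, n_cells=40, n_genes=30, density=0.3):
    dense = (rng.random((n_cells, n_genes)) < density).astype(float)
    dense[0, 0] = 1.0  # ensure non-empty
    return _rna_graph(dense, n_levels=1)


# ---------------------------------------------------------------------------
# edge splitting
# ---------------------------------------------------------------------------


def test_split_produces_exact_fraction_and_partition():
    rng = np.random.default_rng(0)
    g = _random_graph(rng, 50, 40, 0.5)  # about 1000 edges
    n = g.n_edges
    train, ev = split_edges(g, eval_fraction=0.05, seed=0)
    assert len(ev) == int(round(0.05 * n))
    assert len(train) + len(ev) == n
    keys = lambda e: set(zip(e.src.tolist(), e.dst.tolist()))
    assert keys(train) | keys(ev) == keys(train) ^ keys(ev) | (keys(train) & keys(ev))
    assert not (keys(train) & keys(ev))


def test_split_fraction_zero_keeps_all_edges_for_training():
    g = _rna_graph([[1, 2], [2, 1]])
    train, ev = split_edges(g, eval_fraction=0.0, seed=1)
    assert len(ev) == 0 and len(train) == g.n_edges


def test_every_relation_keeps_a_training_edge():
    # one relation has a single edge; a 50% split must give it back
    g = _rna_graph([[1, 1, 2]])
    for seed in range(5):
        train, _ = split_edges(g, eval_fraction=0.5, seed=seed)
        assert (train.rel == 1).sum() >= 1  # the lv2 relation


# ---------------------------------------------------------------------------
# negative sampling
# ---------------------------------------------------------------------------


def test_candidates_respect_type_constraints():
    rng = np.random.default_rng(2)
    g = _random_graph(rng, 30, 20, 0.4)
    train, _ = split_edges(g, 0.0, 0)
    cfg = EmbeddingConfig(seed=0)
    sample = sample_negatives(
        (train.src[0], train.dst[0], train.rel[0], train.w[0]),
        train,
        cfg,
        np.random.default_rng(0),
    )
    assert sample.n_negatives == 200
    flat = train.flat
    cell_lo, cell_hi = flat.type_range["cell"]
    gene_lo, gene_hi = flat.type_range["gene"]
    for ent, replaces_src in zip(sample.neg_entities, sample.neg_replaces_source):
        if replaces_src:
            assert cell_lo <= ent < cell_hi
        else:
            assert gene_lo <= ent < gene_hi


def test_zero_degree_entities_never_appear_in_the_degree_half():
    # gene column 0 has no edges at all
    dense = np.ones((10, 5))
    dense[:, 0] = 0.0
    g = _rna_graph(dense, n_levels=1)
    train, _ = split_edges(g, 0.0, 0)
    cfg = EmbeddingConfig(seed=0, n_neg_uniform=1, n_neg_degree=400)
    rng = np.random.default_rng(3)
    sample = sample_negatives(
        (train.src[0], train.dst[0], train.rel[0], train.w[0]), train, cfg, rng
    )
    gene_lo, _ = train.flat.type_range["gene"]
    degree_half = sample.neg_entities[1:]
    assert not np.any(degree_half == gene_lo + 0)


# ---------------------------------------------------------------------------
# loss closed forms
# ---------------------------------------------------------------------------


def _manual_sample(theta_rows, pos, negs, sides, weight=1.0):
    return LossSample(
        src=pos[0],
        dst=pos[1],
        rel=0,
        weight=weight,
        neg_entities=np.asarray(negs),
        neg_replaces_source=np.asarray(sides, dtype=bool),
    )


def test_equal_scores_give_log_of_candidate_count():
    # all entities share one vector: every candidate scores identically
    theta = np.tile([[1.0, 0.5]], (5, 1))
    sample = _manual_sample(theta, (0, 1), [2] * 200, [True] * 200)
    assert edge_loss(theta, sample) == pytest.approx(np.log(201), abs=1e-10)


def test_loss_is_linear_in_edge_weight():
    rng = np.random.default_rng(4)
    theta = rng.normal(size=(10, 4))
    negs = rng.integers(0, 10, size=200)
    sides = rng.random(200) < 0.5
    s1 = _manual_sample(theta, (0, 1), negs, sides, weight=1.0)
    s2 = _manual_sample(theta, (0, 1), negs, sides, weight=2.0)
    s2.weight = 2.0
    assert edge_loss(theta, s2) == pytest.approx(2 * edge_loss(theta, s1), abs=1e-10)


def test_ten_unit_margin_loss_closed_form():
    theta = np.zeros((4, 2))
    theta[0] = [1.0, 10.0]
    theta[1] = [0.0, 1.0]  # positive score = 10; negatives at entity 2/3 score 0
    sample = _manual_sample(theta, (0, 1), [2] * 200, [True] * 200)
    expected = np.log(1 + 200 * np.exp(-10.0))
    assert edge_loss(theta, sample) == pytest.approx(expected, abs=1e-10)


# ---------------------------------------------------------------------------
# training behavior
# ---------------------------------------------------------------------------


def test_same_seed_reproduces_embeddings_bitwise():
    rng = np.random.default_rng(5)
    g = _random_graph(rng, 30, 20, 0.4)
    cfg = EmbeddingConfig(dim=8, n_epochs=2, seed=7, eval_fraction=0.1)
    m1, r1 = cf.train(g, cfg)
    m2, r2 = cf.train(g, cfg)
    np.testing.assert_array_equal(m1.theta, m2.theta)
    assert r1.mrr == r2.mrr


def test_training_loss_decreases_on_planted_fixture(small_multiome):
    rna = small_multiome[0]
    disc, _ = cf.discretize(cf.normalize_rna(cf.filter_low_presence(rna)))
    g = cf.build_rna_graph(disc)
    _, report = cf.train(g, EmbeddingConfig(n_epochs=5, seed=0))
    losses = [e["train_loss"] for e in report.epochs]
    assert losses[-1] <= losses[1] + 1e-6


def test_cells_with_identical_edges_get_similar_embeddings(small_multiome):
    rna = small_multiome[0]
    disc, _ = cf.discretize(cf.normalize_rna(cf.filter_low_presence(rna)))
    dense = disc.to_dense()
    dense[1] = dense[0]  # duplicate cell 0's discretized profile onto cell 1
    dup = CellFeatureMatrix.from_dense(
        dense, cell_ids=disc.cell_ids, feature_ids=disc.feature_ids, layer="discretized"
    )
    dup.meta["n_levels"] = 5
    g = cf.build_rna_graph(dup)
    # modest dimension relative to the tiny graph, so shared context (not
    # memorization capacity) determines the embeddings
    model, _ = cf.train(
        g, EmbeddingConfig(dim=10, n_epochs=40, seed=0, wd=0.05, wd_interval=5)
    )
    a = model.vector("cell", disc.cell_ids[0])
    b = model.vector("cell", disc.cell_ids[1])
    cos = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
    assert cos >= 0.9


def test_first_order_similarity_tracks_empirical_edge_weights(small_multiome):
    """Per gene, softmax edge probabilities over cells should correlate with
    the empirical (weighted) edge distribution after training."""
    rna = small_multiome[0]
    disc, _ = cf.discretize(cf.normalize_rna(cf.filter_low_presence(rna)))
    g = cf.build_rna_graph(disc)
    model, _ = cf.train(g, EmbeddingConfig(n_epochs=10, seed=1))
    cells = model.vectors_of_type("cell")
    dense = disc.to_dense()
    rhos = []
    for j, gene in enumerate(model.ids_of_type("gene")):
        col = dense[:, list(disc.feature_ids).index(gene)]
        if np.count_nonzero(col) < 5:
            continue
        probs = np.exp(cells @ model.vector("gene", gene))
        rho = spearmanr(col, probs).statistic
        rhos.append(rho)
    assert np.mean(rhos) >= 0.5


def test_fixed_only_graph_leaves_real_rows_at_initialization():
    g = cf.MultiRelationGraph()
    g.add_entity_type("cell", [f"c{i}" for i in range(6)])
    g.add_entity_type("null_gene", ["n0", "n1", "n2"], is_fixed=True)
    g.add_relation("null_edge", "null_gene", "cell", weight=1.0)
    g.add_edges("null_edge", [0, 1, 2, 0], [0, 1, 2, 3])
    cfg = EmbeddingConfig(dim=6, n_epochs=3, seed=9, eval_fraction=0.0, wd=0.1)
    model, _ = cf.train(g, cfg)
    D = cfg.dim
    init = np.random.default_rng(cfg.seed).uniform(
        -1 / np.sqrt(D), 1 / np.sqrt(D), size=(9, D)
    )
    cell_rows = model.rows_of_type("cell")
    null_rows = model.rows_of_type("null_gene")
    np.testing.assert_array_equal(model.theta[cell_rows], init[cell_rows])
    assert not np.array_equal(model.theta[null_rows], init[null_rows])


def test_removing_weight_decay_widens_the_generalization_gap():
    rng = np.random.default_rng(6)
    g = _random_graph(rng, 100, 60, 0.15)  # small, overfit-prone
    gaps = {}
    for wd in (0.0, 1.0):
        _, report = cf.train(
            g,
            EmbeddingConfig(
                n_epochs=20, seed=3, eval_fraction=0.2, wd=wd,
                wd_interval=1, batch_size=256,
            ),
        )
        last = report.epochs[-1]
        gaps[wd] = last["val_loss"] - last["train_loss"]
    assert gaps[0.0] > gaps[1.0] + 1.0


def test_divergence_is_reported_as_an_error():
    rng = np.random.default_rng(8)
    g = _random_graph(rng, 20, 15, 0.4)
    with pytest.raises(RuntimeError, match="diverged"):
        cf.train(g, EmbeddingConfig(n_epochs=3, seed=0, learning_rate=1e200, wd=0.0))


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def test_random_embeddings_score_chance_auc():
    rng = np.random.default_rng(10)
    g = _random_graph(rng, 60, 50, 0.4)
    train, ev = split_edges(g, 0.4, 0)
    model = cf.EmbeddingModel(
        np.random.default_rng(0).normal(scale=0.01, size=(train.flat.n_entities, 16)),
        train.flat,
    )
    report = evaluate_link_prediction(
        model, ev, EmbeddingConfig(dim=16), np.random.default_rng(1), train
    )
    assert report.auc == pytest.approx(0.5, abs=0.05)
    assert 0 <= report.r1 <= report.r10 <= report.r50 <= 1
    assert report.tie_policy == "pessimistic"


def test_empty_evaluation_yields_null_metrics():
    rng = np.random.default_rng(11)
    g = _random_graph(rng, 10, 10, 0.4)
    train, ev = split_edges(g, 0.0, 0)
    model = cf.EmbeddingModel(np.zeros((train.flat.n_entities, 4)), train.flat)
    report = evaluate_link_prediction(
        model, ev, EmbeddingConfig(dim=4), np.random.default_rng(0), train
    )
    assert report.mrr is None and report.n_eval_edges == 0


def test_model_save_load_round_trip(tmp_path):
    rng = np.random.default_rng(12)
    g = _random_graph(rng, 12, 8, 0.5)
    model, _ = cf.train(g, EmbeddingConfig(dim=4, n_epochs=1, seed=0))
    model.save(tmp_path / "model")
    back = cf.EmbeddingModel.load(tmp_path / "model")
    np.testing.assert_array_equal(model.theta, back.theta)
    assert back.type_names() == model.type_names()
    np.testing.assert_array_equal(
        back.vector("cell", "cell0"), model.vector("cell", "cell0")
    )
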