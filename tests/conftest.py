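import numpy as np
import pytest

import cofembed as cf
from cofembed.pipelines import batch_pipeline, multiome_pipeline


@pytest.fixture(scope="session")
def multiome_data():
    """The standard planted multiome dataset (3 types x 300 cells)."""
    return cf.simulate_multiome(seed=1)


@pytest.fixture(scope="session")
def trained_multiome(multiome_data):
    """Multiome pipeline (with planted motifs) trained on the fixture."""
    rna, atac, seqs, ann, truth = multiome_data
    pwms = {
        m["name"]: np.asarray(cf.consensus_pwm(m["consensus"]))
        for m in truth.params["motif_spec"]
    }
    cfg = cf.RunConfig(scenario="multiome", seed=1)
    res = multiome_pipeline(
        rna, atac, sequences=seqs, pwms=pwms, cfg=cfg, include_kmers=False
    )
    res["truth"] = truth
    res["ann"] = ann
    res["pwms"] = pwms
    res["labels"] = np.array(truth.cell_labels)
    return res


@pytest.fixture(scope="session")
def batch_corrected():
    """Two balanced synthetic batches with shared types, integrated."""
    rna, _, _, _, truth = cf.simulate_multiome(seed=5)
    labels = np.array(truth.cell_labels)
    batches, btruth = cf.simulate_batches(rna, labels, n_batches=2, seed=5)
    cfg = cf.RunConfig(scenario="batch", seed=5)
    res = batch_pipeline(batches, cfg)
    res["batches"] = batches
    res["truth"] = btruth
    return res


@pytest.fixture(scope="session")
def small_multiome():
    """A miniature planted dataset for fast unit tests."""
    return cf.simulate_multiome(
        n_types=2,
        cells_per_type=40,
        n_genes=80,
        markers_per_type=10,
        n_peaks=160,
        seed=11,
    )


@pytest.fixture(scope="session")
def null_significance_run():
    """An expression graph extended with degree-matched null genes, trained.

    Used to check the empirical null machinery: a subset of the nulls plays
    the role of 'observed' features whose p-values against the remaining
    nulls must be approximately uniform.
    """
    rna, _, _, _, truth = cf.simulate_multiome(
        n_types=3,
        cells_per_type=100,
        n_genes=80,
        markers_per_type=10,
        n_peaks=200,
        seed=21,
    )
    norm = cf.normalize_rna(cf.filter_low_presence(rna))
    disc, _ = cf.discretize(norm)
    graph = cf.build_rna_graph(disc)
    graph = cf.add_null_features(graph, "gene", multiplier=20, seed=21)
    model, report = cf.train(graph, cf.EmbeddingConfig(n_epochs=5, seed=21))
    return {"graph": graph, "model": model, "report": report, "truth": truth}
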