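"""End-to-end wiring of the five graph scenarios.

Thin orchestration over the preprocessing, graph, embedding and transform
modules: each pipeline takes raw matrices, applies the standard
preprocessing, assembles the scenario's graph, trains the embedding and
returns every intermediate next to the model. The examples/ scripts and
the acceptance workflow call these functions rather than re-wiring stages.
"""

from __future__ import annotations

import numpy as np

from .config import RunConfig
from .embedding import train
from .genome import GenomicAnnotation
from .graph import (
    MultiRelationGraph,
    build_atac_graph,
    build_rna_graph,
    combine_graphs,
    gene_scores,
    hub_batch,
    infer_edges,
)
from .matrix import CellFeatureMatrix
from .preprocess import (
    binarize,
    discretize,
    filter_low_presence,
    normalize_rna,
    scan_sequence_features,
    select_variable_genes,
)
from .transform import TransformConfig, softmax_transform

__all__ = [
    "rna_pipeline",
    "atac_pipeline",
    "multiome_pipeline",
    "batch_pipeline",
    "integration_pipeline",
]


def _prep_rna(raw: CellFeatureMatrix, cfg: RunConfig):
    norm = normalize_rna(filter_low_presence(raw, cfg.min_cells))
    disc, model = discretize(norm, n_levels=cfg.n_levels)
    return norm, disc, model


def rna_pipeline(raw: CellFeatureMatrix, cfg: RunConfig | None = None) -> dict:
    """Normalize, discretize, build the cell-gene graph and train."""
    cfg = cfg or RunConfig(scenario="rna")
    norm, disc, disc_model = _prep_rna(raw, cfg)
    graph = build_rna_graph(disc)
    model, report = train(graph, cfg.embedding_config())
    return {
        "normalized": norm,
        "discretized": disc,
        "discretization": disc_model,
        "graph": graph,
        "model": model,
        "report": report,
    }


def atac_pipeline(
    raw_peaks: CellFeatureMatrix,
    sequences: dict | None = None,
    pwms: dict | None = None,
    cfg: RunConfig | None = None,
    include_kmers: bool = True,
) -> dict:
    """Binarize accessibility, scan sequences, build the graph and train.

    k-mer and motif nodes can be used independently; ``include_kmers=False``
    keeps only the motif relation, which trims the graph substantially.
    """
    cfg = cfg or RunConfig(scenario="atac")
    peaks = binarize(filter_low_presence(raw_peaks, cfg.min_cells))
    kmers = motifs = None
    if sequences is not None:
        seqs = {p: sequences[p] for p in peaks.feature_ids}
        kmers, motifs = scan_sequence_features(seqs, k=cfg.kmer_length, pwms=pwms)
        if not include_kmers:
            kmers = None
    graph = build_atac_graph(peaks, kmers=kmers, motifs=motifs)
    model, report = train(graph, cfg.embedding_config())
    return {
        "binarized": peaks,
        "kmers": kmers,
        "motifs": motifs,
        "graph": graph,
        "model": model,
        "report": report,
    }


def multiome_pipeline(
    raw_rna: CellFeatureMatrix,
    raw_peaks: CellFeatureMatrix,
    sequences: dict | None = None,
    pwms: dict | None = None,
    cfg: RunConfig | None = None,
    include_kmers: bool = True,
) -> dict:
    """Joint graph over one cell population measured in both modalities."""
    cfg = cfg or RunConfig(scenario="multiome")
    norm, disc, disc_model = _prep_rna(raw_rna, cfg)
    peaks = binarize(filter_low_presence(raw_peaks, cfg.min_cells))
    kmers = motifs = None
    if sequences is not None:
        seqs = {p: sequences[p] for p in peaks.feature_ids}
        kmers, motifs = scan_sequence_features(seqs, k=cfg.kmer_length, pwms=pwms)
        if not include_kmers:
            kmers = None
    rna_graph = build_rna_graph(disc)
    atac_graph = build_atac_graph(peaks, kmers=kmers, motifs=motifs)
    graph = combine_graphs([rna_graph, atac_graph])
    model, report = train(graph, cfg.embedding_config())
    return {
        "normalized": norm,
        "discretized": disc,
        "discretization": disc_model,
        "binarized": peaks,
        "kmers": kmers,
        "motifs": motifs,
        "graph": graph,
        "model": model,
        "report": report,
    }


def _prefix_cells(m: CellFeatureMatrix, prefix: str) -> CellFeatureMatrix:
    from dataclasses import replace

    return replace(m, cell_ids=np.array([f"{prefix}{c}" for c in m.cell_ids], dtype=object))


def _shared_variable_genes(mats: list[CellFeatureMatrix], cfg: RunConfig) -> list:
    """Variable genes shared across datasets (fallbacks keep >= d features)."""
    shared = set(mats[0].feature_ids)
    for m in mats[1:]:
        shared &= set(m.feature_ids)
    selections = []
    for m in mats:
        sub = m.subset_features(sorted(shared))
        selections.append(set(select_variable_genes(sub, n_top=cfg.n_top_genes).selected_ids))
    inter = set.intersection(*selections) if selections else set()
    if len(inter) >= cfg.svd_components:
        return sorted(inter)
    union = set.union(*selections) & shared
    if len(union) >= cfg.svd_components:
        return sorted(union)
    return sorted(shared)


def batch_pipeline(
    raw_batches: list[CellFeatureMatrix],
    cfg: RunConfig | None = None,
    link_weight: float = 1.0,
) -> dict:
    """Batch correction: per-batch cell-gene graphs + inferred cell links.

    Each batch keeps its own cell entity type; gene nodes are shared. The
    largest batch is the hub: mutual-nearest-neighbor edges are inferred
    between it and every other batch on shared variable genes, and after
    training all non-hub cells and the genes are softmax-transformed
    against the hub cells.
    """
    cfg = cfg or RunConfig(scenario="batch")
    norms, discs, graphs = [], [], []
    for b, raw in enumerate(raw_batches):
        norm, disc, _ = _prep_rna(raw, cfg)
        norms.append(norm)
        discs.append(disc)
        graphs.append(build_rna_graph(disc, cell_type_name=f"cell_batch{b}"))
    graph = combine_graphs(graphs)
    sizes = {f"cell_batch{b}": m.n_cells for b, m in enumerate(norms)}
    hub = hub_batch(sizes)
    hub_idx = int(hub.removeprefix("cell_batch"))
    shared_genes = _shared_variable_genes(norms, cfg)
    links = {}
    for b in range(len(norms)):
        if b == hub_idx:
            continue
        pairs = infer_edges(
            norms[hub_idx].subset_features(shared_genes),
            norms[b].subset_features(shared_genes),
            d=cfg.svd_components,
            k=cfg.mnn_neighbors,
            seed=cfg.seed,
        )
        links[b] = pairs
        rel = f"link_{hub}_cell_batch{b}"
        graph.add_relation(rel, hub, f"cell_batch{b}", weight=link_weight)
        if pairs:
            idx_a = graph.entity_types[hub].index()
            idx_b = graph.entity_types[f"cell_batch{b}"].index()
            graph.add_edges(
                rel,
                np.array([idx_a[a] for a, _ in pairs]),
                np.array([idx_b[bb] for _, bb in pairs]),
            )
    model, report = train(graph, cfg.embedding_config())
    transformed = softmax_transform(
        model,
        query_types=[t for t in model.type_names() if t != hub],
        reference_type=hub,
        config=TransformConfig(temperature=cfg.temperature),
    )
    return {
        "normalized": norms,
        "discretized": discs,
        "graph": graph,
        "hub": hub,
        "links": links,
        "model": model,
        "transformed": transformed,
        "report": report,
    }


def integration_pipeline(
    raw_rna: CellFeatureMatrix,
    raw_peaks: CellFeatureMatrix,
    ann: GenomicAnnotation,
    cfg: RunConfig | None = None,
    link_weight: float = 1.0,
) -> dict:
    """Integrate expression and accessibility measured in different cells.

    The accessibility matrix is summarized into gene activity scores, which
    share a feature space with the expression matrix; mutual nearest
    neighbors between the two cell populations on shared variable genes
    become inferred cell-cell edges connecting the two modality graphs.
    The RNA cells act as the anchor for the softmax transformation.
    """
    cfg = cfg or RunConfig(scenario="integration")
    norm, disc, _ = _prep_rna(raw_rna, cfg)
    peaks = binarize(filter_low_presence(raw_peaks, cfg.min_cells))
    # namespace the cell ids per modality: a manually split dual-omics
    # dataset presents the same barcodes on both sides
    disc = _prefix_cells(disc, "rna:")
    norm = _prefix_cells(norm, "rna:")
    peaks = _prefix_cells(peaks, "atac:")
    rna_graph = build_rna_graph(disc, cell_type_name="cell_rna")
    atac_graph = build_atac_graph(peaks, cell_type_name="cell_atac")
    graph = combine_graphs([rna_graph, atac_graph])
    activity = gene_scores(peaks, ann)
    shared_genes = _shared_variable_genes([norm, activity], cfg)
    pairs = infer_edges(
        norm.subset_features(shared_genes),
        activity.subset_features(shared_genes),
        d=cfg.svd_components,
        k=cfg.mnn_neighbors,
        seed=cfg.seed,
    )
    rel = "link_cell_rna_cell_atac"
    graph.add_relation(rel, "cell_rna", "cell_atac", weight=link_weight)
    if pairs:
        idx_a = graph.entity_types["cell_rna"].index()
        idx_b = graph.entity_types["cell_atac"].index()
        graph.add_edges(
            rel,
            np.array([idx_a[a] for a, _ in pairs]),
            np.array([idx_b[b] for _, b in pairs]),
        )
    model, report = train(graph, cfg.embedding_config())
    transformed = softmax_transform(
        model,
        query_types=[t for t in model.type_names() if t != "cell_rna"],
        reference_type="cell_rna",
        config=TransformConfig(temperature=cfg.temperature),
    )
    return {
        "normalized": norm,
        "gene_scores": activity,
        "graph": graph,
        "links": pairs,
        "model": model,
        "transformed": transformed,
        "report": report,
    }
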