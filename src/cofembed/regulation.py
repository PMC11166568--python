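"""Queries of the co-embedding space and regulatory inference.

Entities live in one shared metric space after the softmax transformation,
so biology reduces to geometry: exact Euclidean nearest-neighbor queries
(optionally restricted to entity types), master-regulator calling (a TF
whose motif and gene are both cell-type-specific and mutually close), and
target-gene inference (candidate genes close to both the TF motif and the
TF gene, whose nearby motif-containing peaks are too).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import rankdata

from .embedding import EmbeddingModel
from .genome import GenomicAnnotation
from .matrix import CellFeatureMatrix

__all__ = [
    "QueryResult",
    "query_neighbors",
    "find_master_regulators",
    "find_target_genes",
]


@dataclass
class QueryResult:
    """Nearest-neighbor hits, ascending by distance (ties by id)."""

    hits: pd.DataFrame  # columns: type, id, distance
    query: dict = field(default_factory=dict)


def _stack_entities(model: EmbeddingModel, type_filter):
    types = type_filter if type_filter is not None else model.type_names()
    recs_type, recs_id, mats = [], [], []
    for t in types:
        ids = model.ids_of_type(t)
        if len(ids) == 0:
            continue
        recs_type.extend([t] * len(ids))
        recs_id.extend(ids.tolist())
        mats.append(model.vectors_of_type(t))
    if not mats:
        raise ValueError("no entities match the type filter")
    return np.asarray(recs_type, dtype=object), np.asarray(recs_id, dtype=object), np.vstack(mats)


def query_neighbors(
    model: EmbeddingModel,
    query=None,
    *,
    entity: tuple[str, str] | None = None,
    k: int | None = None,
    radius: float | None = None,
    type_filter: list[str] | None = None,
) -> QueryResult:
    """Exact Euclidean nearest neighbors of a point or an embedded entity.

    Exactly one of ``k`` (nearest count) or ``radius`` must be given. With
    ``entity=(type, id)`` the entity itself is excluded from the hits. A
    ``type_filter`` restricts the search to the listed entity types. When
    ``k`` exceeds the filtered population, all entities are returned with a
    warning.
    """
    if (k is None) == (radius is None):
        raise ValueError("give exactly one of k or radius")
    if (query is None) == (entity is None):
        raise ValueError("give exactly one of query (a point) or entity=(type, id)")
    if entity is not None:
        point = model.vector(*entity)
    else:
        point = np.asarray(query, dtype=float)
    types, ids, X = _stack_entities(model, type_filter)
    tree = cKDTree(X)
    if k is not None:
        kk = min(k + (1 if entity is not None else 0), X.shape[0])
        if k > X.shape[0]:
            import warnings

            warnings.warn(
                f"k={k} exceeds the {X.shape[0]} entities after filtering; returning all"
            )
        dist, idx = tree.query(point, k=kk)
        dist, idx = np.atleast_1d(dist), np.atleast_1d(idx)
    else:
        idx = np.asarray(tree.query_ball_point(point, r=radius), dtype=int)
        dist = np.linalg.norm(X[idx] - point, axis=1) if idx.size else np.empty(0)
    hits = pd.DataFrame({"type": types[idx], "id": ids[idx], "distance": dist})
    if entity is not None:
        hits = hits[~((hits["type"] == entity[0]) & (hits["id"] == entity[1]))]
        if k is not None:
            hits = hits.iloc[:k]
    hits = hits.sort_values(["distance", "id"], kind="stable").reset_index(drop=True)
    return QueryResult(hits=hits, query={"entity": entity, "k": k, "radius": radius})


def _competition_ranks(distances: np.ndarray) -> np.ndarray:
    """Competition ("min") ranks, 1-based; ties share the smallest rank."""
    return rankdata(distances, method="min").astype(int)


def find_master_regulators(
    model: EmbeddingModel,
    tf_pairs: list[tuple[str, str]],
    motif_specificity: pd.DataFrame,
    gene_specificity: pd.DataFrame,
    motif_type: str = "motif",
    gene_type: str = "gene",
    metrics: tuple[str, ...] = ("max_value", "gini"),
    cutoff_quantile: float = 0.5,
) -> pd.DataFrame:
    """Rank TFs by the proximity of their gene to their motif.

    For each (motif id, gene id) pair, the Euclidean distances from the
    motif to every gene are computed and the TF gene's competition rank
    among all genes is recorded. TFs whose motif or gene falls below the
    ``cutoff_quantile`` of the chosen specificity metrics (within their own
    feature kind) are flagged ``filtered`` but kept in the report, which is
    sorted by ascending gene rank.
    """
    gene_ids = model.ids_of_type(gene_type)
    G = model.vectors_of_type(gene_type)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    motif_cut = {m: motif_specificity[m].quantile(cutoff_quantile) for m in metrics}
    gene_cut = {m: gene_specificity[m].quantile(cutoff_quantile) for m in metrics}
    rows = []
    for motif_id, tf_gene in tf_pairs:
        if tf_gene not in gene_pos:
            import warnings

            warnings.warn(f"motif {motif_id!r}: paired gene {tf_gene!r} not embedded; skipped")
            continue
        mv = model.vector(motif_type, motif_id)
        dist = np.linalg.norm(G - mv, axis=1)
        ranks = _competition_ranks(dist)
        gene_rank = int(ranks[gene_pos[tf_gene]])
        passed = True
        for metric in metrics:
            if motif_specificity.loc[motif_id, metric] < motif_cut[metric]:
                passed = False
            if gene_specificity.loc[tf_gene, metric] < gene_cut[metric]:
                passed = False
        rec = {
            "motif_id": motif_id,
            "gene_id": tf_gene,
            "gene_rank": gene_rank,
            "filtered": not passed,
        }
        for metric in metrics:
            rec[f"motif_{metric}"] = float(motif_specificity.loc[motif_id, metric])
            rec[f"gene_{metric}"] = float(gene_specificity.loc[tf_gene, metric])
        rows.append(rec)
    report = pd.DataFrame(rows)
    if len(report):
        report = report.sort_values(
            ["filtered", "gene_rank", "motif_id"], kind="stable"
        ).reset_index(drop=True)
    return report


def find_target_genes(
    model: EmbeddingModel,
    regulator: tuple[str, str],
    ann: GenomicAnnotation,
    peak_motif_matrix: CellFeatureMatrix,
    motif_type: str = "motif",
    gene_type: str = "gene",
    peak_type: str = "peak",
    k: int = 200,
    tss_window: int = 100_000,
    peak_rank_cutoff: int = 1000,
    avg_rank_cutoff: int = 5000,
    rank_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
) -> pd.DataFrame:
    """Infer the target genes of a master regulator from the co-embedding.

    Candidates are the union of the ``k`` genes nearest the TF motif and
    the ``k`` nearest the TF gene. A candidate survives only if some peak
    within ``tss_window`` of its TSS contains the TF motif. For survivors,
    four Euclidean distances are converted to competition ranks over the
    whole gene or peak population: gene-to-TF-gene, gene-to-TF-motif, and
    (for the gene's best nearby motif-bearing peak) peak-to-TF-motif and
    peak-to-TF-gene. A gene passes when its best peak rank is within
    ``peak_rank_cutoff`` and its (weighted) average rank within
    ``avg_rank_cutoff``; all candidates are reported with pass flags,
    sorted by average rank then id.
    """
    motif_id, tf_gene = regulator
    if motif_id not in set(peak_motif_matrix.feature_ids):
        raise ValueError(f"motif {motif_id!r} absent from the peak x motif matrix")
    gene_ids = model.ids_of_type(gene_type)
    peak_ids = model.ids_of_type(peak_type)
    G = model.vectors_of_type(gene_type)
    P = model.vectors_of_type(peak_type)
    v_motif = model.vector(motif_type, motif_id)
    v_gene = model.vector(gene_type, tf_gene)

    d_gene_tfgene = np.linalg.norm(G - v_gene, axis=1)
    d_gene_motif = np.linalg.norm(G - v_motif, axis=1)
    rank_gene_tfgene = _competition_ranks(d_gene_tfgene)
    rank_gene_motif = _competition_ranks(d_gene_motif)
    d_peak_motif = np.linalg.norm(P - v_motif, axis=1)
    d_peak_tfgene = np.linalg.norm(P - v_gene, axis=1)
    rank_peak_motif = _competition_ranks(d_peak_motif)
    rank_peak_tfgene = _competition_ranks(d_peak_tfgene)

    def top_k(dist):
        order = np.lexsort((gene_ids.astype(str), dist))
        return set(gene_ids[order[: min(k, len(order))]])

    candidates = sorted(top_k(d_gene_motif) | top_k(d_gene_tfgene))

    # peaks carrying the motif, grouped by chromosome
    motif_col = peak_motif_matrix.feature_index()[motif_id]
    carrier = np.asarray(
        (peak_motif_matrix.values[:, motif_col] > 0).todense()
    ).ravel()
    carrier_ids = set(np.asarray(peak_motif_matrix.cell_ids)[carrier])
    peaks_meta = ann.peaks.set_index("peak_id")
    genes_meta = ann.genes.set_index("gene_id")
    peak_pos = {p: i for i, p in enumerate(peak_ids)}

    pmid = {
        p: (int(peaks_meta.at[p, "start"]) + int(peaks_meta.at[p, "end"])) // 2
        for p in peak_ids
        if p in peaks_meta.index
    }
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    rows = []
    wts = np.asarray(rank_weights, dtype=float)
    for gid in candidates:
        if gid not in genes_meta.index or gid not in gene_pos:
            continue
        chrom = genes_meta.at[gid, "chrom"]
        tss = int(genes_meta.at[gid, "tss"])
        nearby = [
            p
            for p in carrier_ids
            if p in pmid
            and peaks_meta.at[p, "chrom"] == chrom
            and abs(pmid[p] - tss) <= tss_window
            and p in peak_pos
        ]
        if not nearby:
            continue  # no motif-containing open region near the TSS
        pidx = np.array([peak_pos[p] for p in nearby])
        best_peak_motif = int(rank_peak_motif[pidx].min())
        best_peak_tfgene = int(rank_peak_tfgene[pidx].min())
        gi = gene_pos[gid]
        ranks = np.array(
            [
                rank_gene_tfgene[gi],
                rank_gene_motif[gi],
                best_peak_motif,
                best_peak_tfgene,
            ],
            dtype=float,
        )
        avg_rank = float((ranks * wts).sum() / wts.sum())
        passes = (
            min(best_peak_motif, best_peak_tfgene) <= peak_rank_cutoff
            and avg_rank <= avg_rank_cutoff
        )
        rows.append(
            {
                "gene_id": gid,
                "rank_gene_to_tf_gene": int(ranks[0]),
                "rank_gene_to_tf_motif": int(ranks[1]),
                "rank_best_peak_to_tf_motif": best_peak_motif,
                "rank_best_peak_to_tf_gene": best_peak_tfgene,
                "average_rank": avg_rank,
                "passes": passes,
            }
        )
    report = pd.DataFrame(rows)
    if len(report):
        report = report.sort_values(
            ["average_rank", "gene_id"], kind="stable"
        ).reset_index(drop=True)
    return report
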