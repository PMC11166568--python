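"""Typed multi-relation graphs over cells and features.

A :class:`MultiRelationGraph` holds a registry of entity types (cells of one
or more batches/modalities, genes, peaks, k-mers, motifs, null features) and
typed weighted relations between them, plus the edge list itself. Builders
cover the five construction scenarios: RNA (expression-level relations),
ATAC (binary accessibility plus sequence-feature relations), multiome,
multi-batch and cross-modality integration (via computationally inferred
cell-cell edges), along with gene activity scores used to bridge chromatin
accessibility to expression.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.extmath import randomized_svd

from .genome import GenomicAnnotation
from .matrix import CellFeatureMatrix

__all__ = [
    "EntityType",
    "RelationType",
    "MultiRelationGraph",
    "build_rna_graph",
    "build_atac_graph",
    "combine_graphs",
    "infer_edges",
    "gene_scores",
    "add_null_features",
    "hub_batch",
]


@dataclass
class EntityType:
    """A class of graph nodes (e.g. one batch of cells, genes, peaks)."""

    name: str
    ids: np.ndarray
    is_fixed: bool = False

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError(f"duplicate ids in entity type {self.name!r}")

    def __len__(self) -> int:
        return len(self.ids)

    def index(self) -> dict:
        return {v: i for i, v in enumerate(self.ids)}


@dataclass
class RelationType:
    """A typed edge class with a relation-level weight."""

    name: str
    source_type: str
    dest_type: str
    weight: float = 1.0

    def __post_init__(self):
        if self.weight <= 0:
            raise ValueError(f"relation {self.name!r}: weight must be > 0")


class MultiRelationGraph:
    """Typed entities, typed weighted relations, and an edge list."""

    def __init__(self):
        self.entity_types: dict[str, EntityType] = {}
        self.relations: dict[str, RelationType] = {}
        self._edges: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    # -- construction --------------------------------------------------

    def add_entity_type(self, name: str, ids, is_fixed: bool = False) -> EntityType:
        if name in self.entity_types:
            raise ValueError(f"entity type {name!r} already registered")
        et = EntityType(name=name, ids=ids, is_fixed=is_fixed)
        self.entity_types[name] = et
        return et

    def add_relation(
        self, name: str, source_type: str, dest_type: str, weight: float = 1.0
    ) -> RelationType:
        if name in self.relations:
            raise ValueError(f"relation {name!r} already registered")
        for t in (source_type, dest_type):
            if t not in self.entity_types:
                raise ValueError(f"unknown entity type {t!r}")
        rel = RelationType(name=name, source_type=source_type, dest_type=dest_type, weight=weight)
        self.relations[name] = rel
        self._edges[name] = (
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=float),
        )
        return rel

    def add_edges(self, relation: str, src, dst, weights=None) -> None:
        """Append edges (local indices into the relation's endpoint types)."""
        rel = self.relations[relation]
        src = np.asarray(src, dtype=np.int64)
        dst = np.asarray(dst, dtype=np.int64)
        if src.shape != dst.shape:
            raise ValueError("src and dst must have the same length")
        n_src = len(self.entity_types[rel.source_type])
        n_dst = len(self.entity_types[rel.dest_type])
        if src.size and (src.min() < 0 or src.max() >= n_src):
            raise ValueError(f"source index out of range for type {rel.source_type!r}")
        if dst.size and (dst.min() < 0 or dst.max() >= n_dst):
            raise ValueError(f"dest index out of range for type {rel.dest_type!r}")
        if weights is None:
            w = np.full(src.shape, rel.weight, dtype=float)
        else:
            w = np.asarray(weights, dtype=float)
            if w.shape != src.shape:
                raise ValueError("weights must match edge count")
            if w.size and w.min() <= 0:
                raise ValueError("edge weights must be > 0")
        old_src, old_dst, old_w = self._edges[relation]
        all_src = np.concatenate([old_src, src])
        all_dst = np.concatenate([old_dst, dst])
        key = all_src * np.int64(n_dst) + all_dst
        if len(np.unique(key)) != len(key):
            raise ValueError(f"duplicate (source, relation, dest) edges in {relation!r}")
        self._edges[relation] = (all_src, all_dst, np.concatenate([old_w, w]))

    # -- views ---------------------------------------------------------

    def edges(self, relation: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._edges[relation]

    @property
    def n_edges(self) -> int:
        return sum(len(s) for s, _, _ in self._edges.values())

    def n_entities(self, type_name: str | None = None) -> int:
        if type_name is not None:
            return len(self.entity_types[type_name])
        return sum(len(et) for et in self.entity_types.values())

    def degrees(self, type_name: str) -> np.ndarray:
        """Total degree (as source plus as destination) per entity of a type."""
        deg = np.zeros(len(self.entity_types[type_name]), dtype=np.int64)
        for rel in self.relations.values():
            src, dst, _ = self._edges[rel.name]
            if rel.source_type == type_name:
                np.add.at(deg, src, 1)
            if rel.dest_type == type_name:
                np.add.at(deg, dst, 1)
        return deg

    def edge_table(self) -> pd.DataFrame:
        """Flat edge list with string ids, one row per edge."""
        frames = []
        for rel in self.relations.values():
            src, dst, w = self._edges[rel.name]
            frames.append(
                pd.DataFrame(
                    {
                        "source_type": rel.source_type,
                        "source_id": self.entity_types[rel.source_type].ids[src],
                        "relation": rel.name,
                        "dest_type": rel.dest_type,
                        "dest_id": self.entity_types[rel.dest_type].ids[dst],
                        "weight": w,
                    }
                )
            )
        if not frames:
            return pd.DataFrame(
                columns=["source_type", "source_id", "relation", "dest_type", "dest_id", "weight"]
            )
        return pd.concat(frames, ignore_index=True)

    def copy(self) -> "MultiRelationGraph":
        g = MultiRelationGraph()
        for et in self.entity_types.values():
            g.add_entity_type(et.name, et.ids.copy(), is_fixed=et.is_fixed)
        for rel in self.relations.values():
            g.add_relation(rel.name, rel.source_type, rel.dest_type, rel.weight)
            src, dst, w = self._edges[rel.name]
            g._edges[rel.name] = (src.copy(), dst.copy(), w.copy())
        return g

    # -- serialization -------------------------------------------------

    def save(self, outdir) -> None:
        """Write the graph as a TSV edge list plus a JSON type schema."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.edge_table().to_csv(outdir / "edges.tsv", sep="\t", index=False)
        schema = {
            "entity_types": [
                {"name": et.name, "is_fixed": et.is_fixed, "ids": et.ids.tolist()}
                for et in self.entity_types.values()
            ],
            "relations": [
                {
                    "name": r.name,
                    "source_type": r.source_type,
                    "dest_type": r.dest_type,
                    "weight": r.weight,
                }
                for r in self.relations.values()
            ],
        }
        (outdir / "schema.json").write_text(json.dumps(schema, indent=1))

    @classmethod
    def load(cls, outdir) -> "MultiRelationGraph":
        outdir = Path(outdir)
        schema = json.loads((outdir / "schema.json").read_text())
        g = cls()
        for et in schema["entity_types"]:
            g.add_entity_type(et["name"], et["ids"], is_fixed=et["is_fixed"])
        for r in schema["relations"]:
            g.add_relation(r["name"], r["source_type"], r["dest_type"], r["weight"])
        table = pd.read_csv(outdir / "edges.tsv", sep="\t", dtype={"source_id": str, "dest_id": str})
        for rel_name, sub in table.groupby("relation", sort=False):
            rel = g.relations[rel_name]
            src_index = g.entity_types[rel.source_type].index()
            dst_index = g.entity_types[rel.dest_type].index()
            src = np.array([src_index[i] for i in sub["source_id"]], dtype=np.int64)
            dst = np.array([dst_index[i] for i in sub["dest_id"]], dtype=np.int64)
            g.add_edges(rel_name, src, dst, sub["weight"].to_numpy())
        return g


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def _expression_level_weights(n_levels: int) -> np.ndarray:
    """Relation weights for expression levels 1..n, evenly spaced 1.0 to 5.0."""
    if n_levels == 1:
        return np.array([5.0])
    return np.linspace(1.0, 5.0, n_levels)


def build_rna_graph(
    m: CellFeatureMatrix,
    add_edge_weights: bool = False,
    cell_type_name: str = "cell",
    gene_type_name: str = "gene",
) -> MultiRelationGraph:
    """Cells and genes connected by expression edges.

    Default mode takes a discretized matrix and encodes each expression
    level as its own relation; the n relation weights are evenly spaced so
    the lowest level has weight 1.0 and the highest 5.0 (for the default
    five levels: 1, 2, 3, 4, 5), letting high expression pull embeddings
    more strongly. With ``add_edge_weights=True``, a single relation of
    weight 1.0 is used and the (normalized or discretized) expression value
    becomes the per-edge weight.
    """
    if m.values.nnz == 0:
        raise ValueError("matrix has no non-zero entries; nothing to encode")
    g = MultiRelationGraph()
    g.add_entity_type(cell_type_name, m.cell_ids)
    g.add_entity_type(gene_type_name, m.feature_ids)
    coo = m.values.tocoo()
    if add_edge_weights:
        if m.layer not in ("normalized", "discretized"):
            raise ValueError("weighted mode expects a normalized or discretized matrix")
        rel = f"{cell_type_name}_expresses_{gene_type_name}"
        g.add_relation(rel, cell_type_name, gene_type_name, weight=1.0)
        g.add_edges(rel, coo.row, coo.col, weights=coo.data)
        return g
    if m.layer != "discretized":
        raise ValueError("default mode expects a discretized matrix")
    n_levels = int(m.meta.get("n_levels", int(coo.data.max())))
    weights = _expression_level_weights(n_levels)
    levels = coo.data.astype(int)
    for lv in range(1, n_levels + 1):
        rel = f"{cell_type_name}_expresses_{gene_type_name}_lv{lv}"
        g.add_relation(rel, cell_type_name, gene_type_name, weight=float(weights[lv - 1]))
        sel = levels == lv
        if sel.any():
            g.add_edges(rel, coo.row[sel], coo.col[sel])
    return g


def build_atac_graph(
    peaks: CellFeatureMatrix,
    kmers: CellFeatureMatrix | None = None,
    motifs: CellFeatureMatrix | None = None,
    cell_type_name: str = "cell",
    peak_type_name: str = "peak",
    cell_peak_weight: float = 1.0,
    peak_kmer_weight: float = 0.02,
    peak_motif_weight: float = 0.2,
) -> MultiRelationGraph:
    """Cells and peaks (plus optional sequence features) as a graph.

    Relation weights follow the accessibility scenario: cell-peak 1.0,
    peak-k-mer 0.02, peak-motif 0.2. One edge per non-zero binary entry.
    """
    if peaks.layer != "binarized":
        raise ValueError("peak matrix must be binarized")
    g = MultiRelationGraph()
    g.add_entity_type(cell_type_name, peaks.cell_ids)
    g.add_entity_type(peak_type_name, peaks.feature_ids)
    rel = f"{cell_type_name}_open_{peak_type_name}"
    g.add_relation(rel, cell_type_name, peak_type_name, weight=cell_peak_weight)
    coo = peaks.values.tocoo()
    g.add_edges(rel, coo.row, coo.col)

    peak_index = {p: i for i, p in enumerate(peaks.feature_ids)}
    for sub, kind, weight in ((kmers, "kmer", peak_kmer_weight), (motifs, "motif", peak_motif_weight)):
        if sub is None:
            continue
        unknown = [p for p in sub.cell_ids if p not in peak_index]
        if unknown:
            raise ValueError(
                f"{kind} matrix references unknown peaks: {', '.join(map(str, unknown[:5]))}"
            )
        g.add_entity_type(kind, sub.feature_ids)
        rel = f"{peak_type_name}_contains_{kind}"
        g.add_relation(rel, peak_type_name, kind, weight=weight)
        coo = sub.values.tocoo()
        rows = np.array([peak_index[p] for p in sub.cell_ids[coo.row]], dtype=np.int64)
        g.add_edges(rel, rows, coo.col)
    return g


def combine_graphs(
    parts: list[MultiRelationGraph],
    link_edges: tuple[str, str, list] | None = None,
    link_relation: str = "cell_cell_link",
    link_weight: float = 1.0,
) -> MultiRelationGraph:
    """Union of several graphs, merging entity types that share a name.

    Entity types with the same name are merged into the union of their ids
    (e.g. the shared gene set of two batches); cell types of different
    batches or modalities keep distinct type names and stay separate.
    Optionally adds computationally inferred cell-cell edges under a
    dedicated relation of weight ``link_weight``: ``link_edges`` is
    ``(type_a, type_b, [(id_a, id_b), ...])``.
    """
    out = MultiRelationGraph()
    for part in parts:
        for et in part.entity_types.values():
            if et.name in out.entity_types:
                existing = out.entity_types[et.name]
                if existing.is_fixed != et.is_fixed:
                    raise ValueError(f"is_fixed mismatch for entity type {et.name!r}")
                known = set(existing.ids)
                extra = [i for i in et.ids if i not in known]
                if extra:
                    existing.ids = np.concatenate(
                        [existing.ids, np.asarray(extra, dtype=object)]
                    )
            else:
                out.add_entity_type(et.name, et.ids.copy(), is_fixed=et.is_fixed)
    # ids must not collide across different types
    seen: dict[str, str] = {}
    for et in out.entity_types.values():
        for i in et.ids:
            if i in seen and seen[i] != et.name:
                raise ValueError(
                    f"id {i!r} appears in both {seen[i]!r} and {et.name!r}"
                )
            seen[i] = et.name
    for part in parts:
        for rel in part.relations.values():
            if rel.name in out.relations:
                prev = out.relations[rel.name]
                if (prev.source_type, prev.dest_type, prev.weight) != (
                    rel.source_type,
                    rel.dest_type,
                    rel.weight,
                ):
                    raise ValueError(f"conflicting definitions of relation {rel.name!r}")
            else:
                out.add_relation(rel.name, rel.source_type, rel.dest_type, rel.weight)
            src, dst, w = part.edges(rel.name)
            src_map = _index_map(part.entity_types[rel.source_type], out.entity_types[rel.source_type])
            dst_map = _index_map(part.entity_types[rel.dest_type], out.entity_types[rel.dest_type])
            out.add_edges(rel.name, src_map[src], dst_map[dst], w)
    if link_edges is not None:
        type_a, type_b, pairs = link_edges
        idx_a = out.entity_types[type_a].index()
        idx_b = out.entity_types[type_b].index()
        out.add_relation(link_relation, type_a, type_b, weight=link_weight)
        if pairs:
            src = np.array([idx_a[a] for a, _ in pairs], dtype=np.int64)
            dst = np.array([idx_b[b] for _, b in pairs], dtype=np.int64)
            out.add_edges(link_relation, src, dst)
    return out


def _index_map(old: EntityType, new: EntityType) -> np.ndarray:
    idx = new.index()
    return np.array([idx[i] for i in old.ids], dtype=np.int64)


def hub_batch(sizes: dict[str, int]) -> str:
    """Name of the largest batch: the hub that is linked to all others."""
    return max(sizes, key=lambda k: (sizes[k], k))


# ---------------------------------------------------------------------------
# inferred cell-cell edges
# ---------------------------------------------------------------------------


def infer_edges(
    X1,
    X2,
    d: int = 20,
    k: int = 20,
    seed: int = 0,
) -> list[tuple]:
    """Mutual-nearest-neighbor cell pairs across two datasets.

    The cross-product matrix ``X = X1 @ X2.T`` over shared feature columns
    is factored by truncated randomized SVD into ``U S V^T`` (``d``
    components); rows of U and V are L2-normalized and a pair (i, j) is kept
    iff each is among the other's ``k`` nearest neighbors by Euclidean
    distance. When the inputs are :class:`CellFeatureMatrix`, pairs of cell
    ids are returned (features are aligned by intersection first); plain
    arrays yield index pairs.
    """
    ids1 = ids2 = None
    if isinstance(X1, CellFeatureMatrix) and isinstance(X2, CellFeatureMatrix):
        shared = sorted(set(X1.feature_ids) & set(X2.feature_ids))
        if not shared:
            raise ValueError("no shared features between the two datasets")
        ids1, ids2 = X1.cell_ids, X2.cell_ids
        X1 = X1.subset_features(shared).values
        X2 = X2.subset_features(shared).values
    A1 = sp.csr_matrix(X1) if not sp.issparse(X1) else X1.tocsr()
    A2 = sp.csr_matrix(X2) if not sp.issparse(X2) else X2.tocsr()
    if A1.shape[1] != A2.shape[1]:
        raise ValueError("datasets must share aligned feature columns")
    m = A1.shape[1]
    if m < d:
        raise ValueError(
            f"only {m} shared features but d={d} components requested; use a smaller d"
        )
    X = np.asarray((A1 @ A2.T).todense(), dtype=float)
    d_eff = min(d, min(X.shape))
    U, S, Vt = randomized_svd(
        X, n_components=d_eff, n_oversamples=10, n_iter=4, random_state=seed
    )
    V = Vt.T
    U = _l2_normalize_rows(U)
    V = _l2_normalize_rows(V)
    k1 = min(k, V.shape[0])
    k2 = min(k, U.shape[0])
    nn_v = NearestNeighbors(n_neighbors=k1).fit(V)
    nn_u = NearestNeighbors(n_neighbors=k2).fit(U)
    knn_of_u = nn_v.kneighbors(U, return_distance=False)  # for each row of U: k nearest in V
    knn_of_v = nn_u.kneighbors(V, return_distance=False)
    in_knn_u = [set(row) for row in knn_of_u]
    in_knn_v = [set(row) for row in knn_of_v]
    pairs = []
    for i in range(U.shape[0]):
        for j in in_knn_u[i]:
            if i in in_knn_v[j]:
                pairs.append((i, int(j)))
    pairs = sorted(set(pairs))
    if ids1 is not None:
        return [(ids1[i], ids2[j]) for i, j in pairs]
    return pairs


def _l2_normalize_rows(A: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(A, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return A / norms


# ---------------------------------------------------------------------------
# gene activity scores
# ---------------------------------------------------------------------------


def gene_scores(
    peaks: CellFeatureMatrix,
    ann: GenomicAnnotation,
    tss_window: int = 100_000,
    upstream_flank: int = 5_000,
    decay_scale: float = 5_000.0,
) -> CellFeatureMatrix:
    """Per-cell gene activity from chromatin accessibility near each gene.

    For every gene, peaks whose midpoint lies within ``tss_window`` of the
    TSS contribute their cell-wise values with weight 1.0 when the peak
    overlaps the gene body or the strand-aware 5 kb upstream flank, and
    ``exp(-distance/decay_scale)`` of the midpoint-TSS distance otherwise.
    The weighted sum is divided by the gene's body length relative to the
    median body length, so long genes do not score higher merely by
    intersecting more peaks. Genes with no qualifying peak keep an all-zero
    column.
    """
    peak_meta = ann.peaks.set_index("peak_id")
    missing = [p for p in peaks.feature_ids if p not in peak_meta.index]
    if missing:
        raise ValueError(f"peaks missing from annotation: {missing[:5]}")
    pchrom = peak_meta.loc[peaks.feature_ids, "chrom"].to_numpy()
    pstart = peak_meta.loc[peaks.feature_ids, "start"].to_numpy()
    pend = peak_meta.loc[peaks.feature_ids, "end"].to_numpy()
    pmid = (pstart + pend) // 2

    genes = ann.genes
    body_len = (genes["end"] - genes["start"]).to_numpy().astype(float)
    size_factor = body_len / float(np.median(body_len))

    rows, cols, vals = [], [], []
    for gi in range(len(genes)):
        chrom = genes.at[gi, "chrom"]
        tss = int(genes.at[gi, "tss"])
        gstart, gend = int(genes.at[gi, "start"]), int(genes.at[gi, "end"])
        strand = genes.at[gi, "strand"]
        on_chrom = np.flatnonzero(pchrom == chrom)
        if on_chrom.size == 0:
            continue
        dist = np.abs(pmid[on_chrom] - tss)
        near = on_chrom[dist <= tss_window]
        if near.size == 0:
            continue
        if strand == "+":
            zs, ze = gstart - upstream_flank, gend
        else:
            zs, ze = gstart, gend + upstream_flank
        proximal = (pstart[near] < ze) & (pend[near] > zs)
        w = np.where(
            proximal, 1.0, np.exp(-np.abs(pmid[near] - tss) / decay_scale)
        )
        rows.extend(near.tolist())
        cols.extend([gi] * near.size)
        vals.extend((w / size_factor[gi]).tolist())
    W = sp.csr_matrix(
        (vals, (rows, cols)), shape=(peaks.n_features, len(genes))
    )
    scores = peaks.values @ W
    return CellFeatureMatrix(
        values=scores,
        cell_ids=peaks.cell_ids,
        feature_ids=genes["gene_id"].to_numpy(dtype=object),
        feature_kind="gene",
        layer="normalized",
        meta={"source": "gene_scores", "tss_window": tss_window},
    )


# ---------------------------------------------------------------------------
# null features for significance
# ---------------------------------------------------------------------------


def _degree_preserving_permutation(deg: np.ndarray, subset: np.ndarray, rng) -> np.ndarray:
    """A permutation of ``subset`` that only maps between equal-degree members."""
    perm = subset.copy()
    degrees = deg[subset]
    for d in np.unique(degrees):
        pos = np.flatnonzero(degrees == d)
        perm[pos] = subset[pos][rng.permutation(len(pos))]
    return perm


def add_null_features(
    g: MultiRelationGraph,
    target_type: str,
    multiplier: float,
    seed: int = 0,
) -> MultiRelationGraph:
    """Extend a graph with degree-matched shuffled copies of a feature type.

    ``multiplier * n`` null entities of a new fixed type ``null_<target>``
    are added (20x genes for expression graphs and 5x peaks for
    accessibility graphs by convention). Each full round of nulls replays
    the target type's edges with the target endpoint re-assigned through a
    degree-preserving permutation (so the null degree multiset equals the
    real one exactly) and the opposite endpoint re-assigned through a
    degree-preserving permutation of its own type, which destroys the
    biological connectivity while preserving the degree structure. Null
    entities are flagged fixed so their edges never update real embeddings
    during training.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be > 0")
    if target_type not in g.entity_types:
        raise ValueError(f"unknown entity type {target_type!r}")
    touched = [
        r
        for r in g.relations.values()
        if target_type in (r.source_type, r.dest_type)
    ]
    if not touched or all(len(g.edges(r.name)[0]) == 0 for r in touched):
        raise ValueError(f"entity type {target_type!r} has no edges")
    rng = np.random.default_rng(seed)
    n_t = len(g.entity_types[target_type])
    n_nulls = int(round(multiplier * n_t))
    full_rounds, remainder = divmod(n_nulls, n_t)

    deg_target = g.degrees(target_type)
    other_degrees = {
        t: g.degrees(t)
        for t in {r.source_type for r in touched} | {r.dest_type for r in touched}
        if t != target_type
    }

    out = g.copy()
    null_type = f"null_{target_type}"
    null_ids = []
    target_ids = g.entity_types[target_type].ids
    rounds: list[np.ndarray] = [np.arange(n_t)] * full_rounds
    if remainder:
        rounds.append(np.sort(rng.choice(n_t, size=remainder, replace=False)))
    offset = 0
    round_offsets = []
    for r, subset in enumerate(rounds):
        round_offsets.append(offset)
        null_ids.extend(f"null{r}:{target_ids[i]}" for i in subset)
        offset += len(subset)
    out.add_entity_type(null_type, np.asarray(null_ids, dtype=object), is_fixed=True)

    for rel in touched:
        target_is_src = rel.source_type == target_type
        other_type = rel.dest_type if target_is_src else rel.source_type
        if target_is_src:
            out.add_relation(f"null_{rel.name}", null_type, other_type, rel.weight)
        else:
            out.add_relation(f"null_{rel.name}", rel.source_type, null_type, rel.weight)

    collected = {rel.name: ([], [], []) for rel in touched}
    for r, subset in enumerate(rounds):
        # one degree-preserving permutation of the targets per round, shared
        # across relations so the total degree of each null node equals the
        # total degree of one real node exactly
        perm = _degree_preserving_permutation(deg_target, subset, rng)
        partner = np.full(n_t, -1, dtype=np.int64)
        partner[subset] = perm
        pos_in_round = np.full(n_t, -1, dtype=np.int64)
        pos_in_round[subset] = np.arange(len(subset))
        operms = {
            t: _degree_preserving_permutation(deg, np.arange(len(deg)), rng)
            for t, deg in other_degrees.items()
        }
        for rel in touched:
            target_is_src = rel.source_type == target_type
            other_type = rel.dest_type if target_is_src else rel.source_type
            src, dst, w = g.edges(rel.name)
            target_side = src if target_is_src else dst
            other_side = dst if target_is_src else src
            keep = np.isin(target_side, subset)
            if not keep.any():
                continue
            mapped = round_offsets[r] + pos_in_round[partner[target_side[keep]]]
            other_mapped = operms[other_type][other_side[keep]]
            ns, nd = (mapped, other_mapped) if target_is_src else (other_mapped, mapped)
            parts = collected[rel.name]
            parts[0].append(ns)
            parts[1].append(nd)
            parts[2].append(w[keep])

    for rel in touched:
        s_parts, d_parts, w_parts = collected[rel.name]
        if not s_parts:
            continue
        name = f"null_{rel.name}"
        ns = np.concatenate(s_parts)
        nd = np.concatenate(d_parts)
        nw = np.concatenate(w_parts)
        # the other-side permutation can in principle collide pairs across
        # parallel relations; dedupe defensively within each relation
        n_dst_total = len(out.entity_types[out.relations[name].dest_type])
        key = ns * np.int64(n_dst_total) + nd
        _, first = np.unique(key, return_index=True)
        if len(first) < len(key):
            warnings.warn(f"dropped {len(key) - len(first)} duplicate null edges")
        first = np.sort(first)
        out.add_edges(name, ns[first], nd[first], nw[first])
    return out
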