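"""Synthetic single- and multi-modal datasets with planted ground truth.

The generator emulates the structure a joint expression/accessibility assay
produces: discrete cell types, negative-binomial expression counts with
elevated means on each type's marker genes, Bernoulli-open chromatin peaks
with marker peaks genomically linked to marker genes (within the
100 kb regulatory window of their TSS), peak DNA sequences with planted
transcription-factor motif strings, and one designated TF gene per planted
regulator co-expressed with its cell type. Everything is a pure function of
(parameters, seed), so fixtures regenerate bitwise-identically and every
pipeline stage can be tested against known truth without downloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

from .genome import GenomicAnnotation
from .matrix import CellFeatureMatrix

import pandas as pd

__all__ = [
    "SyntheticTruth",
    "BatchEffect",
    "simulate_multiome",
    "simulate_batches",
    "consensus_pwm",
    "evaluate_recovery",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticTruth:
    """Ground truth and full generative parameters of a synthetic dataset."""

    seed: int
    cell_labels: list
    marker_genes: dict
    marker_peaks: dict
    peak_to_gene: dict
    motif_to_peaks: dict
    tf_pairs: list
    target_genes: dict
    batch_labels: list | None = None
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        return cls(**json.loads(text))


def _nb_counts(rng, mean, shape):
    """Negative binomial via gamma-Poisson mixture (mean/dispersion form)."""
    lam = rng.gamma(shape=shape, scale=np.asarray(mean) / shape)
    return rng.poisson(lam)


def _random_seq(rng, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def consensus_pwm(consensus: str, match_prob: float = 0.91) -> list:
    """Near-one-hot PWM (rows A, C, G, T) for a consensus string."""
    off = (1.0 - match_prob) / 3.0
    cols = []
    for ch in consensus:
        col = [off] * 4
        col["ACGT".index(ch)] = match_prob
        cols.append(col)
    return np.asarray(cols).T.tolist()


def simulate_multiome(
    n_types: int = 3,
    cells_per_type: int = 300,
    n_genes: int = 600,
    markers_per_type: int = 30,
    peaks_per_gene: int = 2,
    n_peaks: int = 1500,
    motif_spec: list | None = None,
    noise: float = 0.25,
    seed: int = 0,
    baseline_mean: float = 0.04,
    gene_mean_sigma: float = 1.2,
    marker_mean: float = 5.0,
    dispersion: float = 4.0,
    marker_open_rate: float = 0.9,
    background_open_rate: float = 0.015,
    peak_rate_sigma: float = 0.8,
    peak_length: int = 200,
    motif_length: int = 8,
):
    """Generate a paired expression/accessibility dataset with planted truth.

    Returns ``(rna, atac, sequences, annotation, truth)``: raw count
    matrices, a dict of peak DNA sequences, the gene/peak annotation on a
    toy genome (0-based half-open coordinates), and the
    :class:`SyntheticTruth`.

    Parameters
    ----------
    motif_spec
        Optional list of ``{"name", "consensus", "cell_type"}`` dicts; by
        default one motif per cell type with a random consensus of
        ``motif_length`` bases, planted into that type's marker peaks. The
        first marker gene of the type doubles as the TF gene.
    noise
        Standard deviation of the log-normal per-cell depth factor.

    Notes
    -----
    Expression mimics the sparsity regime of droplet data: per-gene
    baseline means are log-normal around ``baseline_mean`` (heavy-tailed,
    most genes near-silent in most cells) and marker genes rise to
    ``marker_mean`` in their own type, so roughly 95% of background
    entries are zero while markers are detected in most cells of their
    type. Accessibility likewise uses per-peak log-normal background open
    rates around ``background_open_rate`` with marker peaks open at
    ``marker_open_rate`` in their type.
    """
    if markers_per_type * n_types > n_genes:
        raise ValueError("markers_per_type * n_types must not exceed n_genes")
    n_marker_peaks = n_types * markers_per_type * peaks_per_gene
    if n_marker_peaks > n_peaks:
        raise ValueError(
            f"need at least {n_marker_peaks} peaks for the planted markers"
        )
    rng = np.random.default_rng(seed)
    n_cells = n_types * cells_per_type
    cell_ids = [f"cell{i:04d}" for i in range(n_cells)]
    labels = np.repeat(np.arange(n_types), cells_per_type)
    gene_ids = [f"gene{j:04d}" for j in range(n_genes)]

    # --- toy genome: genes on 3 chromosomes at a fixed pitch -------------
    n_chroms = 3
    pitch = 300_000
    chrom_of = np.array([f"chr{1 + j % n_chroms}" for j in range(n_genes)], dtype=object)
    slot = np.arange(n_genes) // n_chroms
    body_len = rng.integers(2_000, 20_001, size=n_genes)
    starts = slot * pitch + 50_000
    strands = np.where(rng.random(n_genes) < 0.5, "+", "-")
    genes_df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": chrom_of,
            "start": starts,
            "end": starts + body_len,
            "strand": strands,
        }
    )

    # --- cell-type structure --------------------------------------------
    marker_genes = {}
    pool = rng.permutation(n_genes)
    for t in range(n_types):
        marker_genes[t] = np.sort(pool[t * markers_per_type : (t + 1) * markers_per_type])

    # --- RNA counts -------------------------------------------------------
    gene_base = baseline_mean * np.exp(rng.normal(0.0, gene_mean_sigma, size=n_genes))
    mean = np.tile(gene_base, (n_cells, 1))
    for t in range(n_types):
        mean[np.ix_(labels == t, marker_genes[t])] = marker_mean
    depth = np.exp(rng.normal(0.0, noise, size=n_cells))
    mean *= depth[:, None]
    rna_counts = _nb_counts(rng, mean, dispersion)
    rna = CellFeatureMatrix(
        values=sp.csr_matrix(rna_counts.astype(float)),
        cell_ids=cell_ids,
        feature_ids=gene_ids,
        feature_kind="gene",
        layer="raw",
    )

    # --- peaks: marker peaks near marker-gene TSSs, background elsewhere --
    tss = np.where(strands == "+", starts, starts + body_len - 1)
    peak_records = []
    peak_to_gene = {}
    marker_peaks = {t: [] for t in range(n_types)}
    pid = 0
    for t in range(n_types):
        for g in marker_genes[t]:
            for _ in range(peaks_per_gene):
                offset = int(rng.integers(2_000, 80_000)) * int(rng.choice([-1, 1]))
                mid = max(int(tss[g]) + offset, peak_length)
                start = mid - peak_length // 2
                name = f"peak{pid:04d}"
                peak_records.append((name, chrom_of[g], start, start + peak_length, t, True))
                peak_to_gene[name] = gene_ids[g]
                marker_peaks[t].append(name)
                pid += 1
    n_background = n_peaks - pid
    max_slot = (n_genes // n_chroms) * pitch + 100_000
    for _ in range(n_background):
        name = f"peak{pid:04d}"
        chrom = f"chr{1 + int(rng.integers(0, n_chroms))}"
        start = int(rng.integers(0, max_slot))
        peak_records.append((name, chrom, start, start + peak_length, -1, False))
        pid += 1
    peaks_df = pd.DataFrame(
        [r[:4] for r in peak_records], columns=["peak_id", "chrom", "start", "end"]
    )
    peak_ids = peaks_df["peak_id"].tolist()
    peak_type_of = np.array([r[4] for r in peak_records])

    peak_base = np.minimum(
        background_open_rate * np.exp(rng.normal(0.0, peak_rate_sigma, size=n_peaks)),
        0.2,
    )
    open_rate = np.tile(peak_base, (n_cells, 1))
    for t in range(n_types):
        cols = np.flatnonzero(peak_type_of == t)
        open_rate[np.ix_(labels == t, cols)] = marker_open_rate
    atac_counts = (rng.random((n_cells, n_peaks)) < open_rate).astype(float)
    atac = CellFeatureMatrix(
        values=sp.csr_matrix(atac_counts),
        cell_ids=cell_ids,
        feature_ids=peak_ids,
        feature_kind="peak",
        layer="raw",
    )

    # --- sequences and planted motifs ------------------------------------
    if motif_spec is None:
        motif_spec = [
            {
                "name": f"MOTIF_T{t}",
                "consensus": _random_seq(rng, motif_length),
                "cell_type": t,
            }
            for t in range(n_types)
        ]
    sequences = {p: _random_seq(rng, peak_length) for p in peak_ids}
    motif_to_peaks = {}
    for spec_item in motif_spec:
        t = spec_item["cell_type"]
        cons = spec_item["consensus"]
        assigned = list(marker_peaks[t])
        for p in assigned:
            seq = sequences[p]
            pos = int(rng.integers(0, peak_length - len(cons) + 1))
            sequences[p] = seq[:pos] + cons + seq[pos + len(cons) :]
        motif_to_peaks[spec_item["name"]] = assigned

    tf_pairs = []
    target_genes = {}
    for spec_item in motif_spec:
        t = spec_item["cell_type"]
        tf_gene = gene_ids[int(marker_genes[t][0])]
        tf_pairs.append((spec_item["name"], tf_gene))
        target_genes[spec_item["name"]] = [gene_ids[int(g)] for g in marker_genes[t]]

    ann = GenomicAnnotation(genes=genes_df, peaks=peaks_df)
    truth = SyntheticTruth(
        seed=seed,
        cell_labels=labels.tolist(),
        marker_genes={int(t): [gene_ids[int(g)] for g in gs] for t, gs in marker_genes.items()},
        marker_peaks={int(t): list(ps) for t, ps in marker_peaks.items()},
        peak_to_gene=peak_to_gene,
        motif_to_peaks=motif_to_peaks,
        tf_pairs=tf_pairs,
        target_genes=target_genes,
        params={
            "n_types": n_types,
            "cells_per_type": cells_per_type,
            "n_genes": n_genes,
            "markers_per_type": markers_per_type,
            "peaks_per_gene": peaks_per_gene,
            "n_peaks": n_peaks,
            "noise": noise,
            "baseline_mean": baseline_mean,
            "gene_mean_sigma": gene_mean_sigma,
            "marker_mean": marker_mean,
            "dispersion": dispersion,
            "marker_open_rate": marker_open_rate,
            "background_open_rate": background_open_rate,
            "peak_rate_sigma": peak_rate_sigma,
            "peak_length": peak_length,
            "motif_spec": motif_spec,
        },
    )
    return rna, atac, sequences, ann, truth


@dataclass
class BatchEffect:
    """Multiplicative batch effect specification.

    ``gene_scale_sigma`` is the s.d. of the per-gene log-normal scaling in
    each batch; ``depth_sigma`` the s.d. of the per-cell depth jitter.
    ``drop_types`` optionally removes whole cell types from given batches,
    e.g. ``{1: [2]}``. Zero sigmas and no drops yield identical iid
    subsamples.
    """

    gene_scale_sigma: float = 0.3
    depth_sigma: float = 0.2
    drop_types: dict | None = None

    def __post_init__(self):
        if self.gene_scale_sigma < 0 or self.depth_sigma < 0:
            raise ValueError("batch effect sigmas must be >= 0")


def simulate_batches(
    rna: CellFeatureMatrix,
    labels,
    n_batches: int = 2,
    effect: BatchEffect | None = None,
    seed: int = 0,
):
    """Split cells into batches and apply a multiplicative batch effect.

    Cells are dealt round-robin within each cell type, so the batches share
    the type composition; per batch a log-normal per-gene scale and
    per-cell depth jitter multiply the counts (rounded back to integers).
    With the identity effect the batches are untouched disjoint subsamples.
    """
    if n_batches < 2:
        raise ValueError("need at least two batches")
    effect = effect or BatchEffect()
    labels = np.asarray(labels)
    if len(labels) != rna.n_cells:
        raise ValueError("labels must match the number of cells")
    rng = np.random.default_rng(seed)
    assignment = np.empty(rna.n_cells, dtype=int)
    for t in np.unique(labels):
        members = np.flatnonzero(labels == t)
        assignment[members] = np.arange(len(members)) % n_batches
    drop = effect.drop_types or {}
    batches, batch_labels = [], []
    identity = effect.gene_scale_sigma == 0 and effect.depth_sigma == 0
    for b in range(n_batches):
        keep = assignment == b
        for t in drop.get(b, []):
            keep &= labels != t
        sub = rna.subset_cells(rna.cell_ids[keep])
        if identity:
            scaled = sub.values
        else:
            gene_scale = np.exp(rng.normal(0.0, effect.gene_scale_sigma, size=rna.n_features))
            depth = np.exp(rng.normal(0.0, effect.depth_sigma, size=sub.n_cells))
            scaled = sp.diags(depth) @ sub.values @ sp.diags(gene_scale)
            scaled = scaled.tocsr()
            scaled.data = np.round(scaled.data)
            scaled.eliminate_zeros()
        mat = CellFeatureMatrix(
            values=scaled,
            cell_ids=[f"b{b}:{c}" for c in sub.cell_ids],
            feature_ids=sub.feature_ids,
            feature_kind=sub.feature_kind,
            layer="raw",
        )
        batches.append(mat)
        batch_labels.append(labels[keep])
    truth = SyntheticTruth(
        seed=seed,
        cell_labels=[lab.tolist() for lab in batch_labels],
        marker_genes={},
        marker_peaks={},
        peak_to_gene={},
        motif_to_peaks={},
        tf_pairs=[],
        target_genes={},
        batch_labels=[[b] * batches[b].n_cells for b in range(n_batches)],
        params={
            "n_batches": n_batches,
            "gene_scale_sigma": effect.gene_scale_sigma,
            "depth_sigma": effect.depth_sigma,
            "drop_types": drop,
        },
    )
    return batches, truth


def evaluate_recovery(
    cell_embeddings: np.ndarray,
    cell_labels,
    batch_labels=None,
    selections=None,
    true_markers=None,
    n_neighbors: int = 15,
    seed: int = 0,
) -> dict:
    """Score how well an embedding (or a selection) recovers planted truth.

    Returns a dict with ``ari`` (k-means on the embedding against the
    planted labels), optionally ``marker_precision`` (fraction of selected
    features that are planted markers) and ``same_batch_fraction`` (mean
    fraction of each cell's ``n_neighbors`` nearest neighbors drawn from
    its own batch; about the batch size share when batches are well mixed).
    """
    cell_labels = np.asarray(cell_labels)
    out: dict = {}
    X = np.asarray(cell_embeddings, dtype=float)
    if len(cell_labels) != X.shape[0]:
        raise ValueError("labels do not match the embedding rows")
    km = KMeans(
        n_clusters=len(np.unique(cell_labels)), n_init=10, random_state=seed
    ).fit(X)
    out["ari"] = float(adjusted_rand_score(cell_labels, km.labels_))
    if selections is not None:
        if true_markers is None:
            raise ValueError("true_markers required with selections")
        sel = list(selections)
        truth_set = set(true_markers)
        out["marker_precision"] = (
            float(np.mean([s in truth_set for s in sel])) if sel else 0.0
        )
    if batch_labels is not None:
        batch_labels = np.asarray(batch_labels)
        if len(batch_labels) != X.shape[0]:
            raise ValueError("batch labels do not match the embedding rows")
        nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(X)
        idx = nn.kneighbors(X, return_distance=False)[:, 1:]
        same = batch_labels[idx] == batch_labels[:, None]
        out["same_batch_fraction"] = float(same.mean())
        per_type = {}
        for t in np.unique(cell_labels):
            sel_t = cell_labels == t
            per_type[int(t)] = float(same[sel_t].mean())
        out["same_batch_fraction_per_type"] = per_type
    return out
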