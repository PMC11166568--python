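"""Preprocessing of single-cell matrices and peak sequences.

Implements the steps upstream of graph construction: library-size
normalization of expression counts, low-presence feature filtering, optimal
one-dimensional k-means discretization of expression into a small number of
levels, dispersion-based variable gene selection, truncated-SVD variable peak
selection with knee-point detection, binarization of accessibility, and
k-mer / position-weight-matrix scanning of peak DNA sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import TruncatedSVD

from .matrix import CellFeatureMatrix

__all__ = [
    "DiscretizationModel",
    "VariableFeatureSet",
    "normalize_rna",
    "filter_low_presence",
    "discretize",
    "select_variable_genes",
    "select_variable_peaks",
    "binarize",
    "scan_sequence_features",
    "kmeans_1d",
]


# ---------------------------------------------------------------------------
# normalization / filtering
# ---------------------------------------------------------------------------


def normalize_rna(raw: CellFeatureMatrix) -> CellFeatureMatrix:
    """Library-size normalize counts to the median cell total, then log1p.

    Each cell's counts are scaled so all cells share the same total (the
    median of per-cell totals), then mapped through ``log(1 + x)``. Both maps
    are monotone within a cell, so the within-cell rank order of genes is
    preserved.

    Raises
    ------
    ValueError
        If the layer is not ``raw`` or any cell has a zero total count.
    """
    if raw.layer != "raw":
        raise ValueError(f"normalize_rna expects layer 'raw', got {raw.layer!r}")
    totals = raw.counts_per_cell()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = ", ".join(map(str, raw.cell_ids[zero[:5]]))
        raise ValueError(f"cells with zero total count: {names}")
    target = float(np.median(totals))
    X = raw.values.tocsr(copy=True).astype(float)
    # row-scale then log1p on the non-zero data only (log1p(0) = 0)
    scale = target / totals
    X = sp.diags(scale) @ X
    X = X.tocsr()
    X.data = np.log1p(X.data)
    out = raw.with_values(X, "normalized")
    out.meta = dict(raw.meta, library_size_target=target)
    return out


def filter_low_presence(m: CellFeatureMatrix, min_cells: int = 3) -> CellFeatureMatrix:
    """Drop features with non-zero entries in fewer than ``min_cells`` cells.

    ``min_cells=0`` is the identity. Cells are never removed.
    """
    if min_cells < 0:
        raise ValueError("min_cells must be >= 0")
    if min_cells == 0:
        return m
    presence = m.cells_per_feature()
    keep = presence >= min_cells
    if not keep.any():
        raise ValueError(
            f"no features present in at least {min_cells} cells; nothing left"
        )
    return m.subset_features(m.feature_ids[keep])


# ---------------------------------------------------------------------------
# optimal 1-D k-means discretization
# ---------------------------------------------------------------------------


@dataclass
class DiscretizationModel:
    """Binning of non-zero values into ``n_levels`` expression levels.

    ``boundaries`` are strictly ascending cut points over the non-zero value
    range (``n_levels - 1`` of them); ``centers`` are the weighted cluster
    means, one per level, ascending. Zeros always map to level 0; a value
    exactly on a boundary maps to the lower level.
    """

    n_levels: int
    boundaries: np.ndarray
    centers: np.ndarray

    def __post_init__(self):
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        if len(self.boundaries) != self.n_levels - 1:
            raise ValueError("need n_levels - 1 boundaries")
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly ascending")

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Map values to levels 0..n_levels (0 reserved for exact zeros)."""
        values = np.asarray(values, dtype=float)
        levels = np.searchsorted(self.boundaries, values, side="left") + 1
        levels[values == 0] = 0
        return levels

    def to_dict(self) -> dict:
        return {
            "n_levels": int(self.n_levels),
            "boundaries": self.boundaries.tolist(),
            "centers": self.centers.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscretizationModel":
        return cls(
            n_levels=int(d["n_levels"]),
            boundaries=np.asarray(d["boundaries"], dtype=float),
            centers=np.asarray(d["centers"], dtype=float),
        )


def _weighted_kmeans_dp(values: np.ndarray, weights: np.ndarray, k: int):
    """Exact optimal 1-D k-means on sorted unique values with counts.

    Dynamic program over contiguous segments (an optimal 1-D clustering is
    always a contiguous partition of the sorted values). Returns the index
    of the first value of each cluster, ascending.
    """
    u = len(values)
    c0 = np.concatenate([[0.0], np.cumsum(weights)])
    c1 = np.concatenate([[0.0], np.cumsum(weights * values)])
    c2 = np.concatenate([[0.0], np.cumsum(weights * values * values)])

    idx = np.arange(u + 1)
    # seg_cost[i, j] = SSE of values[i:j] (0 for empty / singleton segments)
    W = c0[None, :] - c0[:, None]
    M1 = c1[None, :] - c1[:, None]
    M2 = c2[None, :] - c2[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        seg = M2 - np.where(W > 0, M1 * M1 / np.where(W > 0, W, 1.0), 0.0)
    seg = np.maximum(seg, 0.0)  # clamp tiny negative round-off
    seg[idx[:, None] >= idx[None, :]] = np.inf

    D = seg[0].copy()  # one cluster over values[0:j]
    splits = np.zeros((k, u + 1), dtype=int)
    for layer in range(1, k):
        cand = D[:, None] + seg  # cand[i, j] = best (layer) clusters ending at i + seg i..j
        splits[layer] = np.argmin(cand, axis=0)
        D = cand[splits[layer], idx]
    # backtrack from full length
    starts = []
    j = u
    for layer in range(k - 1, 0, -1):
        i = int(splits[layer][j])
        starts.append(i)
        j = i
    starts.append(0)
    return np.array(starts[::-1], dtype=int)


def kmeans_1d(values: np.ndarray, k: int, max_exact: int = 2048):
    """Optimal (or near-optimal) 1-D k-means of a value multiset.

    Values are reduced to unique values with multiplicities and clustered by
    an exact dynamic program. When the number of distinct values exceeds
    ``max_exact`` they are first pooled into ``max_exact`` weighted quantile
    bins, which keeps the procedure deterministic and close to optimal at a
    bounded cost.

    Returns
    -------
    centers, boundaries
        Ascending cluster means and the ``k - 1`` midpoints between adjacent
        cluster extremes, usable as cut points.
    """
    values = np.asarray(values, dtype=float)
    uniq, counts = np.unique(values, return_counts=True)
    if len(uniq) < k:
        raise ValueError(
            f"only {len(uniq)} distinct values; reduce n_levels to at most {len(uniq)}"
        )
    if len(uniq) > max_exact:
        # pool into weighted quantile bins of roughly equal mass
        q = np.linspace(0, 1, max_exact + 1)
        edges = np.unique(np.quantile(np.repeat(uniq, counts), q))
        bin_idx = np.clip(np.searchsorted(edges, uniq, side="right") - 1, 0, len(edges) - 2)
        w = np.bincount(bin_idx, weights=counts, minlength=len(edges) - 1)
        s = np.bincount(bin_idx, weights=counts * uniq, minlength=len(edges) - 1)
        keep = w > 0
        uniq, counts = s[keep] / w[keep], w[keep]
        order = np.argsort(uniq)
        uniq, counts = uniq[order], counts[order]
    starts = _weighted_kmeans_dp(uniq, counts.astype(float), k)
    ends = np.append(starts[1:], len(uniq))
    centers = np.array(
        [
            np.average(uniq[a:b], weights=counts[a:b])
            for a, b in zip(starts, ends)
        ]
    )
    boundaries = np.array(
        [(uniq[b - 1] + uniq[b]) / 2.0 for b in starts[1:]]
    )
    return centers, boundaries


def discretize(
    m: CellFeatureMatrix, n_levels: int = 5, seed: int | None = None
) -> tuple[CellFeatureMatrix, DiscretizationModel]:
    """Bin the non-zero values of a normalized matrix into ``n_levels`` levels.

    Bin widths come from one-dimensional k-means clustering of the non-zero
    values (zeros are excluded from boundary estimation and always stay 0).
    Levels are labeled 1..n_levels by ascending cluster center, so higher
    levels mean higher expression. The default of five levels follows the
    standard coarse-grained binning of normalized expression.

    The procedure is deterministic; ``seed`` is accepted for interface
    uniformity and ignored.
    """
    if m.layer not in ("normalized", "raw"):
        raise ValueError("discretize expects a normalized (or raw) matrix")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    data = m.values.data
    if data.size == 0:
        raise ValueError("matrix has no non-zero values")
    centers, boundaries = kmeans_1d(data, n_levels)
    model = DiscretizationModel(n_levels=n_levels, boundaries=boundaries, centers=centers)
    X = m.values.copy()
    X.data = model.assign(X.data).astype(float)
    X.eliminate_zeros()
    disc = m.with_values(X, "discretized")
    disc.meta = dict(m.meta, n_levels=n_levels, discretization=model.to_dict())
    return disc, model


# ---------------------------------------------------------------------------
# variable feature selection
# ---------------------------------------------------------------------------


@dataclass
class VariableFeatureSet:
    """Result of variable gene/peak selection."""

    selected_ids: np.ndarray
    method: str
    per_feature_stats: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    n_components_used: int = 0

    def __post_init__(self):
        self.selected_ids = np.asarray(self.selected_ids, dtype=object)


def select_variable_genes(
    m: CellFeatureMatrix,
    n_top: int = 2000,
    n_bins: int = 20,
) -> VariableFeatureSet:
    """Rank genes by mean-binned normalized dispersion and take the top.

    Dispersion is variance over mean of the normalized values; genes are
    grouped into ``n_bins`` equal-width bins of mean expression and the
    dispersion is z-scored within each bin, so highly expressed genes do not
    dominate purely through their scale. Genes with zero dispersion (constant
    across cells) are never selected.
    """
    if m.n_cells < 2:
        raise ValueError("need at least two cells")
    X = m.values
    n = m.n_cells
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = (sq - mean**2) * n / max(n - 1, 1)
    # cancellation in E[x^2] - E[x]^2 leaves O(eps * mean^2) residue on
    # constant genes; clamp it to an exact zero
    var[var < 1e-10 * mean**2] = 0.0
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    candidates = disp > 0
    if not candidates.any():
        warnings.warn("all genes are constant; no variable genes selected")
        return VariableFeatureSet(
            selected_ids=np.array([], dtype=object), method="dispersion"
        )
    df = pd.DataFrame({"mean": mean, "disp": disp})
    # quantile bins keep occupancy even, so no gene sits alone in a bin
    try:
        bins = pd.qcut(df["mean"], q=n_bins, labels=False, duplicates="drop")
    except ValueError:
        bins = pd.Series(np.zeros(len(df)))
    z = np.zeros(len(df))
    for b in np.unique(bins[~np.isnan(bins)]):
        sel = bins == b
        mu = df.loc[sel, "disp"].mean()
        sd = df.loc[sel, "disp"].std(ddof=1)
        if sd and np.isfinite(sd) and sd > 0:
            z[sel.to_numpy()] = (df.loc[sel, "disp"] - mu) / sd
        else:
            z[sel.to_numpy()] = 0.0
    z = np.where(candidates, z, -np.inf)
    order = np.argsort(-z, kind="stable")
    order = order[candidates[order]]
    top = order[: min(n_top, len(order))]
    stats = pd.Series(z, index=m.feature_ids, name="normalized_dispersion")
    return VariableFeatureSet(
        selected_ids=m.feature_ids[np.sort(top)],
        method="dispersion",
        per_feature_stats=stats,
    )


def _knee_index(y: np.ndarray) -> int | None:
    """Index of maximum distance to the chord of a descending curve.

    The curve is normalized to the unit square first (as knee detectors do),
    so the answer does not depend on axis units. Returns ``None`` when the
    curve is flat (no knee exists).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3 or np.ptp(y) == 0:
        return None
    x = np.linspace(0.0, 1.0, n)
    yn = (y - y.min()) / np.ptp(y)
    # chord from first to last point of the normalized curve
    dx, dy = x[-1] - x[0], yn[-1] - yn[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (x - x[0]) - dx * (yn - yn[0])) / norm
    return int(np.argmax(dist))


def select_variable_peaks(
    m: CellFeatureMatrix,
    max_components: int = 50,
    seed: int = 0,
) -> VariableFeatureSet:
    """Select variable peaks via truncated SVD and knee-point detection.

    The number of retained components is read off the elbow of the
    explained-variance-ratio curve; within each retained component, peaks
    whose absolute loading falls before the knee of the descending sorted
    loadings curve are selected. The union over components is returned.
    Components with perfectly flat loadings contribute nothing (no knee
    exists) and raise a warning.
    """
    if m.n_cells < 2 or m.n_features < 2:
        raise ValueError("need at least two cells and two peaks")
    n_comp = int(min(max_components, min(m.shape) - 1, m.n_features - 1))
    n_comp = max(n_comp, 1)
    svd = TruncatedSVD(n_components=n_comp, random_state=seed)
    svd.fit(m.values)
    evr = svd.explained_variance_ratio_
    if len(evr) == 1:
        k_used = 1
    else:
        elbow = _knee_index(np.sort(evr)[::-1])
        k_used = (elbow + 1) if elbow is not None else len(evr)
        k_used = max(k_used, 1)
    selected: set = set()
    stats = np.zeros(m.n_features)
    for c in range(k_used):
        load = np.abs(svd.components_[c])
        stats = np.maximum(stats, load)
        order = np.argsort(-load, kind="stable")
        knee = _knee_index(load[order])
        if knee is None:
            warnings.warn(f"component {c}: flat loadings, no peaks selected")
            continue
        if knee == 0:
            continue
        selected.update(m.feature_ids[order[:knee]])
    ids = np.array(sorted(selected), dtype=object)
    return VariableFeatureSet(
        selected_ids=ids,
        method="svd_knee",
        per_feature_stats=pd.Series(stats, index=m.feature_ids, name="max_abs_loading"),
        n_components_used=k_used,
    )


# ---------------------------------------------------------------------------
# binarization and sequence features
# ---------------------------------------------------------------------------


def binarize(m: CellFeatureMatrix) -> CellFeatureMatrix:
    """Map every positive entry to 1. Idempotent; sparsity preserved."""
    X = m.values.copy()
    X.data = np.ones_like(X.data)
    return m.with_values(X, "binarized")


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _pwm_log_odds(pwm: np.ndarray, pseudo: float = 1e-3) -> np.ndarray:
    """Log-odds of a 4 x L probability (or count) matrix vs uniform background."""
    pwm = np.asarray(pwm, dtype=float)
    if pwm.shape[0] != 4:
        raise ValueError("PWM must have 4 rows (A, C, G, T)")
    col = pwm.sum(axis=0)
    probs = (pwm + pseudo) / (col + 4 * pseudo)
    return np.log(probs / 0.25)


def _scan_pwm(seq: str, lod: np.ndarray, threshold: float) -> bool:
    L = lod.shape[1]
    if len(seq) < L:
        return False
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    enc = lut[codes]
    for start in range(len(seq) - L + 1):
        window = enc[start : start + L]
        if (window < 0).any():
            continue
        if lod[window, np.arange(L)].sum() >= threshold:
            return True
    return False


def scan_sequence_features(
    sequences: dict,
    k: int = 6,
    pwms: dict | None = None,
    include_revcomp: bool = False,
    pwm_score_fraction: float = 0.8,
) -> tuple[CellFeatureMatrix, CellFeatureMatrix | None]:
    """Binary peak x k-mer and peak x motif presence matrices.

    Parameters
    ----------
    sequences
        Mapping ``peak_id -> DNA sequence`` (uppercased internally). The row
        order of the outputs follows the mapping's insertion order.
    k
        k-mer length; an entry is 1 iff the exact k-mer occurs on the forward
        strand (optionally merged with its reverse complement).
    pwms
        Optional mapping ``motif_id -> 4 x L matrix`` (rows A, C, G, T;
        counts or probabilities). A peak matches a motif when the best
        log-odds window score reaches ``pwm_score_fraction`` of the motif's
        maximum achievable score.
    include_revcomp
        Merge each k-mer with its reverse complement (canonical form) and
        scan motifs on both strands.

    Returns
    -------
    (kmer_matrix, motif_matrix)
        Binarized matrices with peaks on the rows. ``motif_matrix`` is None
        when no PWMs are supplied. Sequences shorter than ``k`` yield all-zero
        k-mer rows; windows spanning non-ACGT characters are skipped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    peak_ids = list(sequences.keys())
    per_peak_kmers: list[set] = []
    vocab: set = set()
    for pid in peak_ids:
        seq = str(sequences[pid]).upper()
        found = set()
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if any(ch not in "ACGT" for ch in w):
                continue
            if include_revcomp:
                w = min(w, _revcomp(w))
            found.add(w)
        per_peak_kmers.append(found)
        vocab.update(found)
    kmer_ids = sorted(vocab)
    kmer_col = {km: j for j, km in enumerate(kmer_ids)}
    rows, cols = [], []
    for i, found in enumerate(per_peak_kmers):
        for km in found:
            rows.append(i)
            cols.append(kmer_col[km])
    kmat = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(peak_ids), len(kmer_ids)),
    )
    kmer_matrix = CellFeatureMatrix(
        values=kmat,
        cell_ids=np.asarray(peak_ids, dtype=object),
        feature_ids=np.asarray(kmer_ids, dtype=object),
        feature_kind="kmer",
        layer="binarized",
    )

    motif_matrix = None
    if pwms:
        motif_ids = list(pwms.keys())
        dense = np.zeros((len(peak_ids), len(motif_ids)))
        for j, mid in enumerate(motif_ids):
            lod = _pwm_log_odds(pwms[mid])
            max_score = lod.max(axis=0).sum()
            threshold = pwm_score_fraction * max_score
            for i, pid in enumerate(peak_ids):
                seq = str(sequences[pid]).upper()
                hit = _scan_pwm(seq, lod, threshold)
                if not hit and include_revcomp:
                    hit = _scan_pwm(_revcomp(seq), lod, threshold)
                dense[i, j] = 1.0 if hit else 0.0
        motif_matrix = CellFeatureMatrix(
            values=sp.csr_matrix(dense),
            cell_ids=np.asarray(peak_ids, dtype=object),
            feature_ids=np.asarray(motif_ids, dtype=object),
            feature_kind="motif",
            layer="binarized",
        )
    return kmer_matrix, motif_matrix
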