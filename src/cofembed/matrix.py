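"""Sparse cell-by-feature matrices with layer semantics.

The central container is :class:`CellFeatureMatrix`, a thin, validated wrapper
around a ``scipy.sparse`` CSR matrix with string identifiers on both axes.
Every stage of the pipeline (normalization, discretization, binarization,
graph construction) consumes and produces this container, with the ``layer``
tag recording how the values are to be interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

FEATURE_KINDS = ("gene", "peak", "kmer", "motif")
LAYERS = ("raw", "normalized", "discretized", "binarized")


def _as_str_array(ids, what: str) -> np.ndarray:
    arr = np.asarray(ids, dtype=object)
    if arr.ndim != 1:
        raise ValueError(f"{what} must be one-dimensional")
    return np.array([str(x) for x in arr], dtype=object)


@dataclass
class CellFeatureMatrix:
    """A non-negative cells x features matrix with typed features.

    Parameters
    ----------
    values
        Sparse (or dense, converted on construction) matrix of shape
        ``(n_cells, n_features)``. Entries must be finite and non-negative.
    cell_ids, feature_ids
        Unique string identifiers matching the matrix dimensions.
    feature_kind
        One of ``gene``, ``peak``, ``kmer``, ``motif``.
    layer
        One of ``raw``, ``normalized``, ``discretized``, ``binarized``.
        ``discretized`` requires integer entries; ``binarized`` requires
        entries in {0, 1}.
    """

    values: sp.csr_matrix
    cell_ids: np.ndarray
    feature_ids: np.ndarray
    feature_kind: str = "gene"
    layer: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values, dtype=float))
        else:
            self.values = self.values.tocsr().astype(float)
        self.values.eliminate_zeros()
        self.cell_ids = _as_str_array(self.cell_ids, "cell_ids")
        self.feature_ids = _as_str_array(self.feature_ids, "feature_ids")
        n, m = self.values.shape
        if len(self.cell_ids) != n:
            raise ValueError(
                f"cell_ids length {len(self.cell_ids)} does not match {n} rows"
            )
        if len(self.feature_ids) != m:
            raise ValueError(
                f"feature_ids length {len(self.feature_ids)} does not match {m} columns"
            )
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell ids")
        if len(set(self.feature_ids)) != m:
            raise ValueError("duplicate feature ids")
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"feature_kind must be one of {FEATURE_KINDS}")
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}")
        data = self.values.data
        if data.size:
            if not np.all(np.isfinite(data)):
                raise ValueError("matrix contains NaN or Inf entries")
            if data.min() < 0:
                raise ValueError("matrix contains negative entries")
            if self.layer == "discretized" and not np.all(data == np.round(data)):
                raise ValueError("discretized layer requires integer entries")
            if self.layer == "binarized" and not np.all(data == 1.0):
                raise ValueError("binarized layer requires entries in {0, 1}")

    # -- basic views ---------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def cells_per_feature(self) -> np.ndarray:
        """Number of cells with a non-zero entry, per feature."""
        return np.asarray((self.values > 0).sum(axis=0)).ravel()

    def counts_per_cell(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=1)).ravel()

    def cell_index(self) -> dict:
        return {c: i for i, c in enumerate(self.cell_ids)}

    def feature_index(self) -> dict:
        return {f: j for j, f in enumerate(self.feature_ids)}

    # -- subsetting ----------------------------------------------------

    def subset_features(self, feature_ids) -> "CellFeatureMatrix":
        """Restrict to the given features, preserving their requested order."""
        idx = self.feature_index()
        cols = []
        for f in feature_ids:
            if f not in idx:
                raise KeyError(f"unknown feature id: {f!r}")
            cols.append(idx[f])
        cols = np.asarray(cols, dtype=int)
        return replace(
            self,
            values=self.values[:, cols],
            feature_ids=self.feature_ids[cols],
        )

    def subset_cells(self, cell_ids) -> "CellFeatureMatrix":
        idx = self.cell_index()
        rows = []
        for c in cell_ids:
            if c not in idx:
                raise KeyError(f"unknown cell id: {c!r}")
            rows.append(idx[c])
        rows = np.asarray(rows, dtype=int)
        return replace(
            self,
            values=self.values[rows, :],
            cell_ids=self.cell_ids[rows],
        )

    def with_values(self, values, layer: str) -> "CellFeatureMatrix":
        """Return a copy with new values and layer, identical axes."""
        return replace(self, values=values, layer=layer)

    @classmethod
    def from_dense(
        cls,
        array,
        cell_ids=None,
        feature_ids=None,
        feature_kind: str = "gene",
        layer: str = "raw",
    ) -> "CellFeatureMatrix":
        array = np.asarray(array, dtype=float)
        n, m = array.shape
        if cell_ids is None:
            cell_ids = [f"cell{i}" for i in range(n)]
        if feature_ids is None:
            feature_ids = [f"feat{j}" for j in range(m)]
        return cls(
            values=sp.csr_matrix(array),
            cell_ids=np.asarray(cell_ids, dtype=object),
            feature_ids=np.asarray(feature_ids, dtype=object),
            feature_kind=feature_kind,
            layer=layer,
        )
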