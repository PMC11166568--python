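"""Softmax transformation into the comparable co-embedding space.

Raw trained embeddings of different entity types live on different manifolds
of the latent space because their edge distributions differ. The softmax
transformation re-expresses each query entity (a feature, or a cell of a
non-anchor batch/modality) as a convex combination of reference cell
embeddings, weighted by the model's edge probabilities raised to 1/T. The
temperature T (default 0.5) controls sharpness: T -> 0 snaps each query to
its single most probable reference cell, T -> infinity averages all
references uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, softmax

from .embedding import EmbeddingModel

__all__ = ["TransformConfig", "ProbabilityProfile", "edge_probabilities", "softmax_transform"]


@dataclass
class TransformConfig:
    """Temperature of the softmax transformation (T > 0, default 0.5)."""

    temperature: float = 0.5

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


@dataclass
class ProbabilityProfile:
    """Model-estimated edge probabilities from one query to reference cells.

    ``probabilities`` sums to one; ``sorted_descending`` (ids and values) is
    the view the barcode plot draws.
    """

    query_type: str
    query_id: str
    reference_type: str
    reference_ids: np.ndarray
    probabilities: np.ndarray

    def sorted_descending(self) -> tuple[np.ndarray, np.ndarray]:
        order = np.argsort(-self.probabilities, kind="stable")
        return self.reference_ids[order], self.probabilities[order]


def _reference_matrix(model: EmbeddingModel, reference_type: str, reference_ids=None):
    if reference_ids is None:
        ids = model.ids_of_type(reference_type)
        R = model.vectors_of_type(reference_type)
    else:
        ids = np.asarray(reference_ids, dtype=object)
        R = np.stack([model.vector(reference_type, i) for i in ids])
    if len(ids) == 0:
        raise ValueError("empty reference set")
    return ids, R


def edge_probabilities(
    model: EmbeddingModel,
    query_type: str,
    query_id: str,
    reference_type: str = "cell",
    reference_ids=None,
) -> ProbabilityProfile:
    """Softmax over reference cells of the query's dot products.

    The result is the model's predicted distribution of an edge from the
    query over the reference cells (shift-invariant in the dot products).
    """
    ids, R = _reference_matrix(model, reference_type, reference_ids)
    v = model.vector(query_type, query_id)
    logits = R @ v
    return ProbabilityProfile(
        query_type=query_type,
        query_id=str(query_id),
        reference_type=reference_type,
        reference_ids=ids,
        probabilities=softmax(logits),
    )


def softmax_transform(
    model: EmbeddingModel,
    query_types: list[str] | None = None,
    reference_type: str = "cell",
    reference_ids=None,
    config: TransformConfig | None = None,
) -> EmbeddingModel:
    """Re-express query entities as convex combinations of reference cells.

    Every entity of the listed query types (default: all types except the
    reference type) is replaced by sum_i w_i v_ci with weights proportional
    to p_i^(1/T), computed in log space so sharp profiles do not underflow.
    Reference cells pass through unchanged. Returns a new model over the
    same entity registry.
    """
    config = config or TransformConfig()
    ids, R = _reference_matrix(model, reference_type, reference_ids)
    if query_types is None:
        query_types = [t for t in model.type_names() if t != reference_type]
    theta = model.theta.copy()
    invT = 1.0 / config.temperature
    for t in query_types:
        if t == reference_type:
            continue
        Q = model.vectors_of_type(t)
        if Q.shape[0] == 0:
            continue
        logits = Q @ R.T  # (n_query, n_ref)
        logp = logits - logsumexp(logits, axis=1, keepdims=True)
        weights = softmax(logp * invT, axis=1)
        rows = model.rows_of_type(t)
        theta[rows] = weights @ R
    return model.with_theta(theta)
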