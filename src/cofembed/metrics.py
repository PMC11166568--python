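"""Clustering-free cell-type-specificity metrics for embedded features.

Each feature's dot products against all cells induce a probability profile
(softmax over cells); four summary statistics score how concentrated that
profile is on a subset of cells — i.e. how cell-type-specific the feature
is — without any clustering: the max score (mean normalized similarity of
the top k cells), the Gini index and entropy of the probability profile,
and the standard deviation of the dot products. Significance is assessed
empirically against degree-matched null features trained in the same model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp, softmax
from statsmodels.stats.multitest import multipletests

from .embedding import EmbeddingModel

__all__ = [
    "max_score",
    "gini_index",
    "sd_score",
    "entropy_score",
    "feature_specificity_table",
    "significance",
    "MetricsConfig",
]


@dataclass
class MetricsConfig:
    """Parameters of the specificity table.

    ``top_k`` cells enter the max score (default 50). ``temperature``
    applies to the probability profile used for Gini and entropy (default
    1.0, i.e. the plain softmax of the dot products).
    """

    top_k: int = 50
    temperature: float = 1.0


def max_score(x: np.ndarray, k: int = 50) -> float:
    """Mean normalized similarity of the top ``k`` cells.

    The normalization ``norm(x_i) = x_i - log(mean(exp(x_j)))`` cancels any
    constant shift of the dot products; a constant profile scores exactly 0.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in 1..{n}, got {k}")
    norm = x - (logsumexp(x) - np.log(n))
    top = np.sort(norm)[-k:]
    return float(top.mean())


def gini_index(p: np.ndarray) -> float:
    """Gini index of a non-negative profile, sorted ascending first.

    0 for a uniform profile; (n-1)/n for a one-hot profile. Invariant to
    positive rescaling of ``p``.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("profile must be non-negative")
    total = p.sum()
    if total == 0:
        raise ValueError("profile is all zeros")
    n = len(p)
    ps = np.sort(p)
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * ps).sum() / (n * total))


def sd_score(x: np.ndarray) -> float:
    """Sample standard deviation (n-1 denominator) of the dot products."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two values")
    return float(np.std(x, ddof=1))


def entropy_score(p: np.ndarray) -> float:
    """Natural-log entropy -sum p log p with 0 log 0 = 0."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def feature_specificity_table(
    model: EmbeddingModel,
    feature_type: str,
    feature_ids=None,
    cell_type: str = "cell",
    config: MetricsConfig | None = None,
) -> pd.DataFrame:
    """All four specificity metrics for the requested features.

    Max score and s.d. are computed on the raw dot products; Gini and
    entropy on the softmax probability profile over cells (optionally
    tempered). Rows are indexed by feature id.
    """
    config = config or MetricsConfig()
    cells = model.vectors_of_type(cell_type)
    n = cells.shape[0]
    k = min(config.top_k, n)
    if feature_ids is None:
        feature_ids = model.ids_of_type(feature_type)
        F = model.vectors_of_type(feature_type)
    else:
        feature_ids = np.asarray(feature_ids, dtype=object)
        F = np.stack([model.vector(feature_type, f) for f in feature_ids])
    X = F @ cells.T  # (n_features, n_cells) dot products
    norm = X - (logsumexp(X, axis=1, keepdims=True) - np.log(n))
    top = np.sort(norm, axis=1)[:, -k:]
    maxes = top.mean(axis=1)
    sds = np.std(X, axis=1, ddof=1)
    P = softmax(X / config.temperature, axis=1)
    ps = np.sort(P, axis=1)
    i = np.arange(1, n + 1)
    ginis = ((2 * i - n - 1) * ps).sum(axis=1) / (n * P.sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        logP = np.where(P > 0, np.log(np.where(P > 0, P, 1.0)), 0.0)
    entropies = -(P * logP).sum(axis=1)
    return pd.DataFrame(
        {
            "kind": feature_type,
            "max_value": maxes,
            "gini": ginis,
            "sd": sds,
            "entropy": entropies,
        },
        index=pd.Index(feature_ids, name="feature"),
    )


# metrics where a LOWER value means more cell-type-specific
_LOWER_IS_SPECIFIC = {"entropy"}


def significance(
    real_table: pd.DataFrame,
    null_table: pd.DataFrame,
    metrics: tuple[str, ...] = ("max_value", "gini"),
) -> pd.DataFrame:
    """Empirical one-sided p-values against the null feature distribution.

    For each chosen metric, ``p = (1 + #null at least as extreme) / (1 +
    #null)`` — "extreme" meaning >= the observed value, except for entropy
    where the specific tail is the low one. Benjamini-Hochberg FDR is
    attached per metric.
    """
    if len(null_table) == 0:
        raise ValueError("empty null table")
    out = real_table.copy()
    n_null = len(null_table)
    for metric in metrics:
        null_vals = np.sort(null_table[metric].to_numpy())
        obs = out[metric].to_numpy()
        if metric in _LOWER_IS_SPECIFIC:
            count = np.searchsorted(null_vals, obs, side="right")
        else:
            count = n_null - np.searchsorted(null_vals, obs, side="left")
        p = (1.0 + count) / (1.0 + n_null)
        out[f"pvalue_{metric}"] = p
        out[f"fdr_{metric}"] = multipletests(p, method="fdr_bh")[1]
    return out
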