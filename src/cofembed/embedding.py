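"""Link-prediction embedding of multi-relation graphs.

Every entity (cell, gene, peak, k-mer, motif, null feature) receives a
D-dimensional vector; the score of an edge (u, v) is the dot product
theta_u . theta_v. Training minimizes a sampled multi-class log loss: each
observed edge is contrasted against candidate edges obtained by corrupting
one endpoint, drawn under the relation's type constraints — half uniformly
within the correct entity type, half proportional to entity degree.
Embeddings are regularized with amortized L2 weight decay, updated with
row-wise Adagrad, and evaluated on a held-out fraction of edges with ranking
metrics (MRR, hits@1/10/50, AUC).

Edges incident to "fixed" entity types (the shuffled null features used for
significance testing) update only the fixed entities' rows; gradients from
those edges are masked off all real rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._kernel import batch_update
from .graph import MultiRelationGraph

__all__ = [
    "EmbeddingConfig",
    "EmbeddingModel",
    "LossSample",
    "LinkEvalReport",
    "FlatEdges",
    "split_edges",
    "sample_negatives",
    "edge_loss",
    "train",
    "evaluate_link_prediction",
]


@dataclass
class EmbeddingConfig:
    """Hyper-parameters of the embedding trainer.

    ``dim`` defaults to 50 dimensions. Each positive edge is contrasted
    against ``n_neg_uniform + n_neg_degree`` corrupted candidates (100 +
    100). Weight decay ``wd`` defaults to ``auto_decay_constant / N_e``
    (N_e = number of training edges) and is applied in amortized form with
    coefficient ``wd * wd_interval`` once every ``wd_interval`` batches.
    ``eval_fraction`` of edges (5%) is held out for link-prediction
    validation.
    """

    dim: int = 50
    n_epochs: int = 10
    learning_rate: float = 0.1
    n_neg_uniform: int = 100
    n_neg_degree: int = 100
    wd: float | None = None
    wd_interval: int = 50
    auto_decay_constant: float = 6000.0
    eval_fraction: float = 0.05
    batch_size: int = 1024
    seed: int = 0
    early_stop: bool = False
    patience: int = 2

    def __post_init__(self):
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if not (0 <= self.eval_fraction < 1):
            raise ValueError("eval_fraction must be in [0, 1)")
        for name in ("n_epochs", "n_neg_uniform", "n_neg_degree", "wd_interval", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_negatives(self) -> int:
        return self.n_neg_uniform + self.n_neg_degree


# ---------------------------------------------------------------------------
# flattened graph view
# ---------------------------------------------------------------------------


class _FlatGraph:
    """Global entity indexing plus relation metadata arrays."""

    def __init__(self, g: MultiRelationGraph):
        self.type_names = list(g.entity_types)
        self.type_range: dict[str, tuple[int, int]] = {}
        ids, fixed = [], []
        lo = 0
        for name in self.type_names:
            et = g.entity_types[name]
            hi = lo + len(et)
            self.type_range[name] = (lo, hi)
            ids.append(et.ids)
            fixed.append(np.full(len(et), et.is_fixed))
            lo = hi
        self.n_entities = lo
        self.entity_ids = np.concatenate(ids) if ids else np.empty(0, dtype=object)
        self.entity_type_of = np.concatenate(
            [
                np.full(self.type_range[t][1] - self.type_range[t][0], i, dtype=np.int32)
                for i, t in enumerate(self.type_names)
            ]
        ) if ids else np.empty(0, dtype=np.int32)
        self.is_fixed = np.concatenate(fixed) if fixed else np.empty(0, dtype=bool)

        self.rel_names = list(g.relations)
        self.rel_src_lo = np.empty(len(self.rel_names), dtype=np.int64)
        self.rel_src_hi = np.empty(len(self.rel_names), dtype=np.int64)
        self.rel_dst_lo = np.empty(len(self.rel_names), dtype=np.int64)
        self.rel_dst_hi = np.empty(len(self.rel_names), dtype=np.int64)
        self.rel_touches_fixed = np.empty(len(self.rel_names), dtype=bool)
        src_all, dst_all, rel_all, w_all = [], [], [], []
        for ri, name in enumerate(self.rel_names):
            rel = g.relations[name]
            s_lo, s_hi = self.type_range[rel.source_type]
            d_lo, d_hi = self.type_range[rel.dest_type]
            self.rel_src_lo[ri], self.rel_src_hi[ri] = s_lo, s_hi
            self.rel_dst_lo[ri], self.rel_dst_hi[ri] = d_lo, d_hi
            self.rel_touches_fixed[ri] = (
                g.entity_types[rel.source_type].is_fixed
                or g.entity_types[rel.dest_type].is_fixed
            )
            src, dst, w = g.edges(name)
            src_all.append(src + s_lo)
            dst_all.append(dst + d_lo)
            rel_all.append(np.full(len(src), ri, dtype=np.int32))
            w_all.append(w)
        self.src = np.concatenate(src_all) if src_all else np.empty(0, dtype=np.int64)
        self.dst = np.concatenate(dst_all) if dst_all else np.empty(0, dtype=np.int64)
        self.rel = np.concatenate(rel_all) if rel_all else np.empty(0, dtype=np.int32)
        self.w = np.concatenate(w_all) if w_all else np.empty(0, dtype=float)


@dataclass
class FlatEdges:
    """A set of edges in global-index form, tied to a flattened graph."""

    flat: _FlatGraph
    src: np.ndarray
    dst: np.ndarray
    rel: np.ndarray
    w: np.ndarray

    def __len__(self) -> int:
        return len(self.src)


def split_edges(
    g: MultiRelationGraph, eval_fraction: float = 0.05, seed: int = 0
) -> tuple[FlatEdges, FlatEdges]:
    """Uniformly random disjoint train/eval partition of the edge list.

    Every relation is guaranteed at least one training edge: if a relation
    is fully consumed by the held-out split, one of its edges is drawn back.
    """
    if not (0 <= eval_fraction < 1):
        raise ValueError("eval_fraction must be in [0, 1)")
    flat = _FlatGraph(g)
    n = len(flat.src)
    if n == 0:
        raise ValueError("graph has no edges")
    rng = np.random.default_rng(seed)
    n_eval = int(round(eval_fraction * n))
    perm = rng.permutation(n)
    eval_mask = np.zeros(n, dtype=bool)
    eval_mask[perm[:n_eval]] = True
    for ri in range(len(flat.rel_names)):
        sel = flat.rel == ri
        if sel.any() and eval_mask[sel].all():
            # put one random edge of this relation back into training
            pool = np.flatnonzero(sel)
            eval_mask[rng.choice(pool)] = False
    tr, ev = ~eval_mask, eval_mask
    return (
        FlatEdges(flat, flat.src[tr], flat.dst[tr], flat.rel[tr], flat.w[tr]),
        FlatEdges(flat, flat.src[ev], flat.dst[ev], flat.rel[ev], flat.w[ev]),
    )


# ---------------------------------------------------------------------------
# negative sampling
# ---------------------------------------------------------------------------


class _NegativeSampler:
    """Type-constrained corruption sampler with a degree-proportional half."""

    def __init__(self, flat: _FlatGraph, train: FlatEdges, config: EmbeddingConfig):
        self.flat = flat
        self.config = config
        deg = np.zeros(flat.n_entities, dtype=np.int64)
        np.add.at(deg, train.src, 1)
        np.add.at(deg, train.dst, 1)
        self.degree = deg
        self.deg_cum = np.concatenate([[0], np.cumsum(deg)]).astype(float)

    def sample(self, src, dst, rel, rng) -> tuple[np.ndarray, np.ndarray]:
        """Corrupt each edge into ``n_negatives`` candidates.

        Returns ``(entities, replace_source)`` of shape (B, N): the sampled
        replacement entity and whether it replaces the source (else the
        destination). The positive edge itself may be re-drawn by chance and
        is kept, as in sampled-softmax practice.
        """
        cfg = self.config
        B = len(src)
        n_u, n_d = cfg.n_neg_uniform, cfg.n_neg_degree
        N = n_u + n_d
        side = rng.random((B, N)) < 0.5  # True: replace source
        lo = np.where(side, self.flat.rel_src_lo[rel][:, None], self.flat.rel_dst_lo[rel][:, None])
        hi = np.where(side, self.flat.rel_src_hi[rel][:, None], self.flat.rel_dst_hi[rel][:, None])
        ent = np.empty((B, N), dtype=np.int64)
        # uniform within the constrained type
        u = rng.random((B, n_u))
        ent[:, :n_u] = lo[:, :n_u] + np.floor(u * (hi[:, :n_u] - lo[:, :n_u])).astype(np.int64)
        # degree-proportional within the constrained type
        C = self.deg_cum
        lo_d, hi_d = lo[:, n_u:], hi[:, n_u:]
        total = C[hi_d] - C[lo_d]
        x = C[lo_d] + rng.random((B, n_d)) * total
        idx = np.searchsorted(C, x, side="right") - 1
        # types with zero total degree fall back to uniform draws
        flatfall = total <= 0
        if flatfall.any():
            u2 = rng.random(int(flatfall.sum()))
            idx[flatfall] = (
                lo_d[flatfall]
                + np.floor(u2 * (hi_d[flatfall] - lo_d[flatfall])).astype(np.int64)
            )
        ent[:, n_u:] = np.clip(idx, lo_d, hi_d - 1)
        return ent, side


@dataclass
class LossSample:
    """One positive edge with its negative candidate set."""

    src: int
    dst: int
    rel: int
    weight: float
    neg_entities: np.ndarray  # (N,) global entity rows
    neg_replaces_source: np.ndarray  # (N,) bool

    @property
    def n_negatives(self) -> int:
        return len(self.neg_entities)


def sample_negatives(
    edge: tuple[int, int, int, float],
    train: FlatEdges,
    config: EmbeddingConfig,
    rng: np.random.Generator,
) -> LossSample:
    """Draw the negative candidate set for one edge (see `_NegativeSampler`)."""
    sampler = _NegativeSampler(train.flat, train, config)
    src, dst, rel, w = edge
    ent, side = sampler.sample(
        np.array([src]), np.array([dst]), np.array([rel]), rng
    )
    flat = train.flat
    for t in (flat.entity_type_of[src], flat.entity_type_of[dst]):
        lo, hi = flat.type_range[flat.type_names[t]]
        if hi - lo == 1:
            import warnings

            warnings.warn(
                f"entity type {flat.type_names[t]!r} has a single member; "
                "corruption on that side is degenerate"
            )
    return LossSample(
        src=int(src),
        dst=int(dst),
        rel=int(rel),
        weight=float(w),
        neg_entities=ent[0],
        neg_replaces_source=side[0],
    )


def edge_loss(theta: np.ndarray, sample: LossSample) -> float:
    """Sampled multi-class log loss of one edge.

    ``w_e * (logsumexp(scores of positive and negatives) - s_positive)``,
    computed with a numerically stable logsumexp.
    """
    u, v = theta[sample.src], theta[sample.dst]
    s_pos = float(u @ v)
    E = theta[sample.neg_entities]
    other = np.where(sample.neg_replaces_source[:, None], v[None, :], u[None, :])
    s_neg = np.einsum("nd,nd->n", E, other)
    scores = np.concatenate([[s_pos], s_neg])
    mx = scores.max()
    lse = mx + np.log(np.exp(scores - mx).sum())
    return sample.weight * (lse - s_pos)


# ---------------------------------------------------------------------------
# model and report containers
# ---------------------------------------------------------------------------


class EmbeddingModel:
    """The |V| x D embedding matrix with a (type, id) -> row index."""

    def __init__(self, theta: np.ndarray, flat_or_types):
        self.theta = np.asarray(theta, dtype=np.float64)
        if isinstance(flat_or_types, _FlatGraph):
            flat = flat_or_types
            self.types = {
                t: (flat.type_range[t], flat.entity_ids[slice(*flat.type_range[t])])
                for t in flat.type_names
            }
            self.fixed_types = {
                t
                for t in flat.type_names
                if flat.is_fixed[flat.type_range[t][0] : flat.type_range[t][1]].any()
            }
        else:
            self.types = flat_or_types
            self.fixed_types = set()
        self._row_index: dict[tuple[str, str], int] | None = None

    @property
    def dim(self) -> int:
        return self.theta.shape[1]

    @property
    def n_entities(self) -> int:
        return self.theta.shape[0]

    def type_names(self) -> list[str]:
        return list(self.types)

    def ids_of_type(self, type_name: str) -> np.ndarray:
        return self.types[type_name][1]

    def rows_of_type(self, type_name: str) -> np.ndarray:
        (lo, hi), _ = self.types[type_name]
        return np.arange(lo, hi)

    def vectors_of_type(self, type_name: str) -> np.ndarray:
        (lo, hi), _ = self.types[type_name]
        return self.theta[lo:hi]

    def row(self, type_name: str, entity_id: str) -> int:
        if self._row_index is None:
            self._row_index = {}
            for t, ((lo, _), ids) in self.types.items():
                for i, eid in enumerate(ids):
                    self._row_index[(t, eid)] = lo + i
        try:
            return self._row_index[(type_name, str(entity_id))]
        except KeyError:
            raise KeyError(f"no entity {entity_id!r} of type {type_name!r}") from None

    def vector(self, type_name: str, entity_id: str) -> np.ndarray:
        return self.theta[self.row(type_name, entity_id)]

    def entity_frame(self) -> pd.DataFrame:
        recs = []
        for t, ((lo, _), ids) in self.types.items():
            for i, eid in enumerate(ids):
                recs.append((t, eid, lo + i))
        return pd.DataFrame(recs, columns=["type", "id", "row"])

    def with_theta(self, theta: np.ndarray) -> "EmbeddingModel":
        out = EmbeddingModel(theta, self.types)
        out.fixed_types = set(self.fixed_types)
        return out

    # -- persistence ---------------------------------------------------

    def save(self, outdir) -> None:
        """Write entities TSV, binary matrix (.npy) and a TSV mirror."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        frame = self.entity_frame()
        frame["is_fixed"] = frame["type"].isin(self.fixed_types)
        frame.to_csv(outdir / "entities.tsv", sep="\t", index=False)
        np.save(outdir / "embeddings.npy", self.theta)
        pd.DataFrame(self.theta).to_csv(
            outdir / "embeddings.tsv", sep="\t", index=False, header=False
        )

    @classmethod
    def load(cls, outdir) -> "EmbeddingModel":
        outdir = Path(outdir)
        theta = np.load(outdir / "embeddings.npy")
        frame = pd.read_csv(outdir / "entities.tsv", sep="\t", dtype={"id": str})
        types: dict = {}
        fixed = set()
        for t, sub in frame.groupby("type", sort=False):
            lo, hi = int(sub["row"].min()), int(sub["row"].max()) + 1
            ids = sub.sort_values("row")["id"].to_numpy(dtype=object)
            types[t] = ((lo, hi), ids)
            if "is_fixed" in sub and sub["is_fixed"].any():
                fixed.add(t)
        model = cls(theta, types)
        model.fixed_types = fixed
        return model


@dataclass
class LinkEvalReport:
    """Per-epoch losses and held-out link-prediction metrics."""

    epochs: list = field(default_factory=list)
    mrr: float | None = None
    r1: float | None = None
    r10: float | None = None
    r50: float | None = None
    auc: float | None = None
    n_eval_edges: int = 0
    tie_policy: str = "pessimistic"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _batch_scores(theta, src, dst, ent, side):
    U = theta[src]
    V = theta[dst]
    E = theta[ent]
    other = np.where(side[:, :, None], V[:, None, :], U[:, None, :])
    s_neg = np.einsum("bnd,bnd->bn", E, other)
    s_pos = np.einsum("bd,bd->b", U, V)
    return U, V, E, other, s_pos, s_neg


def train(
    g: MultiRelationGraph, config: EmbeddingConfig | None = None
) -> tuple[EmbeddingModel, LinkEvalReport]:
    """Learn entity embeddings by minibatch SGD on the sampled softmax loss.

    Embeddings are initialized uniformly in +-1/sqrt(D) from the run seed
    and updated with row-wise Adagrad (base rate ``learning_rate``). L2
    weight decay with coefficient ``wd * wd_interval`` is applied in
    proximal form to the rows touched by a batch, once every ``wd_interval``
    batches. Gradients from edges whose relation touches a fixed entity
    type are masked off all non-fixed rows. Held-out edges are scored each
    epoch; with ``early_stop``, training stops when the validation loss has
    not improved for ``patience`` epochs.
    """
    config = config or EmbeddingConfig()
    train_edges, eval_edges = split_edges(g, config.eval_fraction, config.seed)
    flat = train_edges.flat
    n_e = len(train_edges)
    wd = config.wd if config.wd is not None else config.auto_decay_constant / n_e
    lam = wd * config.wd_interval

    rng = np.random.default_rng(config.seed)
    D = config.dim
    theta = rng.uniform(-1.0 / np.sqrt(D), 1.0 / np.sqrt(D), size=(flat.n_entities, D))
    adagrad = np.zeros(flat.n_entities)
    sampler = _NegativeSampler(flat, train_edges, config)
    report = LinkEvalReport()
    lr = config.learning_rate
    batch_counter = 0
    best_val = np.inf
    stale = 0

    grad_buf = np.zeros_like(theta)
    touched_flag = np.zeros(flat.n_entities, dtype=np.bool_)
    touched_list = np.empty(flat.n_entities, dtype=np.int64)
    true_keys = np.sort(_edge_keys(flat, flat.src, flat.dst))

    for epoch in range(config.n_epochs):
        order = rng.permutation(n_e)
        total_loss = 0.0
        for start in range(0, n_e, config.batch_size):
            sel = order[start : start + config.batch_size]
            src, dst = train_edges.src[sel], train_edges.dst[sel]
            rel, w = train_edges.rel[sel], train_edges.w[sel]
            ent, side = sampler.sample(src, dst, rel, rng)
            batch_counter += 1
            do_decay = lam > 0 and batch_counter % config.wd_interval == 0
            loss = batch_update(
                theta,
                adagrad,
                grad_buf,
                touched_flag,
                touched_list,
                src,
                dst,
                ent,
                side,
                w,
                flat.rel_touches_fixed[rel],
                flat.is_fixed,
                lr,
                lam,
                do_decay,
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: non-finite loss; "
                    "reduce the learning rate or increase weight decay"
                )
            total_loss += loss

        epoch_record = {
            "epoch": epoch,
            "train_loss": float(total_loss / max(n_e, 1)),
        }
        if len(eval_edges):
            eval_rng = np.random.default_rng((config.seed, epoch))
            val = _evaluate(theta, eval_edges, sampler, eval_rng, true_keys)
            epoch_record.update(val)
        report.epochs.append(epoch_record)
        if config.early_stop and "val_loss" in epoch_record:
            if epoch_record["val_loss"] < best_val - 1e-6:
                best_val = epoch_record["val_loss"]
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break

    model = EmbeddingModel(theta, flat)
    if len(eval_edges):
        # average the final metrics over a few negative draws to reduce
        # the sampling variance of the reported ranking metrics
        draws = [
            _evaluate(
                theta,
                eval_edges,
                sampler,
                np.random.default_rng((config.seed, 997, i)),
                true_keys,
            )
            for i in range(3)
        ]
        for key in ("mrr", "r1", "r10", "r50", "auc"):
            setattr(report, key, float(np.mean([d[key] for d in draws])))
        report.n_eval_edges = len(eval_edges)
    return model, report


def _edge_keys(flat: _FlatGraph, src, dst) -> np.ndarray:
    # key on the (source, dest) pair only: parallel relations between the
    # same pair (e.g. expression levels) encode one association
    return src * np.int64(flat.n_entities) + dst


def _evaluate(theta, edges: FlatEdges, sampler: _NegativeSampler, rng, true_keys=None) -> dict:
    """Rank each held-out positive among its sampled negatives.

    Ranking follows the filtered protocol standard in link-prediction
    evaluation: sampled candidates that are themselves observed edges of
    the graph (``true_keys``) are excluded from a positive's ranking, so a
    model is not penalized for scoring a different true edge highly. The
    validation loss keeps all sampled candidates, mirroring training. Ties
    are broken pessimistically (a tying negative counts against the
    positive).
    """
    flat = sampler.flat
    B = 2048
    losses, rr, r1, r10, r50, auc, wsum = [], [], [], [], [], [], []
    for start in range(0, len(edges), B):
        sl = slice(start, start + B)
        src, dst = edges.src[sl], edges.dst[sl]
        rel, w = edges.rel[sl], edges.w[sl]
        ent, side = sampler.sample(src, dst, rel, rng)
        _, _, _, _, s_pos, s_neg = _batch_scores(theta, src, dst, ent, side)
        scores = np.concatenate([s_pos[:, None], s_neg], axis=1)
        mx = scores.max(axis=1, keepdims=True)
        lse = mx[:, 0] + np.log(np.exp(scores - mx).sum(axis=1))
        losses.append(w * (lse - s_pos))
        if true_keys is not None:
            cand_src = np.where(side, ent, src[:, None])
            cand_dst = np.where(side, dst[:, None], ent)
            keys = _edge_keys(flat, cand_src, cand_dst)
            pos_in_true = np.searchsorted(true_keys, keys)
            pos_in_true = np.clip(pos_in_true, 0, len(true_keys) - 1)
            is_true = true_keys[pos_in_true] == keys
        else:
            is_true = np.zeros_like(s_neg, dtype=bool)
        counted = ~is_true
        n_counted = counted.sum(axis=1)
        # pessimistic ranking among the counted negatives
        rank = 1 + ((s_neg >= s_pos[:, None]) & counted).sum(axis=1)
        rr.append(1.0 / rank)
        r1.append(rank <= 1)
        r10.append(rank <= 10)
        r50.append(rank <= 50)
        ok = n_counted > 0
        wins = ((s_neg > s_pos[:, None]) & counted).sum(axis=1)
        ties = ((s_neg == s_pos[:, None]) & counted).sum(axis=1)
        with np.errstate(invalid="ignore"):
            a = 1.0 - (wins + 0.5 * ties) / np.maximum(n_counted, 1)
        auc.append(a[ok])
    cat = np.concatenate
    return {
        "val_loss": float(cat(losses).mean()),
        "mrr": float(cat(rr).mean()),
        "r1": float(cat(r1).mean()),
        "r10": float(cat(r10).mean()),
        "r50": float(cat(r50).mean()),
        "auc": float(cat(auc).mean()) if len(cat(auc)) else float("nan"),
    }


def evaluate_link_prediction(
    model: EmbeddingModel,
    eval_edges: FlatEdges,
    config: EmbeddingConfig,
    rng: np.random.Generator,
    train_edges: FlatEdges | None = None,
) -> LinkEvalReport:
    """Stand-alone held-out evaluation with the training sampler.

    Negatives obey the same type constraints and degree weighting as
    training (degrees from ``train_edges`` when given, else from the
    evaluated edges themselves). Empty evaluation sets yield null metrics.
    """
    report = LinkEvalReport()
    if len(eval_edges) == 0:
        return report
    sampler = _NegativeSampler(eval_edges.flat, train_edges or eval_edges, config)
    flat = eval_edges.flat
    parts = [_edge_keys(flat, eval_edges.src, eval_edges.dst)]
    if train_edges is not None:
        parts.append(_edge_keys(flat, train_edges.src, train_edges.dst))
    true_keys = np.sort(np.concatenate(parts))
    res = _evaluate(model.theta, eval_edges, sampler, rng, true_keys)
    report.mrr = res["mrr"]
    report.r1 = res["r1"]
    report.r10 = res["r10"]
    report.r50 = res["r50"]
    report.auc = res["auc"]
    report.n_eval_edges = len(eval_edges)
    report.epochs.append({"val_loss": res["val_loss"]})
    return report
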