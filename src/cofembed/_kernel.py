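"""Inner training kernel.

The per-batch score/gradient/update step is the hot loop of training; it is
compiled with numba when available and falls back to a vectorized numpy
implementation otherwise. Both variants implement the same update: softmax
gradients of each positive against its candidate set, aggregated per row,
applied with row-wise Adagrad, with optional proximal L2 decay of the
touched rows, and gradient masking of non-fixed rows for edges whose
relation touches a fixed entity type.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _batch_update_numba(
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
    edge_masked,
    is_fixed,
    lr,
    lam,
    do_decay,
):  # pragma: no cover - compiled
    B, N = ent.shape
    D = theta.shape[1]
    n_touched = 0
    total_loss = 0.0
    s_neg = np.empty(N)
    for b in range(B):
        u = src[b]
        v = dst[b]
        tu = theta[u]
        tv = theta[v]
        s_pos = 0.0
        for d in range(D):
            s_pos += tu[d] * tv[d]
        mx = s_pos
        for n in range(N):
            e = ent[b, n]
            te = theta[e]
            s = 0.0
            if side[b, n]:
                for d in range(D):
                    s += te[d] * tv[d]
            else:
                for d in range(D):
                    s += te[d] * tu[d]
            s_neg[n] = s
            if s > mx:
                mx = s
        Z = np.exp(s_pos - mx)
        for n in range(N):
            Z += np.exp(s_neg[n] - mx)
        logZ = np.log(Z) + mx
        total_loss += w[b] * (logZ - s_pos)

        masked = edge_masked[b]
        allow_u = (not masked) or is_fixed[u]
        allow_v = (not masked) or is_fixed[v]
        cpos = w[b] * (np.exp(s_pos - logZ) - 1.0)
        if allow_u:
            if not touched_flag[u]:
                touched_flag[u] = True
                touched_list[n_touched] = u
                n_touched += 1
            gu = grad_buf[u]
            for d in range(D):
                gu[d] += cpos * tv[d]
        if allow_v:
            if not touched_flag[v]:
                touched_flag[v] = True
                touched_list[n_touched] = v
                n_touched += 1
            gv = grad_buf[v]
            for d in range(D):
                gv[d] += cpos * tu[d]
        for n in range(N):
            e = ent[b, n]
            c = w[b] * np.exp(s_neg[n] - logZ)
            te = theta[e]
            allow_e = (not masked) or is_fixed[e]
            if side[b, n]:
                if allow_e:
                    if not touched_flag[e]:
                        touched_flag[e] = True
                        touched_list[n_touched] = e
                        n_touched += 1
                    ge = grad_buf[e]
                    for d in range(D):
                        ge[d] += c * tv[d]
                if allow_v:
                    gv = grad_buf[v]
                    for d in range(D):
                        gv[d] += c * te[d]
            else:
                if allow_e:
                    if not touched_flag[e]:
                        touched_flag[e] = True
                        touched_list[n_touched] = e
                        n_touched += 1
                    ge = grad_buf[e]
                    for d in range(D):
                        ge[d] += c * tu[d]
                if allow_u:
                    gu = grad_buf[u]
                    for d in range(D):
                        gu[d] += c * te[d]

    for t in range(n_touched):
        r = touched_list[t]
        g = grad_buf[r]
        g2 = 0.0
        for d in range(D):
            g2 += g[d] * g[d]
        adagrad[r] += g2 / D
        lr_r = lr / np.sqrt(adagrad[r] + 1e-10)
        tr = theta[r]
        for d in range(D):
            tr[d] -= lr_r * g[d]
        if do_decay:
            f = 1.0 / (1.0 + lr_r * lam)
            for d in range(D):
                tr[d] *= f
        for d in range(D):
            g[d] = 0.0
        touched_flag[r] = False
    return total_loss


def _batch_update_numpy(
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
    edge_masked,
    is_fixed,
    lr,
    lam,
    do_decay,
):
    """Reference implementation of the same update, vectorized in numpy."""
    D = theta.shape[1]
    U = theta[src]
    V = theta[dst]
    E = theta[ent]
    other = np.where(side[:, :, None], V[:, None, :], U[:, None, :])
    s_neg = np.einsum("bnd,bnd->bn", E, other)
    s_pos = np.einsum("bd,bd->b", U, V)
    scores = np.concatenate([s_pos[:, None], s_neg], axis=1)
    mx = scores.max(axis=1, keepdims=True)
    ex = np.exp(scores - mx)
    Z = ex.sum(axis=1, keepdims=True)
    p = ex / Z
    loss = float((w * (np.log(Z[:, 0]) + mx[:, 0] - s_pos)).sum())

    coeff = w[:, None] * p
    cpos = w * (p[:, 0] - 1.0)
    kn = coeff[:, 1:]
    grad_U = cpos[:, None] * V + np.einsum("bn,bnd->bd", kn * (~side), E)
    grad_V = cpos[:, None] * U + np.einsum("bn,bnd->bd", kn * side, E)
    grad_E = (kn[:, :, None] * other).reshape(-1, D)

    rows = np.concatenate([src, dst, ent.reshape(-1)])
    grads = np.concatenate([grad_U, grad_V, grad_E])
    edge_tf = np.concatenate([edge_masked, edge_masked, np.repeat(edge_masked, ent.shape[1])])
    keep = ~(edge_tf & ~is_fixed[rows])
    rows, grads = rows[keep], grads[keep]
    if len(rows) == 0:
        return loss
    uniq, inv = np.unique(rows, return_inverse=True)
    S = sp.csr_matrix(
        (np.ones(len(rows)), (inv, np.arange(len(rows)))), shape=(len(uniq), len(rows))
    )
    G = S @ grads
    adagrad[uniq] += (G * G).mean(axis=1)
    lr_row = lr / np.sqrt(adagrad[uniq] + 1e-10)
    theta[uniq] -= lr_row[:, None] * G
    if do_decay:
        theta[uniq] /= 1.0 + lr_row[:, None] * lam
    return loss


def batch_update(*args, use_numba: bool = True):
    if use_numba and HAVE_NUMBA:
        return _batch_update_numba(*args)
    return _batch_update_numpy(*args)
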