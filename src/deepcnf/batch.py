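"""Batched objective/gradient evaluation across sequences.

Full-batch training evaluates the likelihood and its gradient over every
sequence at each quasi-Newton step.  Doing that one sequence at a time is
dominated by Python overhead, so this module packs the dataset into padded
(n_sequences, L_max, ...) arrays and vectorizes the convolutional stack, the
forward-backward recursions (still in log space) and all gradient
contractions across sequences at once.  Padded positions are masked to zero
after every layer, which reproduces the per-sequence zero-padding contract
exactly; results match the per-sequence path to floating-point accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dcnn import activation_deriv
from .model import ModelParams


@dataclass
class Batch:
    X: np.ndarray  # (n, L_max, D)
    Y: np.ndarray  # (n, L_max) int, zero-filled past each length
    mask: np.ndarray  # (n, L_max) float 0/1
    lengths: np.ndarray  # (n,)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def L(self) -> int:
        return self.X.shape[1]


def pack(dataset) -> Batch:
    n = len(dataset)
    lengths = np.array([len(y) for _, y in dataset])
    L = int(lengths.max())
    D = dataset[0][0].shape[1]
    X = np.zeros((n, L, D))
    Y = np.zeros((n, L), dtype=int)
    mask = np.zeros((n, L))
    for i, (x, y) in enumerate(dataset):
        X[i, : lengths[i]] = x
        Y[i, : lengths[i]] = y
        mask[i, : lengths[i]] = 1.0
    return Batch(X, Y, mask, lengths)


def _shift(A: np.ndarray, n: int) -> np.ndarray:
    """Shift along the position axis (axis 1), zero-filling."""
    out = np.zeros_like(A)
    L = A.shape[1]
    if n >= 0:
        if n < L:
            out[:, : L - n] = A[:, n:]
    else:
        if -n < L:
            out[:, -n:] = A[:, : L + n]
    return out


def _activate(z, kind):
    return np.tanh(z) if kind == "tanh" else 1.0 / (1.0 + np.exp(-z))


def batch_forward(params: ModelParams, batch: Batch) -> list[np.ndarray]:
    """All layer activations, (n, L, M_k) each; padded rows forced to zero."""
    H = [batch.X * batch.mask[:, :, None]]
    for layer, W in zip(params.spec.layers, params.W):
        below = H[-1]
        z = np.zeros((batch.n, batch.L, W.shape[2]))
        for j, off in enumerate(range(-layer.half_window, layer.half_window + 1)):
            z += _shift(below, off) @ W[j]
        H.append(_activate(z, layer.activation) * batch.mask[:, :, None])
    return H


def _lse(a: np.ndarray, axis: int) -> np.ndarray:
    m = a.max(axis=axis, keepdims=True)
    return (m + np.log(np.exp(a - m).sum(axis=axis, keepdims=True))).squeeze(axis)


def batch_objective(params: ModelParams, batch: Batch, lam: float) -> tuple[float, np.ndarray]:
    """Penalized negative log-likelihood and gradient over the whole batch."""
    spec = params.spec
    S = spec.num_labels
    n, L = batch.n, batch.L
    mask = batch.mask
    lengths = batch.lengths

    H = batch_forward(params, batch)
    node = H[-1] @ params.U  # (n, L, S)
    pair = params.T

    # forward recursion (log space), vectorized over sequences
    alpha = np.zeros((n, L, S))
    alpha[:, 0] = node[:, 0]
    for t in range(1, L):
        cand = node[:, t] + _lse(alpha[:, t - 1][:, :, None] + pair[None], axis=1)
        active = (t < lengths)[:, None]
        alpha[:, t] = np.where(active, cand, alpha[:, t - 1])
    log_z = alpha[np.arange(n), lengths - 1]
    log_z = _lse(log_z, axis=1)  # (n,)

    # backward recursion; beta is zero at and past each final position
    beta = np.zeros((n, L, S))
    for t in range(L - 2, -1, -1):
        cand = _lse(pair[None] + (node[:, t + 1] + beta[:, t + 1])[:, None, :], axis=2)
        active = (t <= lengths - 2)[:, None]
        beta[:, t] = np.where(active, cand, 0.0)

    # marginals
    singleton = np.exp(alpha + beta - log_z[:, None, None]) * mask[:, :, None]
    pair_mask = (np.arange(1, L)[None, :] < lengths[:, None]).astype(float)  # (n, L-1)
    pairwise = np.exp(
        alpha[:, :-1, :, None] + pair[None, None] + (node[:, 1:] + beta[:, 1:])[:, :, None, :]
        - log_z[:, None, None, None]
    ) * pair_mask[:, :, None, None]

    # log-likelihood
    idx_n = np.arange(n)[:, None]
    idx_t = np.arange(L)[None, :]
    node_y = node[idx_n, idx_t, batch.Y] * mask
    pair_y = pair[batch.Y[:, :-1], batch.Y[:, 1:]] * pair_mask
    total_ll = float(node_y.sum() + pair_y.sum() - log_z.sum())

    # label error and CRF gradients
    E_label = -singleton
    np.add.at(E_label, (idx_n, idx_t, batch.Y), mask)
    dT = -pairwise.sum(axis=(0, 1))
    np.add.at(dT, (batch.Y[:, :-1].ravel(), batch.Y[:, 1:].ravel()), pair_mask.ravel())
    dU = np.einsum("nlm,nls->ms", H[-1], E_label)

    # back-propagate through the convolutional stack
    E = E_label @ params.U.T
    dW: list[np.ndarray] = [None] * len(spec.layers)
    for k in range(len(spec.layers) - 1, -1, -1):
        layer = spec.layers[k]
        W = params.W[k]
        D = E * activation_deriv(H[k + 1], layer.activation) * mask[:, :, None]
        below = H[k]
        dWk = np.empty_like(W)
        E_below = np.zeros_like(below)
        for j, off in enumerate(range(-layer.half_window, layer.half_window + 1)):
            shifted = _shift(below, off)
            dWk[j] = np.einsum("nld,nlm->dm", shifted, D)
            E_below += _shift(D @ W[j].T, -off)
        dW[k] = dWk
        E = E_below

    theta = params.to_vector()
    grad_ll = np.concatenate([w.ravel() for w in dW] + [dU.ravel(), dT.ravel()])
    f = -total_ll + lam * float(theta @ theta)
    return f, -grad_ll + 2.0 * lam * theta
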