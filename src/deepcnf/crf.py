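"""Linear-chain CRF over secondary-structure labels.

The label sequence Y is scored by node log-potentials phi(i, a) = sum_m
U(m, a) * H^top_i(m) and a single shared pair log-potential table psi(a, b) =
T(a, b) applied to every adjacent label pair:

    log P(Y | X) = sum_i phi(i, y_i) + sum_{i>=2} psi(y_{i-1}, y_i) - log Z(X)

All inference runs in log space (log-sum-exp), so potentials scaled by
thousands stay finite.  Ties in decoding break toward the lower label index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp


@dataclass
class PotentialTable:
    """Node (L x S) and shared pair (S x S) log-potentials for one sequence."""

    node: np.ndarray
    pair: np.ndarray

    def __post_init__(self) -> None:
        self.node = np.asarray(self.node, dtype=float)
        self.pair = np.asarray(self.pair, dtype=float)
        if self.node.ndim != 2:
            raise ValueError("node potentials must be L x S")
        S = self.node.shape[1]
        if self.pair.shape != (S, S):
            raise ValueError(f"pair table must be {S} x {S}, got {self.pair.shape}")

    @property
    def length(self) -> int:
        return self.node.shape[0]

    @property
    def num_labels(self) -> int:
        return self.node.shape[1]


@dataclass
class ChainPosteriors:
    """Marginals from one forward-backward pass.

    ``singleton`` is L x S with P(Y_i = a | X); ``pairwise`` is (L-1) x S x S
    with P(Y_{i-1} = a, Y_i = b | X); ``log_z`` is the log partition function.
    """

    singleton: np.ndarray
    pairwise: np.ndarray
    log_z: float


def make_potentials(U: np.ndarray, T: np.ndarray, H_top: np.ndarray) -> PotentialTable:
    """Build the potential table from CRF parameters and top-layer activations."""
    U = np.asarray(U, dtype=float)
    H_top = np.asarray(H_top, dtype=float)
    if H_top.shape[1] != U.shape[0]:
        raise ValueError(f"top layer width {H_top.shape[1]} != U rows {U.shape[0]}")
    return PotentialTable(H_top @ U, T)


def _forward_messages(pot: PotentialTable) -> np.ndarray:
    L = pot.length
    alpha = np.empty_like(pot.node)
    alpha[0] = pot.node[0]
    for i in range(1, L):
        alpha[i] = pot.node[i] + logsumexp(alpha[i - 1][:, None] + pot.pair, axis=0)
    return alpha


def _backward_messages(pot: PotentialTable) -> np.ndarray:
    L = pot.length
    beta = np.zeros_like(pot.node)
    for i in range(L - 2, -1, -1):
        beta[i] = logsumexp(pot.pair + (pot.node[i + 1] + beta[i + 1])[None, :], axis=1)
    return beta


def log_partition(pot: PotentialTable) -> float:
    """log Z(X) by the forward recursion in log space."""
    return float(logsumexp(_forward_messages(pot)[-1]))


def posteriors(pot: PotentialTable) -> ChainPosteriors:
    """Singleton and pairwise label marginals plus log Z, one forward-backward pass."""
    alpha = _forward_messages(pot)
    beta = _backward_messages(pot)
    log_z = float(logsumexp(alpha[-1]))
    singleton = np.exp(alpha + beta - log_z)
    L = pot.length
    pairwise = np.empty((max(L - 1, 0), pot.num_labels, pot.num_labels))
    for i in range(1, L):
        pairwise[i - 1] = np.exp(
            alpha[i - 1][:, None] + pot.pair + (pot.node[i] + beta[i])[None, :] - log_z
        )
    return ChainPosteriors(singleton, pairwise, log_z)


def sequence_score(pot: PotentialTable, labels: np.ndarray) -> float:
    """Unnormalized log score of one label index sequence."""
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (pot.length,):
        raise ValueError(f"label sequence length {labels.shape} != {pot.length}")
    if labels.min() < 0 or labels.max() >= pot.num_labels:
        raise ValueError("label index out of range")
    score = float(pot.node[np.arange(pot.length), labels].sum())
    if pot.length > 1:
        score += float(pot.pair[labels[:-1], labels[1:]].sum())
    return score


def conditional_log_likelihood(pot: PotentialTable, labels) -> float:
    """log P(Y = labels | X); always <= 0."""
    return sequence_score(pot, np.asarray(labels, dtype=int)) - log_partition(pot)


def decode_viterbi(pot: PotentialTable) -> np.ndarray:
    """Maximum-a-posteriori label sequence; ties break to the lower index."""
    L, S = pot.node.shape
    delta = pot.node[0].copy()
    back = np.zeros((L, S), dtype=int)
    for i in range(1, L):
        cand = delta[:, None] + pot.pair  # cand[a, b]
        back[i] = np.argmax(cand, axis=0)  # argmax takes the lowest index on ties
        delta = pot.node[i] + cand[back[i], np.arange(S)]
    path = np.empty(L, dtype=int)
    path[-1] = int(np.argmax(delta))
    for i in range(L - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path


def decode_posterior(post: ChainPosteriors) -> np.ndarray:
    """Per-position argmax of the singleton marginals (ties to lower index)."""
    return np.argmax(post.singleton, axis=1)
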