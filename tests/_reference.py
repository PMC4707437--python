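"""Independent reference implementations used as test oracles.

Everything here is deliberately coded by a different route from the package:
brute-force enumeration over all label sequences for chain inference, a plain
triple-loop forward pass, and a probability-space (scaled) single-hidden-layer
conditional neural field for the depth-1 reduction check.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------- enumeration oracle for the linear chain ----------

def _score(node: np.ndarray, pair: np.ndarray, ys: tuple[int, ...]) -> float:
    s = sum(node[i, y] for i, y in enumerate(ys))
    s += sum(pair[a, b] for a, b in zip(ys[:-1], ys[1:]))
    return float(s)


def enum_log_partition(node: np.ndarray, pair: np.ndarray) -> float:
    L, S = node.shape
    scores = [_score(node, pair, ys) for ys in itertools.product(range(S), repeat=L)]
    m = max(scores)
    return m + np.log(np.sum(np.exp(np.array(scores) - m)))


def enum_marginals(node: np.ndarray, pair: np.ndarray):
    """(singleton L x S, pairwise (L-1) x S x S) by exhaustive summation."""
    L, S = node.shape
    logZ = enum_log_partition(node, pair)
    single = np.zeros((L, S))
    pairwise = np.zeros((max(L - 1, 0), S, S))
    for ys in itertools.product(range(S), repeat=L):
        p = np.exp(_score(node, pair, ys) - logZ)
        for i, y in enumerate(ys):
            single[i, y] += p
        for i in range(1, L):
            pairwise[i - 1, ys[i - 1], ys[i]] += p
    return single, pairwise


def enum_log_likelihood(node: np.ndarray, pair: np.ndarray, ys) -> float:
    return _score(node, pair, tuple(int(y) for y in ys)) - enum_log_partition(node, pair)


def enum_map(node: np.ndarray, pair: np.ndarray) -> tuple[int, ...]:
    L, S = node.shape
    best, best_score = None, -np.inf
    for ys in itertools.product(range(S), repeat=L):
        s = _score(node, pair, ys)
        if s > best_score:  # strict: keeps the lexicographically smallest on ties
            best, best_score = ys, s
    return best


# ---------- probability-space single-hidden-layer CNF ----------

class ReferenceCNF:
    """A one-hidden-layer conditional neural field coded with plain loops.

    Forward-backward runs in probability space with per-position scaling
    rather than log space; the objective and all gradients are computed with
    explicit loops.  Activation is tanh.
    """

    def __init__(self, W: np.ndarray, U: np.ndarray, T: np.ndarray, half_window: int):
        self.W = W  # (2N+1, D, M)
        self.U = U  # (M, S)
        self.T = T  # (S, S)
        self.N = half_window

    def hidden(self, X: np.ndarray) -> np.ndarray:
        L, D = X.shape
        M = self.W.shape[2]
        H = np.zeros((L, M))
        for i in range(L):
            for m in range(M):
                z = 0.0
                for j, n in enumerate(range(-self.N, self.N + 1)):
                    if 0 <= i + n < L:
                        for d in range(D):
                            z += self.W[j, d, m] * X[i + n, d]
                H[i, m] = np.tanh(z)
        return H

    def _tables(self, X: np.ndarray):
        H = self.hidden(X)
        node = np.zeros((X.shape[0], self.U.shape[1]))
        for i in range(X.shape[0]):
            for a in range(self.U.shape[1]):
                node[i, a] = sum(self.U[m, a] * H[i, m] for m in range(self.U.shape[0]))
        return H, node

    def _forward_backward(self, node: np.ndarray):
        L, S = node.shape
        phi = np.exp(node)
        psi = np.exp(self.T)
        alpha = np.zeros((L, S))
        scale = np.zeros(L)
        alpha[0] = phi[0]
        scale[0] = alpha[0].sum()
        alpha[0] /= scale[0]
        for i in range(1, L):
            for b in range(S):
                alpha[i, b] = phi[i, b] * sum(alpha[i - 1, a] * psi[a, b] for a in range(S))
            scale[i] = alpha[i].sum()
            alpha[i] /= scale[i]
        beta = np.zeros((L, S))
        beta[-1] = 1.0
        for i in range(L - 2, -1, -1):
            for a in range(S):
                beta[i, a] = sum(psi[a, b] * phi[i + 1, b] * beta[i + 1, b] for b in range(S))
            beta[i] /= scale[i + 1]
        log_z = float(np.log(scale).sum())
        single = alpha * beta
        pairwise = np.zeros((L - 1, S, S))
        for i in range(1, L):
            for a in range(S):
                for b in range(S):
                    pairwise[i - 1, a, b] = (
                        alpha[i - 1, a] * psi[a, b] * phi[i, b] * beta[i, b] / scale[i]
                    )
        return single, pairwise, log_z

    def log_likelihood(self, X: np.ndarray, ys: np.ndarray) -> float:
        _, node = self._tables(X)
        _, _, log_z = self._forward_backward(node)
        s = sum(node[i, ys[i]] for i in range(len(ys)))
        s += sum(self.T[ys[i - 1], ys[i]] for i in range(1, len(ys)))
        return float(s - log_z)

    def gradients(self, X: np.ndarray, ys: np.ndarray):
        """(ll, dW, dU, dT) of the log-likelihood for one sequence."""
        L, D = X.shape
        M, S = self.U.shape
        H, node = self._tables(X)
        single, pairwise, log_z = self._forward_backward(node)
        ll = self.log_likelihood(X, ys)
        E = np.zeros((L, S))
        for i in range(L):
            for a in range(S):
                E[i, a] = (1.0 if ys[i] == a else 0.0) - single[i, a]
        dT = np.zeros((S, S))
        for i in range(1, L):
            dT[ys[i - 1], ys[i]] += 1.0
            dT -= pairwise[i - 1]
        dU = np.zeros((M, S))
        for m in range(M):
            for a in range(S):
                dU[m, a] = sum(E[i, a] * H[i, m] for i in range(L))
        dW = np.zeros_like(self.W)
        for i in range(L):
            for m in range(M):
                err = sum(E[i, a] * self.U[m, a] for a in range(S))
                d_act = err * (1.0 - H[i, m] ** 2)
                for j, n in enumerate(range(-self.N, self.N + 1)):
                    if 0 <= i + n < L:
                        for d in range(D):
                            dW[j, d, m] += d_act * X[i + n, d]
        return ll, dW, dU, dT
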