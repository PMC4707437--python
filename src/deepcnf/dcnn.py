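"""The windowed convolutional stack: forward pass and error back-propagation.

Layer k+1 at position i is h( sum_{n=-N_k..N_k} sum_{m'} W^k_n(m',m) *
H^k_{i+n}(m') ), with h = tanh or sigmoid.  Window positions falling outside
the sequence contribute zero (zero padding).  The weight tensor W^k is shared
across positions, making each layer a 1-D convolution.

The backward pass propagates per-position error matrices E^k down the stack;
the derivative of the activation is expressed in the activation value itself:
g = 1 - H^2 for tanh, g = H(1 - H) for sigmoid.
"""

from __future__ import annotations

import numpy as np

from .model import ModelParams, ModelSpec


def _shift(A: np.ndarray, n: int) -> np.ndarray:
    """Rows of A shifted so row i of the result is A[i+n], zero outside."""
    L = A.shape[0]
    out = np.zeros_like(A)
    if n >= 0:
        if n < L:
            out[: L - n] = A[n:]
    else:
        if -n < L:
            out[-n:] = A[: L + n]
    return out


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tanh":
        return np.tanh(z)
    return 1.0 / (1.0 + np.exp(-z))


def activation_deriv(H: np.ndarray, kind: str) -> np.ndarray:
    """g() of the activation, as a function of the activation value."""
    if kind == "tanh":
        return 1.0 - H * H
    return H * (1.0 - H)


def forward(params: ModelParams, X: np.ndarray) -> list[np.ndarray]:
    """Run the stack on one sequence; returns [H^1 = X, H^2, ..., H^top]."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != params.spec.input_width:
        raise ValueError(f"features must be L x {params.spec.input_width}, got {X.shape}")
    H = [X]
    for layer, W in zip(params.spec.layers, params.W):
        below = H[-1]
        z = np.zeros((below.shape[0], W.shape[2]))
        for j, n in enumerate(range(-layer.half_window, layer.half_window + 1)):
            z += _shift(below, n) @ W[j]
        H.append(_activate(z, layer.activation))
    return H


def backward(
    params: ModelParams, H: list[np.ndarray], E_top: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Back-propagate the top-layer error through the stack.

    ``E_top`` is dLL/dH^top (L x M_top).  Returns (dW, E) where dW mirrors
    params.W and E[k] is dLL/dH^{k+1} for each hidden layer, top to input
    order matching H.
    """
    K = len(params.spec.layers)
    E: list[np.ndarray | None] = [None] * (K + 1)
    E[K] = np.asarray(E_top, dtype=float)
    dW: list[np.ndarray | None] = [None] * K
    for k in range(K - 1, -1, -1):
        layer = params.spec.layers[k]
        W = params.W[k]
        # D = dLL/d(pre-activation) at layer k+1, via g in activation values
        D = E[k + 1] * activation_deriv(H[k + 1], layer.activation)
        below = H[k]
        dWk = np.empty_like(W)
        Ek = np.zeros_like(below)
        for j, n in enumerate(range(-layer.half_window, layer.half_window + 1)):
            shifted = _shift(below, n)
            dWk[j] = shifted.T @ D
            # H^k_{i+n} feeds position i above, so its error arrives shifted back
            Ek += _shift(D @ W[j].T, -n)
        dW[k] = dWk
        E[k] = Ek
    return dW, E[1:]  # E for hidden layers only


def forward_direct(params: ModelParams, X: np.ndarray) -> list[np.ndarray]:
    """Position-by-position evaluation of the layer recurrence (reference path).

    A plain triple loop over positions, offsets and neurons; used to check the
    vectorized ``forward`` on small instances.
    """
    X = np.asarray(X, dtype=float)
    H = [X]
    for layer, W in zip(params.spec.layers, params.W):
        below = H[-1]
        L, M_below = below.shape
        M = W.shape[2]
        out = np.zeros((L, M))
        for i in range(L):
            for m in range(M):
                z = 0.0
                for j, n in enumerate(range(-layer.half_window, layer.half_window + 1)):
                    if 0 <= i + n < L:
                        for mp in range(M_below):
                            z += W[j, mp, m] * below[i + n, mp]
                out[i, m] = _activate(np.array(z), layer.activation)
        H.append(out)
    return H
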