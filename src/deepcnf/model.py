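"""Model architecture and trainable parameters.

A model is a stack of windowed (1-D convolutional) hidden layers over the
L x 42 input features, topped by a linear-chain CRF.  The trainable tensors
are the per-layer convolution weights W^k, the top-layer-to-label matrix U and
the label-pair matrix T.  There are no bias terms anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import N_FEATURES

ACTIVATIONS = ("tanh", "sigmoid")


@dataclass(frozen=True)
class LayerSpec:
    """One hidden layer: width (neurons per position), half-window, activation.

    The layer sees a window of 2*half_window + 1 positions of the layer below;
    half_window = 0 is an ordinary position-wise layer.
    """

    neurons: int
    half_window: int
    activation: str = "tanh"

    def __post_init__(self) -> None:
        if self.neurons < 1:
            raise ValueError("neurons must be >= 1")
        if self.half_window < 0:
            raise ValueError("half_window must be >= 0")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")

    @property
    def window(self) -> int:
        return 2 * self.half_window + 1


@dataclass(frozen=True)
class ModelSpec:
    """Full architecture: input width, hidden layers, number of labels."""

    layers: tuple[LayerSpec, ...]
    num_labels: int = 8
    input_width: int = N_FEATURES

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if not self.layers:
            raise ValueError("at least one hidden layer is required")
        if self.num_labels < 2:
            raise ValueError("num_labels must be >= 2")

    @property
    def widths(self) -> tuple[int, ...]:
        """Per-layer widths M_1..M_top, starting at the input layer."""
        return (self.input_width,) + tuple(l.neurons for l in self.layers)

    @property
    def top_width(self) -> int:
        return self.layers[-1].neurons


def default_spec(num_labels: int = 8) -> ModelSpec:
    """The default architecture: 5 hidden layers, 100 neurons, window 11.

    The window covers 11 residues because an average alpha helix spans about
    eleven residues (a strand about six), so one window sees a whole typical
    segment.
    """
    return ModelSpec(tuple(LayerSpec(100, 5) for _ in range(5)), num_labels=num_labels)


def small_spec(num_labels: int = 3, depth: int = 2, neurons: int = 10, half_window: int = 2) -> ModelSpec:
    """A compact preset for synthetic experiments and quick training runs."""
    return ModelSpec(tuple(LayerSpec(neurons, half_window) for _ in range(depth)), num_labels=num_labels)


def count_parameters(spec: ModelSpec) -> int:
    """Total trainable scalar count: all W^k plus U plus T (no biases)."""
    widths = spec.widths
    n = sum(l.window * widths[k] * widths[k + 1] for k, l in enumerate(spec.layers))
    return n + spec.top_width * spec.num_labels + spec.num_labels**2


@dataclass
class ModelParams:
    """The trainable tensors theta = {W^k, U, T} for a given ModelSpec.

    ``W[k]`` has shape (2*N_k+1, M_k, M_{k+1}); ``U`` is (M_top, num_labels);
    ``T`` is (num_labels, num_labels).
    """

    spec: ModelSpec
    W: list[np.ndarray] = field(default_factory=list)
    U: np.ndarray | None = None
    T: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.W and self.U is None and self.T is None:
            widths = self.spec.widths
            self.W = [
                np.zeros((l.window, widths[k], widths[k + 1]))
                for k, l in enumerate(self.spec.layers)
            ]
            self.U = np.zeros((self.spec.top_width, self.spec.num_labels))
            self.T = np.zeros((self.spec.num_labels, self.spec.num_labels))
        self.validate()

    def validate(self) -> None:
        widths = self.spec.widths
        if len(self.W) != len(self.spec.layers):
            raise ValueError("wrong number of W tensors")
        for k, (l, w) in enumerate(zip(self.spec.layers, self.W)):
            expect = (l.window, widths[k], widths[k + 1])
            if w.shape != expect:
                raise ValueError(f"W[{k}] shape {w.shape}, expected {expect}")
        if self.U.shape != (self.spec.top_width, self.spec.num_labels):
            raise ValueError(f"U shape {self.U.shape}")
        if self.T.shape != (self.spec.num_labels, self.spec.num_labels):
            raise ValueError(f"T shape {self.T.shape}")

    # --- flat-vector view, used by the optimizer and the serializer ---

    def to_vector(self) -> np.ndarray:
        parts = [w.ravel() for w in self.W] + [self.U.ravel(), self.T.ravel()]
        return np.concatenate(parts)

    @classmethod
    def from_vector(cls, spec: ModelSpec, vec: np.ndarray) -> "ModelParams":
        vec = np.asarray(vec, dtype=float)
        if vec.size != count_parameters(spec):
            raise ValueError(f"vector length {vec.size} != parameter count {count_parameters(spec)}")
        widths = spec.widths
        W, off = [], 0
        for k, l in enumerate(spec.layers):
            shape = (l.window, widths[k], widths[k + 1])
            n = int(np.prod(shape))
            W.append(vec[off : off + n].reshape(shape).copy())
            off += n
        U = vec[off : off + spec.top_width * spec.num_labels].reshape(
            spec.top_width, spec.num_labels
        ).copy()
        off += U.size
        T = vec[off:].reshape(spec.num_labels, spec.num_labels).copy()
        return cls(spec, W, U, T)

    @classmethod
    def random(cls, spec: ModelSpec, rng: np.random.Generator, scale: float = 0.05) -> "ModelParams":
        """Uniform init in [-scale, +scale]; small to keep activations unsaturated."""
        vec = rng.uniform(-scale, scale, size=count_parameters(spec))
        return cls.from_vector(spec, vec)

    def copy(self) -> "ModelParams":
        return ModelParams.from_vector(self.spec, self.to_vector())
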