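"""Maximum-likelihood training.

The objective is the negative total conditional log-likelihood over the
training sequences plus an L2 penalty lambda * ||theta||^2 over every
parameter (W, U, T; no 1/2 factor — the convention is absorbed into lambda).
Gradients are exact: dT and dU are observed-minus-expected sufficient
statistics from forward-backward, and dW follows by back-propagating the
label-layer error through the convolutional stack.  Optimization is
full-batch quasi-Newton (L-BFGS, memory 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import crf, dcnn
from .model import LayerSpec, ModelParams, ModelSpec

# A training instance is (X, y): an L x input_width feature matrix and an
# integer label-index vector of length L.
Instance = tuple[np.ndarray, np.ndarray]


@dataclass
class TrainConfig:
    """Knobs for one training run.

    ``lam`` is the L2 regularization factor (the objective sums over
    sequences, so lam scales with dataset size); 50 is the cross-validation
    optimum for the real 8-state task and the package default.
    """

    lam: float = 50.0
    max_iterations: int = 200
    gradient_tolerance: float = 1e-4
    seed: int = 0
    pretrain_layerwise: bool = False
    init_scale: float = 0.05

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.gradient_tolerance <= 0:
            raise ValueError("gradient_tolerance must be > 0")


@dataclass
class GradientSet:
    """Gradients mirroring the parameter tensors."""

    dW: list[np.ndarray]
    dU: np.ndarray
    dT: np.ndarray

    def to_vector(self) -> np.ndarray:
        return np.concatenate([w.ravel() for w in self.dW] + [self.dU.ravel(), self.dT.ravel()])


def label_error(post: crf.ChainPosteriors, labels: np.ndarray) -> np.ndarray:
    """Observed-minus-expected label indicators, L x S.

    Entry (i, a) is delta(y_i = a) - P(Y_i = a | X); this seeds the
    back-propagated error stack.
    """
    labels = np.asarray(labels, dtype=int)
    E = -post.singleton.copy()
    E[np.arange(len(labels)), labels] += 1.0
    return E


def sequence_gradients(params: ModelParams, X: np.ndarray, labels) -> tuple[float, GradientSet]:
    """Log-likelihood and its exact gradient for one labeled sequence."""
    labels = np.asarray(labels, dtype=int)
    H = dcnn.forward(params, X)
    pot = crf.make_potentials(params.U, params.T, H[-1])
    post = crf.posteriors(pot)
    ll = crf.sequence_score(pot, labels) - post.log_z

    E_label = label_error(post, labels)
    S = params.spec.num_labels
    # dT: observed adjacent-pair counts minus expected
    dT = -post.pairwise.sum(axis=0) if len(labels) > 1 else np.zeros((S, S))
    if len(labels) > 1:
        np.add.at(dT, (labels[:-1], labels[1:]), 1.0)
    dU = H[-1].T @ E_label
    E_top = E_label @ params.U.T
    dW, _ = dcnn.backward(params, H, E_top)
    return ll, GradientSet(dW, dU, dT)


def gradients(params: ModelParams, X: np.ndarray, labels) -> GradientSet:
    """Gradient of the (unpenalized) log-likelihood for one sequence."""
    return sequence_gradients(params, X, labels)[1]


def objective(params: ModelParams, dataset: list[Instance], lam: float) -> tuple[float, np.ndarray]:
    """Penalized negative log-likelihood and its gradient as a flat vector."""
    if not dataset:
        raise ValueError("empty dataset")
    theta = params.to_vector()
    total_ll = 0.0
    grad = np.zeros_like(theta)
    for X, y in dataset:
        ll, g = sequence_gradients(params, X, y)
        total_ll += ll
        grad += g.to_vector()
    f = -total_ll + lam * float(theta @ theta)
    return f, -grad + 2.0 * lam * theta


def objective_batched(params: ModelParams, batch, lam: float) -> tuple[float, np.ndarray]:
    """Same objective evaluated on a pre-packed batch (see deepcnf.batch)."""
    from .batch import batch_objective

    return batch_objective(params, batch, lam)


@dataclass
class TrainResult:
    params: ModelParams
    objective_values: list[float] = field(default_factory=list)
    final_objective: float = float("nan")
    n_iterations: int = 0
    converged: bool = False


def train(
    dataset: list[Instance],
    spec: ModelSpec,
    config: TrainConfig,
    init: ModelParams | None = None,
    log=None,
) -> TrainResult:
    """Fit theta by full-batch L-BFGS; deterministic given config.seed."""
    if not dataset:
        raise ValueError("empty dataset")
    if init is None:
        rng = np.random.default_rng(config.seed)
        init = ModelParams.random(spec, rng, config.init_scale)
    values: list[float] = []
    from .batch import batch_objective, pack

    batch = pack(dataset)
    last: dict = {}

    def fun(vec: np.ndarray):
        p = ModelParams.from_vector(spec, vec)
        f, g = batch_objective(p, batch, config.lam)
        if not np.isfinite(f):
            raise FloatingPointError(
                f"non-finite objective at iteration {len(values)} (|theta|={np.abs(vec).max():.3g})"
            )
        last["vec"], last["f"], last["g"] = vec.copy(), f, g
        return f, g

    def callback(vec: np.ndarray) -> None:
        if last.get("vec") is not None and np.array_equal(vec, last["vec"]):
            f, g = last["f"], last["g"]
        else:
            f, g = fun(vec)
        values.append(f)
        if log is not None:
            log(len(values), f, float(np.abs(g).max()))

    res = minimize(
        fun,
        init.to_vector(),
        jac=True,
        method="L-BFGS-B",
        callback=callback,
        options={
            "maxcor": 10,
            "maxiter": config.max_iterations,
            "gtol": config.gradient_tolerance,
            "ftol": 1e-12,
        },
    )
    return TrainResult(
        params=ModelParams.from_vector(spec, res.x),
        objective_values=values,
        final_objective=float(res.fun),
        n_iterations=int(res.nit),
        converged=bool(res.success),
    )


def pretrain_layerwise(
    dataset: list[Instance], spec: ModelSpec, config: TrainConfig, log=None
) -> TrainResult:
    """Supervised layer-by-layer training followed by simultaneous fine-tuning.

    Each stage trains a one-hidden-layer model (the next W plus fresh U, T) on
    the frozen activations of the stack built so far; the stacked W's then
    initialize a full simultaneous run.  With a single hidden layer this is
    identical to plain training.
    """
    if len(spec.layers) == 1:
        return train(dataset, spec, config, log=log)

    widths = spec.widths
    inputs = [X for X, _ in dataset]
    labels = [y for _, y in dataset]
    trained_W: list[np.ndarray] = []
    sub_result: TrainResult | None = None
    for k, layer in enumerate(spec.layers):
        sub_spec = ModelSpec(
            (LayerSpec(layer.neurons, layer.half_window, layer.activation),),
            num_labels=spec.num_labels,
            input_width=widths[k],
        )
        sub_config = TrainConfig(
            lam=config.lam,
            max_iterations=config.max_iterations,
            gradient_tolerance=config.gradient_tolerance,
            seed=config.seed + k,
            init_scale=config.init_scale,
        )
        sub_result = train(list(zip(inputs, labels)), sub_spec, sub_config, log=log)
        trained_W.append(sub_result.params.W[0])
        # freeze this layer's activations as the next stage's inputs
        inputs = [dcnn.forward(sub_result.params, X)[-1] for X in inputs]

    stacked = ModelParams(spec, trained_W, sub_result.params.U.copy(), sub_result.params.T.copy())
    return train(dataset, spec, config, init=stacked, log=log)


def check_gradients(
    params: ModelParams, X: np.ndarray, labels, step: float = 1e-5
) -> float:
    """Max-norm relative error between analytic and central-difference gradients.

    The analytic gradient of the log-likelihood is compared against
    (ll(theta + h e_j) - ll(theta - h e_j)) / 2h for every coordinate j.
    """
    labels = np.asarray(labels, dtype=int)
    spec = params.spec
    _, g = sequence_gradients(params, X, labels)
    analytic = g.to_vector()
    theta = params.to_vector()
    fd = np.empty_like(theta)

    def ll_at(vec: np.ndarray) -> float:
        p = ModelParams.from_vector(spec, vec)
        H = dcnn.forward(p, X)
        pot = crf.make_potentials(p.U, p.T, H[-1])
        return crf.conditional_log_likelihood(pot, labels)

    for j in range(theta.size):
        up = theta.copy()
        up[j] += step
        dn = theta.copy()
        dn[j] -= step
        fd[j] = (ll_at(up) - ll_at(dn)) / (2.0 * step)
    return float(np.abs(analytic - fd).max() / max(1.0, np.abs(analytic).max()))


def kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded random partition of range(n) into k near-equal folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size {n}")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def cross_validate(
    dataset: list[Instance],
    spec: ModelSpec,
    lambdas: list[float],
    k: int,
    seed: int,
    max_iterations: int = 100,
) -> list[dict]:
    """k-fold cross-validation over a lambda grid.

    Returns one record per lambda: {"lam", "mean_accuracy", "fold_accuracies"},
    where accuracy is the per-residue fraction correct of Viterbi decoding on
    the held-out fold.
    """
    folds = kfold_indices(len(dataset), k, seed)
    out = []
    for lam in lambdas:
        accs = []
        for f, val_idx in enumerate(folds):
            val = set(int(i) for i in val_idx)
            train_set = [inst for i, inst in enumerate(dataset) if i not in val]
            config = TrainConfig(lam=lam, max_iterations=max_iterations, seed=seed)
            result = train(train_set, spec, config)
            correct = total = 0
            for i in sorted(val):
                X, y = dataset[i]
                H = dcnn.forward(result.params, X)
                pot = crf.make_potentials(result.params.U, result.params.T, H[-1])
                pred = crf.decode_viterbi(pot)
                correct += int((pred == np.asarray(y)).sum())
                total += len(y)
            accs.append(correct / total)
        out.append(
            {"lam": lam, "mean_accuracy": float(np.mean(accs)), "fold_accuracies": accs}
        )
    return out
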