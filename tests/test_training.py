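"""Gradients, the penalized objective, and the L-BFGS driver."""

import numpy as np
import pytest

from deepcnf import (
    LayerSpec,
    ModelParams,
    ModelSpec,
    TrainConfig,
    check_gradients,
    objective,
    pretrain_layerwise,
    train,
)
from deepcnf.crf import make_potentials, posteriors
from deepcnf.dcnn import forward
from deepcnf.training import (
    cross_validate,
    kfold_indices,
    label_error,
    sequence_gradients,
)

from _reference import ReferenceCNF, enum_marginals


def small_model(rng, depth=2, width=4, input_width=6, labels=3, half_window=1, scale=0.3):
    spec = ModelSpec(
        tuple(LayerSpec(width, half_window) for _ in range(depth)),
        num_labels=labels,
        input_width=input_width,
    )
    return ModelParams.random(spec, rng, scale)


def random_instance(rng, params, L=8):
    X = rng.normal(size=(L, params.spec.input_width))
    y = rng.integers(0, params.spec.num_labels, size=L)
    return X, y


class TestLabelError:
    def test_uniform_posterior(self, rng):
        params = small_model(rng)
        params.U[:] = 0
        params.T[:] = 0
        X, y = random_instance(rng, params)
        H = forward(params, X)
        post = posteriors(make_potentials(params.U, params.T, H[-1]))
        E = label_error(post, y)
        S = params.spec.num_labels
        assert np.allclose(E[np.arange(len(y)), y], 1 - 1 / S)
        mask = np.ones_like(E, dtype=bool)
        mask[np.arange(len(y)), y] = False
        assert np.allclose(E[mask], -1 / S)

    def test_matches_enumeration_marginals(self, rng):
        params = small_model(rng)
        X, y = random_instance(rng, params, L=4)
        H = forward(params, X)
        pot = make_potentials(params.U, params.T, H[-1])
        post = posteriors(pot)
        single, _ = enum_marginals(pot.node, pot.pair)
        onehot = np.zeros_like(single)
        onehot[np.arange(4), y] = 1
        assert np.abs(label_error(post, y) - (onehot - single)).max() < 1e-8


class TestGradients:
    @pytest.mark.parametrize("seed", range(6))
    def test_finite_difference_agreement(self, seed):
        rng = np.random.default_rng(seed)
        params = small_model(rng, depth=2, width=4, half_window=1)
        X, y = random_instance(rng, params, L=int(rng.integers(2, 9)))
        assert check_gradients(params, X, y) < 1e-5

    def test_zero_input_kills_first_layer_gradient(self, rng):
        params = small_model(rng)
        L = 6
        X = np.zeros((L, params.spec.input_width))
        y = rng.integers(0, 3, size=L)
        _, g = sequence_gradients(params, X, y)
        assert np.all(g.dW[0] == 0)

    def test_perfectly_matched_posteriors_give_zero_gradient(self, rng):
        # drive U so hard that the posterior is numerically the one-hot truth
        spec = ModelSpec((LayerSpec(3, 0, "sigmoid"),), num_labels=3, input_width=3)
        params = ModelParams(spec)
        params.W[0][0] = np.eye(3) * 50
        params.U = np.eye(3) * 200
        X = np.eye(3)[np.array([0, 1, 2, 1, 0])] * 2 - 1
        y = np.array([0, 1, 2, 1, 0])
        _, g = sequence_gradients(params, X, y)
        assert np.abs(g.to_vector()).max() < 1e-6


class TestObjective:
    def test_unregularized_is_negative_log_likelihood(self, rng):
        params = small_model(rng)
        data = [random_instance(rng, params) for _ in range(3)]
        total = sum(sequence_gradients(params, X, y)[0] for X, y in data)
        f, _ = objective(params, data, lam=0.0)
        assert f == pytest.approx(-total, abs=1e-10)

    def test_zero_parameters_give_uniform_objective(self, rng):
        spec = ModelSpec((LayerSpec(4, 1),), num_labels=3, input_width=5)
        params = ModelParams(spec)
        data = [
            (rng.normal(size=(L, 5)), rng.integers(0, 3, size=L)) for L in (4, 7, 9)
        ]
        f, _ = objective(params, data, lam=5.0)
        assert f == pytest.approx((4 + 7 + 9) * np.log(3), abs=1e-10)

    @pytest.mark.parametrize("lam", [0.0, 2.5])
    def test_penalized_gradient_matches_finite_differences(self, rng, lam):
        params = small_model(rng, depth=2, width=3, input_width=4)
        data = [random_instance(rng, params, L=5) for _ in range(2)]
        _, grad = objective(params, data, lam)
        theta = params.to_vector()
        h = 1e-5
        idx = rng.choice(theta.size, size=40, replace=False)
        for j in idx:
            up, dn = theta.copy(), theta.copy()
            up[j] += h
            dn[j] -= h
            fu, _ = objective(ModelParams.from_vector(params.spec, up), data, lam)
            fd_, _ = objective(ModelParams.from_vector(params.spec, dn), data, lam)
            fd = (fu - fd_) / (2 * h)
            assert abs(grad[j] - fd) / max(1.0, abs(fd)) < 1e-5

    def test_empty_dataset_rejected(self, rng):
        with pytest.raises(ValueError):
            objective(small_model(rng), [], 1.0)


class TestCnfReduction:
    """A depth-1 model must coincide with an independently coded shallow CNF."""

    @pytest.mark.parametrize("seed", range(3))
    def test_objective_and_gradients_coincide(self, seed):
        rng = np.random.default_rng(seed)
        spec = ModelSpec((LayerSpec(3, 1, "tanh"),), num_labels=3, input_width=4)
        params = ModelParams.random(spec, rng, 0.4)
        ref = ReferenceCNF(params.W[0], params.U, params.T, half_window=1)
        X, y = random_instance(rng, params, L=7)
        ll, g = sequence_gradients(params, X, y)
        ll_ref, dW_ref, dU_ref, dT_ref = ref.gradients(X, y)
        assert abs(ll - ll_ref) < 1e-10
        assert np.abs(g.dW[0] - dW_ref).max() < 1e-10
        assert np.abs(g.dU - dU_ref).max() < 1e-10
        assert np.abs(g.dT - dT_ref).max() < 1e-10


def toy_dataset(rng, n=6, L=20, input_width=5, labels=3):
    """Separable toy task: features leak the label through 3 channels."""
    data = []
    for _ in range(n):
        y = rng.integers(0, labels, size=L)
        X = rng.normal(0, 0.3, size=(L, input_width))
        X[np.arange(L), y] += 1.5
        data.append((X, y))
    return data


class TestTrainDriver:
    def _spec(self, input_width=5, labels=3):
        return ModelSpec((LayerSpec(4, 1), LayerSpec(4, 1)), num_labels=labels,
                         input_width=input_width)

    def test_deterministic_given_seed(self, rng):
        data = toy_dataset(rng)
        cfg = TrainConfig(lam=1.0, max_iterations=15, seed=3)
        r1 = train(data, self._spec(), cfg)
        r2 = train(data, self._spec(), cfg)
        assert np.array_equal(r1.params.to_vector(), r2.params.to_vector())

    def test_objective_decreases_and_iterates_monotone(self, rng):
        data = toy_dataset(rng)
        cfg = TrainConfig(lam=1.0, max_iterations=30, seed=1)
        init = ModelParams.random(self._spec(), np.random.default_rng(1), 0.05)
        f0, _ = objective(init, data, cfg.lam)
        result = train(data, self._spec(), cfg)
        assert result.final_objective <= f0
        vals = np.array(result.objective_values)
        assert np.all(np.diff(vals) <= 1e-9)

    def test_training_improves_fit_over_uniform(self, rng):
        data = toy_dataset(rng)
        result = train(data, self._spec(), TrainConfig(lam=0.1, max_iterations=60, seed=0))
        uniform = sum(len(y) for _, y in data) * np.log(3)
        assert result.final_objective < 0.7 * uniform

    def test_regularization_shrinks_parameters(self, rng):
        data = toy_dataset(rng, n=4, L=15)
        norms = []
        for lam in (0.1, 1.0, 10.0, 100.0):
            r = train(data, self._spec(), TrainConfig(lam=lam, max_iterations=50, seed=2))
            norms.append(np.linalg.norm(r.params.to_vector()))
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))


class TestPretrainLayerwise:
    def test_single_layer_reduces_to_plain_training(self, rng):
        data = toy_dataset(rng, n=4)
        spec = ModelSpec((LayerSpec(4, 1),), num_labels=3, input_width=5)
        cfg = TrainConfig(lam=1.0, max_iterations=20, seed=5)
        a = train(data, spec, cfg)
        b = pretrain_layerwise(data, spec, cfg)
        assert np.array_equal(a.params.to_vector(), b.params.to_vector())

    def test_fine_tune_descends_from_stacked_init(self, rng):
        data = toy_dataset(rng, n=4)
        spec = ModelSpec((LayerSpec(4, 1), LayerSpec(3, 1)), num_labels=3, input_width=5)
        cfg = TrainConfig(lam=1.0, max_iterations=25, seed=5)
        result = pretrain_layerwise(data, spec, cfg)
        assert result.objective_values
        assert result.final_objective <= result.objective_values[0] + 1e-9

    def test_comparable_to_simultaneous_training(self, rng):
        data = toy_dataset(rng, n=5, L=25)
        spec = ModelSpec((LayerSpec(4, 1), LayerSpec(3, 1)), num_labels=3, input_width=5)
        cfg = TrainConfig(lam=1.0, max_iterations=80, seed=4)
        plain = train(data, spec, cfg)
        staged = pretrain_layerwise(data, spec, cfg)
        assert abs(staged.final_objective - plain.final_objective) <= 0.05 * abs(plain.final_objective)


class TestCrossValidation:
    def test_folds_partition_dataset(self):
        folds = kfold_indices(17, 5, seed=9)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(17))
        assert np.array_equal(np.concatenate(kfold_indices(17, 5, seed=9)), all_idx)

    def test_k_larger_than_dataset_rejected(self):
        with pytest.raises(ValueError):
            kfold_indices(3, 5, seed=0)

    def test_selected_lambda_beats_gross_underfitting(self, rng):
        data = toy_dataset(rng, n=8, L=20)
        spec = ModelSpec((LayerSpec(3, 1),), num_labels=3, input_width=5)
        table = cross_validate(data, spec, [1.0, 1e6], k=2, seed=0, max_iterations=40)
        by_lam = {row["lam"]: row["mean_accuracy"] for row in table}
        best = max(table, key=lambda r: r["mean_accuracy"])
        assert best["mean_accuracy"] >= by_lam[1e6]


class TestBatchedPath:
    """The padded, sequence-vectorized objective must match the per-sequence one."""

    @pytest.mark.parametrize("seed", range(3))
    def test_batched_objective_matches_reference_path(self, seed):
        rng = np.random.default_rng(seed)
        params = small_model(rng, depth=2, width=4, input_width=6)
        data = [random_instance(rng, params, L=int(rng.integers(3, 12))) for _ in range(5)]
        from deepcnf.batch import batch_objective, pack

        f_ref, g_ref = objective(params, data, lam=2.0)
        f_bat, g_bat = batch_objective(params, pack(data), lam=2.0)
        assert f_bat == pytest.approx(f_ref, rel=1e-12)
        assert np.abs(g_bat - g_ref).max() < 1e-9
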