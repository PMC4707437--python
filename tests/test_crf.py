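"""Exact chain inference against brute-force enumeration."""

import itertools

import numpy as np
import pytest

from deepcnf.crf import (
    PotentialTable,
    conditional_log_likelihood,
    decode_posterior,
    decode_viterbi,
    log_partition,
    make_potentials,
    posteriors,
    sequence_score,
)

from conftest import random_potentials
from _reference import enum_log_likelihood, enum_log_partition, enum_map, enum_marginals


class TestPotentials:
    def test_zero_parameters_give_zero_potentials(self, rng):
        H = rng.normal(size=(5, 4))
        pot = make_potentials(np.zeros((4, 3)), np.zeros((3, 3)), H)
        assert np.all(pot.node == 0) and np.all(pot.pair == 0)

    def test_constant_activation_gives_constant_node(self):
        U = np.array([[1.0, -2.0, 0.5]])
        pot = make_potentials(U, np.zeros((3, 3)), np.ones((6, 1)))
        assert np.allclose(pot.node, np.tile([1.0, -2.0, 0.5], (6, 1)))

    def test_node_matches_double_loop(self, rng):
        H = rng.normal(size=(4, 3))
        U = rng.normal(size=(3, 2))
        pot = make_potentials(U, np.zeros((2, 2)), H)
        for i in range(4):
            for a in range(2):
                assert pot.node[i, a] == pytest.approx(sum(U[m, a] * H[i, m] for m in range(3)))

    def test_width_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            make_potentials(rng.normal(size=(5, 3)), np.zeros((3, 3)), rng.normal(size=(4, 4)))


class TestPartition:
    def test_uniform_model(self):
        pot = PotentialTable(np.zeros((7, 4)), np.zeros((4, 4)))
        assert log_partition(pot) == pytest.approx(7 * np.log(4), abs=1e-12)

    def test_single_position_is_logsumexp(self, rng):
        node = rng.normal(size=(1, 5))
        pot = PotentialTable(node, rng.normal(size=(5, 5)))
        assert log_partition(pot) == pytest.approx(
            np.log(np.exp(node[0]).sum()), abs=1e-10
        )

    def test_shift_invariance_of_one_position(self, rng):
        pot = random_potentials(rng, 5, 3)
        z0 = log_partition(pot)
        node2 = pot.node.copy()
        node2[2] += 7.5
        assert log_partition(PotentialTable(node2, pot.pair)) == pytest.approx(z0 + 7.5, abs=1e-9)

    def test_large_scale_stays_finite(self, rng):
        pot = random_potentials(rng, 20, 4, scale=1000.0)
        assert np.isfinite(log_partition(pot))
        assert np.isfinite(posteriors(pot).log_z)


@pytest.mark.parametrize("seed", range(10))
class TestEnumerationAgreement:
    def _instance(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(1, 7))
        S = int(rng.integers(2, 5))
        return random_potentials(rng, L, S), rng

    def test_log_partition(self, seed):
        pot, _ = self._instance(seed)
        assert log_partition(pot) == pytest.approx(
            enum_log_partition(pot.node, pot.pair), abs=1e-8
        )

    def test_marginals(self, seed):
        pot, _ = self._instance(seed)
        post = posteriors(pot)
        single, pairwise = enum_marginals(pot.node, pot.pair)
        assert np.abs(post.singleton - single).max() < 1e-8
        if pot.length > 1:
            assert np.abs(post.pairwise - pairwise).max() < 1e-8

    def test_log_likelihood(self, seed):
        pot, rng = self._instance(seed)
        y = rng.integers(0, pot.num_labels, size=pot.length)
        ll = conditional_log_likelihood(pot, y)
        assert ll <= 1e-12
        assert ll == pytest.approx(enum_log_likelihood(pot.node, pot.pair, y), abs=1e-8)

    def test_viterbi(self, seed):
        pot, _ = self._instance(seed)
        assert tuple(decode_viterbi(pot)) == enum_map(pot.node, pot.pair)

    def test_posterior_decode(self, seed):
        pot, _ = self._instance(seed)
        single, _ = enum_marginals(pot.node, pot.pair)
        assert np.array_equal(decode_posterior(posteriors(pot)), np.argmax(single, axis=1))


class TestConsistency:
    def test_total_probability_is_one(self, rng):
        for _ in range(5):
            L, S = int(rng.integers(1, 6)), int(rng.integers(2, 5))
            pot = random_potentials(rng, L, S)
            total = sum(
                np.exp(conditional_log_likelihood(pot, ys))
                for ys in itertools.product(range(S), repeat=L)
            )
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_marginal_normalization_and_agreement(self, rng):
        pot = random_potentials(rng, 12, 4)
        post = posteriors(pot)
        assert np.allclose(post.singleton.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(post.pairwise.sum(axis=(1, 2)), 1.0, atol=1e-9)
        # pairwise slices marginalize to the adjacent singleton rows
        assert np.abs(post.pairwise.sum(axis=2) - post.singleton[:-1]).max() < 1e-9
        assert np.abs(post.pairwise.sum(axis=1) - post.singleton[1:]).max() < 1e-9

    def test_uniform_posteriors_for_zero_potentials(self):
        pot = PotentialTable(np.zeros((6, 8)), np.zeros((8, 8)))
        post = posteriors(pot)
        assert np.allclose(post.singleton, 1.0 / 8)
        ll = conditional_log_likelihood(PotentialTable(np.zeros((1, 8)), np.zeros((8, 8))), [0])
        assert ll == pytest.approx(np.log(1 / 8), abs=1e-12)


class TestDecoding:
    def test_decoupled_chain_is_positionwise_argmax(self, rng):
        node = rng.normal(size=(9, 4))
        pot = PotentialTable(node, np.zeros((4, 4)))
        expected = np.argmax(node, axis=1)
        assert np.array_equal(decode_viterbi(pot), expected)
        assert np.array_equal(decode_posterior(posteriors(pot)), expected)

    def test_all_ties_break_to_first_label(self):
        pot = PotentialTable(np.ones((5, 3)), np.ones((3, 3)))
        assert np.array_equal(decode_viterbi(pot), np.zeros(5, dtype=int))
        assert np.array_equal(decode_posterior(posteriors(pot)), np.zeros(5, dtype=int))

    def test_viterbi_score_dominates_posterior_decode(self, rng):
        for _ in range(10):
            pot = random_potentials(rng, int(rng.integers(2, 9)), int(rng.integers(2, 5)))
            v = decode_viterbi(pot)
            p = decode_posterior(posteriors(pot))
            assert sequence_score(pot, v) >= sequence_score(pot, p) - 1e-12

    def test_out_of_range_label_rejected(self, rng):
        pot = random_potentials(rng, 3, 3)
        with pytest.raises(ValueError):
            conditional_log_likelihood(pot, [0, 3, 1])
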