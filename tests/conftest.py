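import numpy as np
import pytest

from deepcnf import GeneratorConfig, generate
from deepcnf.crf import PotentialTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_potentials(rng, L, S, scale=1.0):
    return PotentialTable(rng.normal(0, scale, (L, S)), rng.normal(0, scale, (S, S)))


@pytest.fixture(scope="session")
def small_synthetic():
    """A compact strong-signal 3-state dataset shared across tests."""
    return generate(GeneratorConfig(num_sequences=30, mean_length=60, seed=7))


# A tiny hand-written PSI-BLAST-style PSSM: 3 residues, known literal scores.
PSSM_FIXTURE = """
Last position-specific scoring matrix computed, weighted observed percentages rounded down
            A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V
    1 M     0  5 -3  1  0  0  0  0  0  0  0  0  7  0  0  0  0  0  0  0
    2 K    -1 -2 -3 -4 -5  0  1  2  3  4  5  6  0  0  0  0  0  0  0  0
    3 V     2 -2  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  9

                      K         Lambda
Standard Ungapped    0.1347     0.3179
"""
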