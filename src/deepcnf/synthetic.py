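"""Seeded synthetic data with secondary-structure-like segment statistics.

Labels follow a semi-Markov process: a hidden state (helix/strand/coil, or the
8-state alphabet) persists for a geometrically distributed duration whose mean
matches typical segment lengths — about eleven residues for an alpha helix,
six for a strand — then jumps to another state.  Each residue emits a
pseudo-profile row: a per-state mean vector over the 20 PSSM columns, scaled
by ``emission_signal``, plus Gaussian noise, quantized to the integers
PSI-BLAST prints (clipped to [-9, 13]).  Residue letters are uninformative.

Because durations are geometric, the label process is exactly a first-order
hidden Markov model, so the Bayes-optimal per-residue decoder is posterior
decoding under the true model — computed here with exact discrete emission
probabilities of the quantized scores.  That oracle is the accuracy ceiling
for any model trained on the same data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from . import crf
from .alphabets import AA_ALPHABET, SS3_ALPHABET, SS8_ALPHABET, ss8_string_to_ss3
from .features import build_features
from .io import (
    LabeledSequence,
    ManifestEntry,
    ProfileMatrix,
    write_fasta,
    write_labels,
    write_manifest,
    write_pssm,
)

# Mean segment lengths (residues). Helix ~11 and strand ~6 reflect average
# observed segment lengths; the 8-state values follow the same families with
# shorter means for the minor states.
SS3_SEGMENT_MEANS = {"H": 11.0, "E": 6.0, "C": 5.0}
SS8_SEGMENT_MEANS = {"H": 11.0, "G": 4.0, "I": 3.0, "E": 6.0, "B": 2.0, "T": 4.0, "S": 3.0, "L": 5.0}

PSSM_MIN, PSSM_MAX = -9, 13
_NOISE_SD = 1.5

# File labels for SS3-state generation use the canonical 8-state representative
# of each class (H -> H, E -> E, C -> L) so label files stay 8-state-valid.
_SS3_FILE_SYMBOL = {"H": "H", "E": "E", "C": "L"}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset."""

    num_sequences: int = 200
    mean_length: int = 100
    state_set: str = "SS3"  # "SS3" or "SS8"
    mean_segment_length: dict[str, float] = field(default_factory=dict)
    transition: np.ndarray | None = None  # between-state jump matrix, row-stochastic
    emission_signal: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.state_set not in ("SS3", "SS8"):
            raise ValueError("state_set must be 'SS3' or 'SS8'")
        defaults = SS3_SEGMENT_MEANS if self.state_set == "SS3" else SS8_SEGMENT_MEANS
        self.mean_segment_length = {**defaults, **self.mean_segment_length}
        if any(v < 1 for v in self.mean_segment_length.values()):
            raise ValueError("mean segment lengths must be >= 1")
        S = len(self.states)
        if self.transition is None:
            # uniform jump to any other state
            self.transition = (np.ones((S, S)) - np.eye(S)) / (S - 1)
        self.transition = np.asarray(self.transition, dtype=float)
        if self.transition.shape != (S, S):
            raise ValueError(f"transition must be {S} x {S}")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")
        if self.emission_signal < 0:
            raise ValueError("emission_signal must be >= 0")

    @property
    def states(self) -> str:
        return SS3_ALPHABET if self.state_set == "SS3" else SS8_ALPHABET


@dataclass
class TruthModel:
    """The exact generative law: HMM transition/initial plus emission means."""

    states: str
    markov: np.ndarray  # S x S including self-loops (geometric durations)
    initial: np.ndarray  # stationary distribution of ``markov``
    means: np.ndarray  # S x 20 emission means (already signal-scaled)
    noise_sd: float

    def emission_logprob(self, pssm_rows: np.ndarray) -> np.ndarray:
        """Exact log P(quantized profile row | state), L x S.

        The observed integers arise by clipping to [-9, 13] then rounding, so
        each integer v covers the interval [v-1/2, v+1/2) with the edge bins
        absorbing the tails.
        """
        V = np.asarray(pssm_rows)  # L x 20
        lo = V - 0.5
        hi = V + 0.5
        out = np.zeros((V.shape[0], len(self.states)))
        for s in range(len(self.states)):
            mu = self.means[s]
            p_hi = norm.cdf(hi, loc=mu, scale=self.noise_sd)
            p_lo = norm.cdf(lo, loc=mu, scale=self.noise_sd)
            p_hi = np.where(V >= PSSM_MAX, 1.0, p_hi)
            p_lo = np.where(V <= PSSM_MIN, 0.0, p_lo)
            out[:, s] = np.log(np.maximum(p_hi - p_lo, 1e-300)).sum(axis=1)
        return out


@dataclass
class SyntheticDataset:
    sequences: list[LabeledSequence]
    profiles: list[ProfileMatrix]
    features: list[np.ndarray]
    state_labels: list[np.ndarray]  # hidden-state indices into truth_model.states
    truth_model: TruthModel
    config: GeneratorConfig


def _state_means(S: int, signal: float) -> np.ndarray:
    """Per-state emission mean vectors over the 20 profile columns.

    Each state favors four columns (+1.5) and disfavors two (-1.0), on a
    rotating layout so all state means are pairwise distinct; scaled by the
    signal strength.
    """
    means = np.zeros((S, 20))
    for j in range(S):
        for t in range(4):
            means[j, (5 * j + t) % 20] = 1.5
        means[j, (5 * j + 10) % 20] = -1.0
        means[j, (5 * j + 11) % 20] = -1.0
    return signal * means


def _truth_model(config: GeneratorConfig) -> TruthModel:
    states = config.states
    S = len(states)
    stay = np.array([1.0 - 1.0 / config.mean_segment_length[s] for s in states])
    markov = np.diag(stay) + (1.0 - stay)[:, None] * config.transition
    # stationary distribution: left eigenvector of the chain
    vals, vecs = np.linalg.eig(markov.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi) / np.abs(pi).sum()
    return TruthModel(states, markov, pi, _state_means(S, config.emission_signal), _NOISE_SD)


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Draw a dataset; deterministic given config.seed."""
    rng = np.random.default_rng(config.seed)
    truth = _truth_model(config)
    S = len(truth.states)
    sequences, profiles, feats, state_paths = [], [], [], []
    for n in range(config.num_sequences):
        L = max(5, int(rng.poisson(config.mean_length)))
        path = np.empty(L, dtype=int)
        path[0] = rng.choice(S, p=truth.initial)
        for i in range(1, L):
            path[i] = rng.choice(S, p=truth.markov[path[i - 1]])
        raw = truth.means[path] + rng.normal(0.0, truth.noise_sd, size=(L, 20))
        pssm = np.rint(np.clip(raw, PSSM_MIN, PSSM_MAX)).astype(int)
        residues = "".join(rng.choice(list(AA_ALPHABET), size=L))
        if config.state_set == "SS3":
            labels = "".join(_SS3_FILE_SYMBOL[truth.states[j]] for j in path)
        else:
            labels = "".join(truth.states[j] for j in path)
        seq = LabeledSequence(f"syn{n:04d}", residues, labels)
        profile = ProfileMatrix(pssm.astype(float), AA_ALPHABET, residues)
        sequences.append(seq)
        profiles.append(profile)
        feats.append(build_features(residues, profile))
        state_paths.append(path)
    return SyntheticDataset(sequences, profiles, feats, state_paths, truth, config)


def write_dataset(dataset: SyntheticDataset, out_dir) -> Path:
    """Write FASTA + PSSM + label files and a manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for seq, profile in zip(dataset.sequences, dataset.profiles):
        fasta = out / f"{seq.id}.fasta"
        pssm = out / f"{seq.id}.pssm"
        labels = out / f"{seq.id}.labels"
        write_fasta([(seq.id, seq.residues)], fasta)
        write_pssm(profile, pssm)
        write_labels([(seq.id, seq.labels)], labels)
        entries.append(ManifestEntry(seq.id, fasta, pssm, labels))
    manifest = out / "manifest.tsv"
    write_manifest(entries, manifest)
    return manifest


def to_instances(dataset: SyntheticDataset, three_state: bool = True):
    """Training instances (X, y) with y indexed into SS3 or SS8 alphabets."""
    insts = []
    for seq, X in zip(dataset.sequences, dataset.features):
        if three_state:
            labels3 = ss8_string_to_ss3(seq.labels)
            y = np.array([SS3_ALPHABET.index(c) for c in labels3])
        else:
            y = np.array([SS8_ALPHABET.index(c) for c in seq.labels])
        insts.append((X, y))
    return insts


def bayes_decode(dataset: SyntheticDataset, index: int) -> np.ndarray:
    """Posterior (per-position MAP) decoding of one sequence under the truth."""
    truth = dataset.truth_model
    emis = truth.emission_logprob(dataset.profiles[index].values)
    node = emis.copy()
    node[0] += np.log(truth.initial)
    pot = crf.PotentialTable(node, np.log(truth.markov))
    return crf.decode_posterior(crf.posteriors(pot))


def bayes_accuracy(dataset: SyntheticDataset) -> float:
    """Per-residue accuracy of the optimal decoder that knows the truth model."""
    if dataset.truth_model is None:
        raise ValueError("dataset carries no truth model")
    correct = total = 0
    for i, path in enumerate(dataset.state_labels):
        pred = bayes_decode(dataset, i)
        correct += int((pred == path).sum())
        total += len(path)
    return correct / total
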