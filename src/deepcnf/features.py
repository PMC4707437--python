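"""Per-residue input features: sigmoid-squashed profile + amino-acid one-hot.

Each residue is described by 42 numbers: 21 profile features (the 20 PSSM
log-odds scores passed through 1/(1+e^-x), plus an unknown-residue slot) and a
21-way indicator of the amino-acid type (20 standard residues + 'X').
"""

from __future__ import annotations

import numpy as np

from .alphabets import AA_ALPHABET, AA_INDEX
from .io import ProfileMatrix

N_FEATURES = 42
_N_PROFILE = 21  # 20 squashed PSSM columns + unknown-residue slot
_N_ONEHOT = 21


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def build_features(residues: str, profile: ProfileMatrix) -> np.ndarray:
    """Build the L x 42 feature matrix for one sequence.

    Columns 0-19: sigmoid of the PSSM log-odds, reordered to the package's
    alphabetical amino-acid column order.  Column 20: 1 where the residue is
    non-standard, else 0; at such positions the 20 profile columns are set to
    the neutral value 0.5.  Columns 21-41: one-hot amino-acid type, with
    non-standard residues mapped to the trailing 'X' slot.
    """
    L = len(residues)
    if profile.values.shape[0] != L:
        raise ValueError(f"sequence length {L} != profile rows {profile.values.shape[0]}")
    order = [profile.residue_order.index(a) for a in AA_ALPHABET]
    squashed = sigmoid(profile.values[:, order])

    X = np.zeros((L, N_FEATURES))
    X[:, :20] = squashed
    for i, aa in enumerate(residues.upper()):
        j = AA_INDEX.get(aa)
        if j is None:  # unknown residue: neutral profile, flag slot, 'X' one-hot
            X[i, :20] = 0.5
            X[i, 20] = 1.0
            X[i, _N_PROFILE + 20] = 1.0
        else:
            X[i, _N_PROFILE + j] = 1.0
    return X


def validate_features(X: np.ndarray) -> None:
    """Check the structural invariants of a feature matrix (raises on failure)."""
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise ValueError(f"feature matrix must be L x {N_FEATURES}, got {X.shape}")
    prof = X[:, :_N_PROFILE]
    if not ((prof > 0) & (prof < 1)).all():
        # the unknown flag column is binary, all others strictly inside (0,1)
        flag = X[:, 20]
        if not np.isin(flag, (0.0, 1.0)).all() or not ((X[:, :20] > 0) & (X[:, :20] < 1)).all():
            raise ValueError("profile block outside (0,1)")
    onehot = X[:, _N_PROFILE:]
    if not np.isin(onehot, (0.0, 1.0)).all() or not np.allclose(onehot.sum(axis=1), 1.0):
        raise ValueError("amino-acid indicator block is not one-hot")
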