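"""Build per-residue input features from a PSI-BLAST profile.

Each residue is encoded by 42 numbers: the 20 PSSM log-odds scores squashed
through a sigmoid (plus an unknown-residue slot), and a 21-way one-hot of the
amino-acid type.
"""

import numpy as np

from deepcnf import build_features
from deepcnf.io import parse_pssm_text

PSSM = """
Last position-specific scoring matrix computed
            A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V
    1 M     0  5 -3  1  0  0  0  0  0  0  0  0  7  0  0  0  0  0  0  0
    2 K    -1 -2 -3 -4 -5  0  1  2  3  4  5  6  0  0  0  0  0  0  0  0
    3 V     2 -2  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  0  9
"""

profile = parse_pssm_text(PSSM)
X = build_features(profile.residues, profile)

print(f"sequence: {profile.residues}")
print(f"feature matrix shape: {X.shape}")  # (3, 42)
np.set_printoptions(precision=3, suppress=True)
print("squashed profile block, residue 1:", X[0, :5], "...")
print("one-hot block row sums:", X[:, 21:].sum(axis=1))
# A PSSM score of 0 maps to 0.5, +5 to ~0.993, -3 to ~0.047: the sigmoid puts
# every profile feature on a common (0,1) scale before the network sees it.
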