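"""Exact inference on the label chain: partition function, marginals, decoding.

A tiny random model shows the quantities the conditional random field layer
computes: log Z(X), per-position label posteriors, the probability of the
observed labeling, and the Viterbi path.
"""

import numpy as np

from deepcnf import (
    LayerSpec,
    ModelParams,
    ModelSpec,
    conditional_log_likelihood,
    decode_posterior,
    decode_viterbi,
    forward,
    make_potentials,
    posteriors,
)

rng = np.random.default_rng(0)
spec = ModelSpec((LayerSpec(6, 2), LayerSpec(6, 2)), num_labels=3, input_width=42)
params = ModelParams.random(spec, rng, scale=0.5)

L = 12
X = rng.normal(size=(L, 42))
H = forward(params, X)  # activations of every layer; H[-1] is the top layer
pot = make_potentials(params.U, params.T, H[-1])
post = posteriors(pot)

print(f"log Z(X) = {post.log_z:.4f}")
print("posterior of label 0 along the chain:", np.round(post.singleton[:, 0], 3))

y = rng.integers(0, 3, size=L)
print(f"log P(random labeling | X) = {conditional_log_likelihood(pot, y):.4f}")

print("Viterbi path:   ", decode_viterbi(pot))
print("posterior path: ", decode_posterior(post))
# The Viterbi path maximizes the joint sequence probability; the posterior
# path maximizes per-position accuracy. They usually agree, but need not.
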