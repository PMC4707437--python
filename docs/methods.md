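# Methods

## Model

The model is a conditional random field over per-residue secondary-structure
labels whose node potentials are produced by a stack of windowed 1-D
convolutional layers. The graphical structure is a linear chain: one node
potential Φ(i, a) = Σₘ U(m, a)·H_i^top(m) per position and one shared pair
potential Ψ(a, b) = T(a, b) applied to every adjacent label pair from
position 2 onward. There are no separate start/end potentials; the first
position simply has no incoming pair term. Exponentiating the summed
potentials and normalizing by the partition function Z(X) gives P(Y | X).

Each hidden layer computes, for every position i and output neuron m,
h(Σ_{n=-N..N} Σ_{m'} W_n(m', m) · H_{i+n}(m')), where 2N+1 is the layer's
window. Weights are position-independent (a convolution); window positions
falling outside [1, L] contribute zero. Zero padding was chosen over window
truncation because it keeps the pre-activation a fixed linear function of the
(padded) layer below, which makes the back-propagation bookkeeping exact and
position-uniform. There are no bias terms: the parameter count is then
Σₖ (2Nₖ+1)·Mₖ·Mₖ₊₁ + M_top·S + S², which reproduces the familiar
~50K/~270K/~500K/~700K accounting for 1/3/5/7 hidden layers of 100 neurons
with window 11 over 42 inputs and 8 labels (exactly 47,064 / 267,064 /
487,064 / 707,064).

The hidden activation defaults to tanh; sigmoid is selectable per layer. Both
are supported in the gradient expressions via their activation-valued
derivatives, g = 1 − H² and g = H(1 − H). tanh is the default because
zero-centered activations keep the early optimization steps well scaled under
the small symmetric initialization used here.

## Input features

Per residue: 20 PSSM log-odds scores mapped through 1/(1+e^(−x)), one
unknown-residue slot, and a 21-way amino-acid indicator (20 standard residues
in alphabetical one-letter order, then 'X'). A profile has 20 columns, so the
21st profile feature is defined as an unknown-residue flag: at positions whose
residue is non-standard the flag is 1 and the 20 squashed profile values are
set to the neutral 0.5. PSSM files are parsed from the PSI-BLAST ASCII layout
(first 20-column log-odds block); label strings use the 8-state DSSP alphabet
(H, G, I, E, B, T, S, L), with blank/'-'/'C' coil dialects normalized to 'L',
and the standard 3-state grouping G,H,I → H; E,B → E; T,S,L → C.

## Inference

All chain inference runs in log space with log-sum-exp: the forward recursion
gives log Z, a forward-backward pass gives per-position and adjacent-pair
posteriors, and both are validated against brute-force enumeration to 1e−8 on
small instances. Potentials scaled by 10³ remain finite. Decoding is Viterbi
by default (posterior/marginal decoding is available behind a flag); ties
break toward the lower label index so results are deterministic.

## Training

The objective is −Σ log P(Y|X) + λ‖θ‖² summed (not averaged) over sequences,
with the penalty applied to all of W, U, T and no ½ factor — the convention
is absorbed into λ. Gradients are exact: dT and dU are
observed-minus-expected sufficient statistics from forward-backward; the
label error E_i(a) = δ(y_i = a) − P(Y_i = a|X) is mapped through U to the top
layer and back-propagated through the stack, with dW accumulated against the
(zero-padded) layer-below activations. A central-finite-difference checker
(step 1e−5) verifies every parameter class to relative error below 1e−5; the
depth-1 model is additionally checked against an independently written
shallow conditional neural field (probability-space forward-backward, plain
loops) to 1e−10.

Optimization is full-batch L-BFGS (memory 10, gradient tolerance 1e−4,
configurable iteration cap) via SciPy; parameters initialize uniformly in
[−0.05, 0.05] from the run's seed, so training is deterministic given seed
and data. For speed, the trainer evaluates the objective on the whole dataset
at once: sequences are packed into padded arrays, activations at padded
positions are masked to zero (which reproduces the per-sequence zero-padding
contract exactly), and the chain recursions and gradient contractions are
vectorized across sequences; the batched path is tested to agree with the
per-sequence reference path to 1e−9.

Layer-wise supervised pretraining is available as an alternative: each stage
trains a one-hidden-layer model (the next W plus fresh U, T) on the frozen
activations of the stack built so far, and the stacked weights then
initialize a simultaneous fine-tuning run. With one hidden layer this reduces
exactly to plain training. The default remains simultaneous training.

The regularization factor defaults to λ = 50, the cross-validation optimum
for the real 8-state task; a k-fold cross-validation driver (seeded random
partition, per-fold training, per-residue Viterbi accuracy) is provided for
selecting λ on new data. Because the objective sums over sequences, λ scales
with dataset size.

## Evaluation

Q8/Q3 is the percentage of residues labeled correctly. Per-state recall and
precision use the convention that an empty denominator scores 0, keeping
aggregated reports NaN-free. SOV follows the 1999 segment-overlap
definition: each observed segment s1 pairs with every same-state overlapping
predicted segment s2 and contributes len(s1)·min((minov+δ)/maxov, 1) with
δ = min(maxov−minov, minov, ⌊len(s1)/2⌋, ⌊len(s2)/2⌋); observed segments with
no overlap contribute only to the normalizer. SOV is computed on 3-state
strings (8-state inputs are mapped first) and, across a dataset, is
residue-weighted per sequence since segment structure does not concatenate
across chains. The earlier 1994 δ variant is not implemented.

## Synthetic data and the Bayes oracle

The generator emulates the two properties of real data the model exploits:
segment-structured labels and label-correlated profile features. Labels
follow a semi-Markov process with geometric durations (mean 11 for helix, 6
for strand, 5 for coil in 3-state mode; shorter means for the minor 8-state
classes) and uniform jumps between distinct states; geometric durations are a
simplification of real segment-length laws chosen because they make the
process exactly first-order Markov. Emissions are per-state mean vectors over
the 20 profile columns (four favored columns at +1.5, two disfavored at −1.0,
rotated per state), scaled by `emission_signal` (default 1.0), plus Gaussian
noise (sd 1.5), quantized to integers clipped to PSI-BLAST's printed [−9, 13]
range so the real parser dialect is exercised. Residue letters are sampled
uniformly and carry no label information.

Because the label process is an HMM and the quantized emission distribution
is known in closed form (normal CDF differences with absorbing edge bins),
the Bayes-optimal per-residue decoder is posterior decoding under the true
model, computed exactly with the same chain machinery. This gives a
principled ceiling: trained models must approach it (learnability) and cannot
exceed it beyond sampling noise. What the generator does **not** emulate:
real evolutionary profiles (column correlations, alignment depth effects),
amino-acid/structure propensities in the sequence itself, or non-geometric
segment-length distributions — so passing these tests demonstrates the
correctness and trainability of the machinery, not real-data accuracy.

Synthetic experiments in the tests and the acceptance script use a compact
2-hidden-layer architecture (10 neurons, window 5) on 200 training and 50
test sequences of mean length 100: wide enough to absorb the planted signal —
it reaches ~99% of the Bayes ceiling — while keeping a full training run
under a minute.

## Numerical conventions and limitations

- Normalization checks use tolerance 1e−9; enumeration comparisons 1e−8.
- Non-finite objectives during line search raise a diagnostic error rather
  than letting the optimizer wander.
- Model files are JSON (version-tagged, shape-checked); floats round-trip
  float64 exactly.
- The likelihood is non-convex for depth ≥ 1, so training finds a local
  optimum dependent on the seed; determinism is per-seed, not global.
- No mini-batching, momentum/Adam, dropout, pooling, or higher-order label
  cliques: the model family is deliberately the exact-inference chain CRF
  with a feed-forward convolutional feature stack.
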