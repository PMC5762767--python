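# Methods

## Model

SdaMLL is a two-stage pipeline for multi-label gene→pathway annotation
from bounded term-frequency features x ∈ [0,1]^d.

**Denoising autoencoder (one layer).** Encoder y = s(Wx̃ + b) with
W ∈ R^{d′×d}; decoder z = s(Wᵀy + b′) with *tied* weights — the decoder
weight is never stored, reconstruction always goes through the transpose —
and a free decoder bias b′. Corruption is masking noise: for each
presented input, exactly ⌊v·d⌋ coordinates chosen uniformly without
replacement are set to 0 (floor chosen as the rounding rule; the count is
fixed, not Bernoulli). The training loss compares the reconstruction to
the *clean* input; both the summed squared error Σ(x−z)² and the
cross-entropy −Σ[x ln z + (1−x) ln(1−z)] are implemented. Cross-entropy is
the default (it is the natural loss for sigmoid outputs on [0,1] data);
reconstructions that saturate to exactly 0/1 in float arithmetic are
clamped to [1e−12, 1−1e−12] and the clamp is logged.

**Optimization of the DAE** is deliberately plain: per-instance SGD with a
fixed learning rate, no momentum, minibatching or weight decay. Weights
initialize uniformly on ±4·√(6/(d+d′)) (the standard sigmoid-net scaling),
biases at zero; the per-epoch instance order is reshuffled from the seeded
stream. The per-epoch trace records the mean *clean-input* reconstruction
loss so layers can be compared on the quantity they are meant to minimize.

**Stacking** is greedy and layer-local: layer k+1 trains on the
uncorrupted codes of layers 1..k, with corruption applied to its own
input. `layer_sizes=[d]` yields an empty stack whose transform is the
identity — this is how the plain BP-MLL baseline is produced from the same
code path. At transform time no corruption is applied. The default
architecture is a single code layer of 200 units when d > 200 (the
reference compression of ~19k terms to 200), else ⌈d/2⌉.

**BP-MLL.** One hidden sigmoid layer of M units and one sigmoid output
per label, trained online on the pairwise exponential error
E_i = (1/(|Y||Ȳ|))·Σ_{(k,l)∈Y×Ȳ} exp(−(c_k − c_l)). The published
description leaves the back-propagated deltas d_j and e_s undefined; we
derive them by the chain rule with sigmoid activations —

- d_j = (1/(|Y||Ȳ|))·e^{−c_j}·Σ_{l∈Ȳ} e^{c_l}·c_j(1−c_j) for j ∈ Y, and
  the negated mirror image for j ∈ Ȳ;
- e_s = (Σ_j d_j w_sj)·b_s(1−b_s);

updates ΔW_sj = α d_j b_s, ΔV_hs = α e_s a_h, Δθ_j = α d_j, Δγ_s = α e_s.
These formulas are *enforced*, not trusted: the test suite compares
−update/α against central finite differences of E_i at random and
near-symmetric parameter points (relative error < 1e−5). Exploiting
exp(−(c_k−c_l)) = e^{−c_k}·e^{c_l}, both E_i and the deltas cost O(N)
rather than O(N²). The sigmoid is used throughout for consistency with
the autoencoder (the original BP-MLL literature uses tanh; the activation
is fixed here, and the finite-difference oracle would pin any variant
equally).

**Stopping rule.** "Global error stops decreasing" is implemented as: E is
evaluated after each epoch, and training stops after `patience` (default
3) consecutive epochs without a strict decrease beyond 1e−9 — a bare
non-increase test would stop on float noise — or at `max_epochs`.

**Degenerate label sets.** E_i is undefined when Y_i is empty or equals
the full label universe (the complement is empty). Datasets with
full-universe instances are *valid*; training and the CV harness skip
those instances (logged/counted), while the metric functions and
`instance_error` reject them loudly so silent nonsense cannot propagate.

**Composition.** Pretraining is strictly unsupervised (its API takes no
labels) and the encoder is frozen once pretrained; BP-MLL trains on the
fixed codes. No supervised fine-tuning of encoder weights is performed —
the two-stage description is sequential, and freezing keeps the
"representation vs classifier" contributions separable in experiments.

## Metrics

Ranks are a deterministic permutation per instance: rank 1 for the highest
score, ties broken by ascending label index. Ranking loss counts a pair as
violated when f(relevant) ≤ f(irrelevant) — ties are errors, which the
index tie-break preserves; this matters for models that emit constant
scores (an untrained network outputs 0.5 everywhere). Coverage is bounded
by N−1 and average precision by (0,1]; a naive pair-enumeration oracle
(tests/oracles.py) pins all three to 1e−12 on randomized inputs.

## Synthetic data

The generator emulates the statistical structure of a literature-mined
gene×term matrix, which is what the method's assumptions touch: sparse
non-negative term frequencies in [0,1], high dimension, and per-pathway
"signature" term enrichment. Each gene draws a label-set cardinality
(default uniform on {1,2,3}, never N, so E_i is always defined), then its
labels; counts are Poisson with mean `signal_strength` (default 5.0) on
the signature terms of owned labels — 25 disjoint terms per label by
default — and `background_rate` (default 0.05) elsewhere; columns are
max-scaled into [0,1]. The defaults give ≈93% exact zeros at the study
size of 500 genes × 2000 terms with 8 labels.

What it does *not* emulate: real vocabulary statistics (Zipf tails,
burstiness), correlated signatures between biologically related pathways,
document-length effects, or label noise. Passing the recovery tests
therefore shows the pipeline extracts planted low-dimensional label
structure from sparse counts — not that it matches any published corpus
numbers, which depended on a non-distributable mined corpus (whose printed
coverage values even exceed the metric's N−1 bound, so they could not be
targets in any case).

## Experiment harness

10-fold cross-validation with seeded, plain-random (not stratified) folds
of size ⌊m/k⌋/⌈m/k⌉; each method fits on the training folds only and
scores the held-out fold. Per-fold metric means ± sd are reported (the
single-number grid aggregates by mean over folds), and pooled out-of-fold
scores are retained for dataset-level statistics. Chance reference: the
label-shuffle permutation null — whole label sets reassigned uniformly
across instances with scores fixed, ≥100 permutations — summarized by
mean, sd and quantiles. On strong-signal synthetic data both SdaMLL and
raw-feature BP-MLL must beat the null (average precision above the 97.5th
percentile, ranking loss below the 2.5th); the ordering *between* methods
on synthetic data is not asserted, as it is an empirical claim about real
corpora. With signal = background (set at rate 0.5 so the matrix has
variation but zero label information) the trained model collapses to a
near-constant label ranking, the null degenerates to a point mass, and
held-out average precision sits inside its central 95% interval.

## Problem sizes and numerical choices

The recovery and null experiments run at 500×2000 with a [2000, 200]
stack, 3 DAE epochs (learning rate 0.1, v = 0.25), and BP-MLL with M = 20,
α = 0.05, ≤15 epochs, patience 3 — small schedules chosen because the
planted signal saturates quickly (the error traces flatten within a few
epochs), keeping the full comparison in the low minutes on one CPU. The
published experiments state no layer sizes, corruption level, learning
rates or epoch budgets, so all such values here are package defaults, not
reproduced settings. All randomness descends from explicit integer seeds
(NumPy `SeedSequence` streams split per stage: simulation, corruption/
init/shuffle, folds, permutations); every CLI run and model file is
byte-reproducible given the same seeds.

## Known limitations

- Per-instance Python-loop SGD is the contract (online updates), so very
  large corpora train slowly; the heavy linear algebra is vectorized per
  step but steps are sequential by definition.
- The encoder is never fine-tuned supervisedly; on real data joint
  fine-tuning might improve codes, but it would blur the two-stage design.
- Binary-relevance KNN/DT baselines ignore label correlations by
  construction; they are comparison points, not recommended annotators.
- The synthetic generator's clean disjoint signatures make the task easier
  than mined text; absolute metric values on it are not comparable to any
  real-corpus figures.
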