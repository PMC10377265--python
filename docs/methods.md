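# Methods

## Problem and pipeline

`mammober` implements a complete study pipeline for two-class (benign vs
malignant) classification of mammogram-like grayscale images:

1. **data** — a synthetic generator stands in for clinical mammogram sets;
2. **augmentation** — the set is enlarged by exact flips and 90° rotations;
3. **feature extraction** — a frozen convolutional backbone maps each image
   to a flat feature vector (transfer-learning stage);
4. **classification** — a small CNN, whose structure and training
   hyperparameters live on an 11-parameter grid, is trained by SGD;
5. **hyperparameter search** — the Advanced Al-Biruni Earth Radius (ABER)
   metaheuristic minimizes `1 − cross-validated accuracy` over the unit
   hypercube, which a deterministic decoder maps onto the grid;
6. **evaluation and statistics** — six confusion-matrix metrics on a
   held-out split, plus descriptive/ANOVA/Wilcoxon comparison of replicated
   runs of competing models.

## The ABER optimizer

ABER is a population method in a bounded box, minimization convention.
Its step-size coefficient descends from Al-Biruni's trigonometric estimate
of the Earth's radius,

    r = h · cos(x) / (1 − cos(x)),

with `h ~ U(0, 2)` and a dip angle `x ~ U(10°, 180°)`; the lower cut keeps
`1 − cos(x)` away from zero. Each iteration the population is split into an
**exploration** group, whose members take diversification steps

    P ← clip(P + D ⊙ (2 r₂ − 1)),   D = c ⊙ (P − 1),   c = min(|r|, 1) · r₁,

and an **exploitation** group, whose members move by a differential
recombination toward the leader P* (the best-so-far solution),

    P ← clip(r₁ ⊙ P₁ + z·r₂ ⊙ (P₂ − P₃) + (1 − z)·r₃ ⊙ (P* − P₁)),

with three distinct peers P₁, P₂, P₃ sampled without replacement,
`r₁, r₂, r₃` elementwise U(0,1) vectors and `z ~ U(0,1)` a scalar.
The advanced variant adds:

* **dynamic group sizing** — the exploration share decays linearly from
  70% to 30% of the population over the run (round-half-even on the
  exploration count; the exploitation group absorbs the remainder), with
  membership reshuffled every iteration;
* **elitism** — the leader is replaced only by a strictly better solution,
  so the best-fitness history is monotone non-increasing;
* a **leader-neighbourhood probe** `P′ = r₁ ⊙ (P* + k)` with radius
  `k = 1 + 2 t²/T²` (growing 1 → 3); the exploiting member keeps the better
  of its recombination move and the probe;
* **stagnation-triggered mutation** — a member whose fitness has not
  strictly improved for `stagnation_limit` consecutive iterations (default
  2) is, with probability `mutation_probability` (default 0.5), restarted
  at `clip(k + (P₁+P₂+P₃) · e^{−z·k})`.

`classic_mode=True` disables all four additions, leaving the baseline BER
scheme with a fixed 70/30 split (a best-so-far solution is still tracked so
a result can be returned).

Design points that were genuinely open, and how they were resolved:

* The exploration pseudo-formulation computes the earth-radius coefficient
  `r` but never visibly consumes it, and the exploitation group computes a
  leader step `D = r₃ ⊙ (P* − P)` that the recombination line ignores. We
  bind `r` into the exploration coefficient (`c = min(|r|,1)·r₁`) so the
  coefficient actually shapes the step, and expose the leader-step form as
  the optional `leader_step_variant` (off by default). Both choices are
  config-switchable.
* The mutation restart's typography admits `·e^{zk}` or `/e^{zk}`; the
  division (decay) reading is used because it keeps the restart bounded.
* The published parameter table lists a coefficient "K decreasing from 2 to
  0", contradicting the pseudo-code's `k = 1 + 2t²/T²` (1 → 3); the
  pseudo-code formula is followed.
* Prose mentions a three-iteration stagnation window where the pseudo-code
  says two; `stagnation_limit` defaults to 2 and is configurable.
* Mutation requires both the stagnation trigger *and* the Bernoulli gate,
  reconciling the pseudo-code (trigger only) with the listed mutation
  probability of 0.5. The check is applied to every member after its move,
  since membership reshuffles each iteration anyway.
* Leader ties: strict improvement required, keeping trajectories
  deterministic under a fixed seed. The whole trajectory is a pure function
  of (seed, config, objective).

Defaults follow the published protocol: population 30, 500 iterations,
30 independent restarts (`n_runs`), exploration fraction 0.70 → 0.30,
mutation probability 0.5.

## Search space and decoding

Eleven ordered parameters: three conv blocks' filter counts
({16,32,64,96}, {48,64,96,128}, {64,96,128}) and kernel sizes ({3,4,5}
each), dense width {60,100,125}, activation {relu, lrelu, elu}, learning
rate {0.001, 0.003, 0.01, 0.03}, batch size {16,32,64,128}, dropout
{0.2 … 0.6}. The structural sub-grid alone has 11 664 points. The printed
source table for the training parameters is corrupted (batch-size row
repeats the learning-rate values); batch sizes use the conventional powers
of two — a documented repair.

A position u ∈ [0,1]¹¹ decodes coordinate-wise: an m-way categorical takes
index `min(⌊u·m⌋, m−1)` (uniform bins, so uniform sampling hits each choice
with probability 1/m); a continuous parameter maps affinely onto its
bounds. Decoding is total, deterministic, and invariant under the
optimizer's bound clipping.

## The CNN classifier

Three conv blocks (conv "same" padding → activation → 2×2 max-pool,
floor semantics), flatten, one dense hidden layer, inverted dropout, and a
2-unit softmax head trained by plain SGD on cross-entropy at the decoded
learning rate and batch size. The network is implemented directly on numpy
arrays (im2col convolutions, explicit backprop through pooling argmax with
tie-splitting), in float32. At the input sizes used — extracted feature
vectors zero-padded and reshaped to small square maps (minimum 8×8 so the
three poolings stay valid) — a full training run takes a fraction of a
second on one CPU core. Leaky-ReLU slope is 0.01 and ELU α = 1.0
(unstated in the source; common defaults). He-style initialization from a
seeded generator makes two builds from the same configuration and seed
bit-identical.

## Fitness and evaluation protocol

The data protocol is a stratified 70:30 outer split; augmentation touches
only the 70% training side; the search objective is
`1 − mean k-fold cross-validated accuracy` (stratified folds, library
default 5), computed inside the training split with per-fold feature
standardization; the winning configuration is retrained on the full
training split and scored exactly once on the untouched 30%. This is the
only leakage-free composition of the stated 70:30 split with k-fold CV.
Identical decoded configurations hit a fitness cache — important because a
converging population re-proposes the same grid point many times. A failed
build/train yields +inf fitness with a recorded warning, keeping the
objective total.

Metrics use malignant as the positive class (clinical convention). A
metric with a zero denominator is returned as NaN — an explicit undefined
marker — never silently 0 or 1, so degenerate folds cannot hide in
aggregate tables. The F-score is computed in counts,
`TP / (TP + 0.5(FP + FN))`, and equals the harmonic mean of precision and
sensitivity whenever both are defined.

## Statistics suite

* **Descriptives**: sample SD (n−1), SEM = sd/√n, percentiles by linear
  interpolation between order statistics (heavily tied replicate sets can
  legitimately print 25% = median).
* **One-way ANOVA** from raw values, or reconstructed from per-group means
  and SDs with equal n via `SS_treat = n Σ(meanᵢ − grand)²` and
  `SS_resid = (n−1) Σ sdᵢ²`; the two routes agree to 1e−12 when the
  summaries are computed at full precision from the same raw data. p-values
  below 1e−4 are formatted as "< 0.0001" in report output.
* **Wilcoxon signed-rank**, one-sample: zero differences dropped, mid-ranks
  for ties. For n ≤ 25 the p-value is exact — the null distribution of W⁺
  over all 2ⁿ sign assignments is computed in full via the generating
  polynomial over doubled ranks (identical to literal enumeration, feasible
  at n = 25); two-sided p = 2·P(W ≤ min(W⁺, W⁻)), capped at 1. Ten
  same-signed replicates give W⁺ = 55, p = 2/1024 ≈ 0.002. Above n = 25 a
  normal approximation with continuity and tie corrections is used. The
  two-sided value is the default report (the one-sided value is also
  returned, since the source text is ambiguous on sidedness and its printed
  0.002 is the two-sided exact value).

## Synthetic data: what it emulates and what it does not

The generator emulates the radiological cues that distinguish lesion
classes: a Gaussian-smoothed noise background (parenchyma texture), one
radially symmetric Gaussian mass per image, and — malignant only — radial
spicule segments and a Poisson number of punctate bright dots
(microcalcifications). All malignant-only amplitudes scale with
`effect_size`; at 0 the class-conditional distributions coincide exactly
(the shared random draws are kept stream-aligned across classes), so
classifier accuracy has expectation 1/2 — a built-in null for calibration.
Images are [0,1] grayscale in memory, 8-bit PNG on disk (round-trip error
≤ 1/255).

It does **not** emulate breast anatomy, pectoral muscle, density
categories, scanner artifacts, label noise, or class imbalance. Passing
tests therefore demonstrate that the machinery — augmentation counts,
leakage-free protocol, optimizer behaviour, statistics — is correct, and
that the search can exploit genuine class signal; they say nothing about
accuracy attainable on clinical data.

## Feature extraction

The default backbone is a frozen random-weights CNN (conv 3×3 "same" →
ReLU → 2×2 max-pool per stage, Gaussian kernels scaled by 1/√fan-in drawn
once from `weights_seed`, global average pooling for vector output, default
stages 16-64-128 → 128 features). Random frozen convolutions preserve local
texture/edge statistics, which is what separates smooth from spiculated
masses here. A pretrained encoder (e.g. an AlexNet embedding) can be
plugged in through the `external_adapter` kind, whose only contract is an
(n, p) matrix with one row per image; nothing downstream depends on which
backbone produced the features.

## Problem sizes and numerical choices

Library defaults mirror the published protocol (population 30 × 500
iterations × 30 restarts, 5-fold CV, 70:30). The `desk_scale` preset the
examples, tests and acceptance script use is the package's reduced study
condition: 24 images per class at 32×32, backbone channels (8, 16, 64)
giving 64 features reshaped to 8×8 maps, 3 training epochs, 2-fold CV,
population 10 × 20 iterations × 3 restarts. A multi-restart at this budget
evaluates ~700 unique configurations and completes in a few minutes on one
CPU core. Other fixed choices: rotation direction counter-clockwise;
pooling floor-drops odd trailing rows/columns; dropout is inverted (scaled
at train time); fold assignment is stratified and seed-deterministic;
random-search comparisons receive exactly the number of objective calls
the ABER run consumed.

## Known limitations

* The numpy CNN is CPU-bound and meant for small inputs; it has no
  momentum, weight decay or scheduling (plain SGD, as specified).
* The synthetic task at full effect size is easy; near-ceiling accuracies
  compress differences between search strategies, so optimizer comparisons
  on it test direction, not magnitude.
* The exact Wilcoxon implementation switches to the normal approximation
  above n = 25; p-values there are approximate by construction.
* `prose8` augmentation includes a 0°-rotation copy that is pixel-identical
  to its source (that is how an ×9 enlargement arises from "eight
  additional shots"); deduplication is deliberately not performed.
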