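# Methods

`metagcn` implements few-shot, imbalance-robust disease classification over
functional-connectivity cohorts: subjects are nodes, their flattened
connectivity matrices are node features, demographic similarity defines the
edges, and a two-layer graph convolutional network (GCN) is meta-trained with
MAML so that a handful of gradient steps on a small labelled support set
suffices to classify new subjects. This note records the model, the
assumptions, the numerical choices, and what the synthetic benchmark does and
does not establish.

## Data model

A subject i contributes a feature vector x_i ∈ R^d, the strict upper triangle
of an n×n region-by-region correlation matrix (d = n(n−1)/2; n = 90 gives
d = 4005), together with three non-image features: age (years), sex (0/1) and
APOE4 allele count (0–2), and a class label y_i ∈ {1..C} (e.g. AD / MCI / NC).
Correlation entries are consumed independently and clipped to [−1, 1];
positive-definiteness of the full matrix is never used and therefore not
enforced by the synthetic generator.

### Synthetic cohort generator

The generator reproduces exactly the statistical structure the classifier
relies on, and nothing more:

* **Connectivity.** Per-edge population means μ_j ~ N(0.1, 0.15) are drawn
  once per cohort; a subject of class c has
  x_ij = clip(μ_j + c·effect_size·1[j ∈ S] + ε, −1, 1), ε ~ N(0, noise_sd),
  where S is a random set of `n_signal_edges` class-discriminative entries.
* **Demographics.** With association strength a = `demo_assoc` ∈ [0, 1] and
  severity sev_c = 1 − c/(C−1) (class 0 severest):
  age ~ N(66 + 16·a·sev, 5), sex ~ Bern(0.4 + 0.2·a·sev),
  apoe4 ~ Bin(2, 0.05 + 0.65·a·sev). At a = 1 the demographic profiles of the
  extreme classes are clearly separated (a cohort in which phenotype edges are
  genuinely informative); at a = 0 demographics carry no class information.
* **Defaults** (the benchmark's study conditions, chosen once): 90 regions,
  class counts 30/92/243 (the severe imbalance typical of this disease
  staging), 300 signal edges, effect_size 0.2, noise_sd 0.1, demo_assoc 0.8.
  An effect of 0.2 correlation units per class step on 300 of 4005 edges is a
  strong but not saturating planted signal: two noise SDs per class step on
  7.5% of the features.

The generator does **not** simulate BOLD time series, preprocessing artefacts,
site effects, or realistic network topology (small-worldness, modularity).
Consequently a pass on synthetic data shows that the pipeline recovers
entrywise mean-shift structure under label imbalance — not that it reaches any
particular accuracy on clinical data.

## Feature processing (SE-AE)

The squeeze-and-excitation block computes a single global importance vector:
z = mean over training subjects of x (squeeze), s = σ(W₂ δ(W₁ z)) with
δ = ReLU, σ = sigmoid, W₁ ∈ R^{(d/r)×d}, W₂ ∈ R^{d×(d/r)} (excitation), and
x̃_i = s ⊙ x_i (rescale). One s is shared by all subjects; since s ∈ (0,1)^d,
rescaling never amplifies a feature. A two-layer encoder (d → h → d̂) and
decoder (d̂ → h → d) then compress the rescaled features.

Two points are underdetermined in the method as published and were fixed here:

* **SE training signal.** The excitation weights are trained jointly with the
  autoencoder under the unsupervised reconstruction loss (mean squared error
  of the decoder output against the **raw** features). The alternative target
  (the rescaled features) is available as `recon_target="rescaled"`; with it
  the loss admits the degenerate solution s → 0, which is why raw is the
  default.
* **Leakage hygiene.** z is computed from the training fold only and frozen;
  validation and test subjects are encoded with the stored s. Likewise the
  phenotype ranges used by the adjacency are training-fold statistics.

Defaults: r = 16, h = 128, d̂ = 64, 120 epochs of full-batch Adam at 1e-3,
snapshot selection by validation MSE (a 10% split of the training fold).
These widths and epoch counts are the smallest round numbers at which the
selected snapshot reliably reaches well under half the untrained validation
error on the default cohort; all are configurable. Training is full-batch
because cohorts of a few hundred subjects fit easily in memory and full-batch
gradients make runs bit-reproducible.

## Task graphs

Meta-training tasks draw exactly k^s per class into the support set and k^q
per class into the query set (defaults 3 and 5, the best-performing published
configuration), with resampling across tasks; M = 200 tasks form the pool.
Meta-testing tasks draw a balanced support (k^s_test = 3 per class) from the
training split while their query sets partition the held-out subjects into
⌈|test|/t⌉ chunks (t = 10), so each test subject is predicted exactly once
and t = 1 recovers fully independent single-subject testing.

Edges come only from the non-image features. Feature u of subjects i, j is
similar when 1 − |s_i^u − s_j^u| / range_u ≥ β₁ (range_u = training max−min;
a constant feature makes every pair similar by convention), and an edge is
drawn when the mean of the three indicators is ≥ β₂. The printed form of the
aggregation rule in the source method is corrupted; the mean-of-indicators
reading is used, with `rule="sum_ge"` as the equivalent count form.

**Thresholds.** Defaults are β₁ = 0.9, β₂ = 1.0: an edge requires similarity
on *all three* features, i.e. age within 10% of the cohort age range, same
sex, same APOE4 dose. This was a genuinely open choice and the single most
consequential one. Measured on the default cohort, a looser graph
(β₂ = 2/3, ≈ 40% density) has fewer than half of its edges within-class, and
two rounds of symmetric-normalized neighbourhood averaging then wash out even
perfectly separable node features (training-task accuracy plateaus near 0.7
while an edgeless graph reaches 1.0). The sparse high-precision graph is the
regime the population-graph assumption — similar phenotype, likely similar
condition — actually supports. The denser β₂ = 2/3 setting remains the right
choice when node features are uninformative and all signal is relational, and
is what the demographics-only ablation experiment uses.

## Meta-learned GCN

Backbone: X^(l+1) = δ(D̃^{−1/2}(A+I)D̃^{−1/2} X^(l) θ^(l)), two layers
(d̂ → 16 hidden, ReLU → C logits), inverted dropout (rate 0.5) on layer
inputs during training only. The loss is cross-entropy averaged over a node
mask; support and query nodes share one graph but the inner loss masks to
support and the outer loss to query, so query labels never influence
adaptation (and at meta-test the query labels are simply absent).

MAML: the inner update θ′ = θ − α₁∇_θ L_support(θ) (α₁ = 0.01, one step by
default) is a pure function; the outer objective is the summed query loss at
θ′ over a batch of 4 tasks. Second-order meta-gradients are the default: the
query gradient is propagated backwards through each inner step as
v ← v − α₁ H_support(θ_j) v. Hessian-vector products are computed by
complex-step differentiation of the hand-derived gradient function,
Im ∇L(θ + iεv)/ε with ε = 1e−60 — exact to machine precision, with no
finite-difference cancellation; ReLU and dropout gates and the softmax shift
read only the real part, so the product corresponds to the almost-everywhere
Hessian of the piecewise-analytic loss. `second_order=False` gives the
cheaper first-order approximation.

The printed outer rule is plain gradient descent at α₂ = 0.003, and
`meta_update` implements exactly that step; in practice that rule stalls on
this landscape (the reference MAML implementation the source method builds on
also uses Adam for the outer loop), so `meta_train` defaults to Adam at rate
α₂ over 500 iterations, with `meta_optimizer="sgd"` available. At meta-test,
a copy of θ is fine-tuned on the balanced support for 5 steps with dropout
off — evaluation is a deterministic function of θ and the task — and query
nodes take argmax softmax labels. One fine-tuning step (the spec of the inner
loop) measurably underfits the 9-subject support; 5 steps is the package
default and is configurable.

Numerical choices: float64 throughout; log-sum-exp-stable softmax; Glorot
initialisation from the run seed; all randomness flows through explicit
`numpy.random.Generator` objects, so every result in this package is
bit-reproducible from its config and seed. Exact score ties at prediction
time (which occur when a degenerate network emits identical logits for every
class, e.g. a fully dead ReLU layer on no-signal data) are broken at random,
seeded per subject — a plain argmax would silently collapse every tie onto
class index 0 and bias chance-level runs toward the first class.

## Evaluation

Stratified 5-fold cross-validation; per fold the SE-AE block, phenotype
ranges and the meta-learned θ are fitted on the training split only. Repeats
rerun everything at seed, seed+1, …. Metrics: accuracy; sensitivity,
specificity and F1 (positive = the severer class for binary tasks, macro
one-vs-rest for C > 2); macro OVR AUC on softmax scores. Macro averaging is
the conservative choice for imbalanced multi-class reporting and is stated in
the report. Ablations remove one component at a time: -SE (no excitation
weighting), -AE (raw d-width features into the GCN), -Meta (one plain GCN on
the training graph, no episodic loop), -NI (no phenotype edges; adjacency
normalises to the identity), -SE-AE.

## Problem sizes

The shipped experiments use cohorts of 200–365 subjects at the full d = 4005
feature width, 200-task pools, 500 meta-iterations and 120 autoencoder
epochs — sizes at which a complete 5-fold cross-validation takes about a
minute on one CPU core and the full acceptance run a few minutes, while every
qualitative property (imbalance robustness, signal recovery, ablation
directions, chance-level nulls) is already stable.

## Known limitations

* The synthetic benchmark's signal model is entrywise and Gaussian; nothing
  here certifies performance under realistic scanner noise, site effects, or
  correlated connectivity structure.
* The SE importance vector is global: one s for the whole cohort, not
  per-subject attention.
* The phenotype graph uses three features and hard thresholds; no learned or
  weighted adjacency.
* Binary classification support (C = 2) is implemented and tested at the
  metric level, but the shipped experiments are three-class.
* With no signal at all the meta-learner's predictions can collapse, per
  fold, onto one class (memorisation of noise plus a degenerate network);
  accuracy then fluctuates around chance with fold-level clustering, which is
  why chance-level checks here use cluster-robust Monte-Carlo standard
  errors rather than binomial ones.
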