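# Methods

`stratgraph` models dynamic risk stratification and intervention planning
for longitudinal multimodal patient cohorts. This note records the model,
the synthetic data-generating process, the numerical choices, and the
limitations a user should know before trusting results on real data.

## Model

### Patient-similarity graph

Patients are nodes; edges connect clinically similar patients. Similarity
has two ingredients:

- a **composite domain similarity** `phi(i, j) = sum_d omega_d *
  cos(x_i^(d), x_j^(d))` over feature domains (by default, the per-modality
  observed time-mean profiles), with nonnegative weights summing to 1;
- a **Gaussian kernel of embedding distance**
  `w_ij = exp(-||h_i - h_j||^2 / (2 sigma^2)) * 1[phi(i, j) > tau]`.

Two sparsification mechanisms act together: the similarity indicator
`1[phi > tau]` and a weight floor `eps_w` (default 0.01) below which kernel
weights are dropped. The floor is what lets the bandwidth `sigma` influence
graph density — with the indicator alone, density would depend on `tau`
only, which contradicts the observed joint sensitivity of density to both
parameters. This dual-threshold reading is flagged to users as a modelling
choice.

Graph construction is brute force over all N(N-1)/2 pairs and
non-differentiable. During training the adjacency is treated as a constant
and rebuilt from current embeddings at a configurable cadence (default:
once per epoch, `graph_update_every=0` for a static graph). Embeddings are
L2-normalized before the kernel so that edge formation is scale-free across
training; the kernel then depends on angular separation rather than the
drifting magnitude of hidden states. Self-loops are *not* stored in the
graph; they are added inside the convolution operator (A + I with symmetric
degree normalization), avoiding double counting. Isolated nodes are allowed
and fall back to self-loop-only aggregation; the normalized-Laplacian
utility uses the `D^{-1/2} = 0` convention for them, keeping the spectrum
in [0, 2].

### Encoder

A fixed three-level stack (graph -> temporal -> cross-modal):

1. **Modality encoders + fusion.** Each modality stream passes through a
   two-layer perceptron (ReLU hidden activation) to a shared hidden
   dimension d. Unobserved steps receive a learned per-modality missing
   embedding. Streams fuse through softmax-parameterized weights `alpha_m`.
2. **Gated graph convolution** (3 layers): at every time step,
   `z_i = sigmoid(P H W + b) * tanh(P H U)` with
   `P = D~^{-1/2}(A + I)D~^{-1/2}`. The sigmoid gate modulates a tanh
   content stream, so outputs are strictly inside (-1, 1); the self-loop
   convention guarantees isolated patients still produce output.
3. **Temporal attention** with an additive relative-position bias: scores
   `(W_q h_t)^T(W_k h_t')/sqrt(d) + phi(t - t')` where `phi` is a learnable
   scalar per signed lag, clipped at |T-1| (a relative-position-bias table,
   the minimal expressive encoding of signed temporal distance).
   Unobserved steps are masked out of the softmax as keys — masked
   positions receive exactly zero attention.
4. **Cross-modal attention** per time step: modality m queries modality n
   (multi-head, shared projection matrices across pairs to keep the
   parameter count proportionate to desk-scale data), averaged over
   n != m, with a residual connection preserving the m-stream. Each
   modality's key positions are masked by its own observation mask.
5. **Hierarchical skip merge**: `H_global = Pool(H_local) +
   Transform(H^(L))`, with Pool the temporal mean of the final stream and
   Transform a learned affine map of the pooled final graph-level states.

Activation choices (ReLU for perceptrons and plain graph convolution) and
the exact level composition were open design decisions; the stack order is
fixed rather than searched. No separate recurrent temporal cell exists —
the temporal pathway is attention only.

### Risk head and uncertainty

Two hidden layers of width d with batch normalization and dropout, then a
K-way softmax (K = 4 strata: High, Moderate-High, Moderate-Low, Low).
Monte Carlo dropout uncertainty runs 50 stochastic forward passes (default)
with dropout active and batch-normalization statistics frozen in evaluation
mode — only dropout is stochastic. Reported summaries: pass-averaged
probabilities, predictive entropy in nats (bounded by ln K; natural log
chosen for unitless comparison), and the coefficient of variation of the
predicted-class probability across passes (one of several possible CoV
definitions; chosen because the predicted class is the clinically acted-on
quantity).

### Intervention decoder

Plans are sequences over a configurable action vocabulary (a packaged
synthetic default of 12 actions plus a reserved end-of-plan token) with
autoregressive factorization `p(I|h, y) = prod_t p(i_t | i_<t, h, y)`. The
cell is a single-layer gated recurrent unit over learned token embeddings
concatenated with the patient embedding and risk distribution. Hard
feasibility comes from a binary symmetric compatibility matrix C applied by
masked renormalization at every step; the constraint is prefix-global (a
token must be compatible with *every* token already emitted, not just the
previous one). The end token is compatible with everything, so decoding
always terminates; after `max_len` actions (default 8) the feasible set
collapses to the end token, which makes the probabilities of all feasible
bounded-length plans sum to exactly one — verified by exhaustive
enumeration on small vocabularies. Emitted plans satisfy C with rate 1.0
by construction. Training uses teacher forcing on the *unconstrained*
softmax (constraints shape inference, not the likelihood), which keeps the
loss a proper NLL of the targets.

## Training

Composite loss `L = lambda1 * CE + lambda2 * NLL + lambda3 * ||theta||^2`
with defaults (1.0, 0.5, 1e-5); the task weights were fixed a priori, not
tuned. Optimizer: adaptive-moment gradient descent with decoupled weight
decay. Training is transductive: graph convolution runs over the full
cohort graph, the loss is evaluated on training patients only, and
validation never updates parameters (asserted by test). Early stopping
watches validation total loss with the configured patience.

Full-scale defaults (hidden 256, 8 heads, 3 graph layers, T = 12, dropout
0.3, lr 1e-4, batch 32, 200 epochs, patience 20, weight decay 1e-5) are
the package's reference configuration. Desk-scale experiments in the test
suite and acceptance script use hidden 32, 4 heads, lr 1e-2 and 30 epochs
with full-cohort gradient steps: the graph couples all patients inside one
adjacency, so stepping on the full cohort is the natural unit, and the few
well-conditioned full-batch steps support a larger step size than the
minibatch default. These problem sizes are the package's own choices for
its planted-signal experiments.

All computation runs on a small reverse-mode automatic-differentiation
engine over numpy arrays written for this package (dense float64, dynamic
tape). Gradient correctness is verified against central finite differences
(relative error < 1e-4 on a composite model, far tighter per op).

## Synthetic cohort generator

The generator is first-class, tested code; it defines the study conditions
for every experiment.

- **Modalities**: vitals (12-d, z-scored), labs (48-d, min-max scaled),
  imaging (512-d) and clinical text (768-d) generated directly in embedding
  space — raw image/text synthesis and their encoders are out of scope.
- **Risk strata**: N patients apportioned to the class mixture
  (18.3 / 24.1 / 31.2 / 26.4 % by default) by largest-remainder rounding,
  then randomly permuted. Stratified assignment reproduces the configured
  mixture up to integer rounding at any N.
- **Planted structure**: features are `cluster_signal * (centroid_c +
  shift_y) + AR(1) noise` with Gaussian cluster centroids, label-linked
  mean shifts, and stationary AR(1) temporal drift (coefficient 0.8, unit
  marginal variance). Patients sharing a cluster or stratum are therefore
  more similar in composite-cosine terms than cross-cluster pairs, with a
  margin that grows with `cluster_signal`; at signal 0 the margin is
  statistically indistinguishable from 0. A 5-nearest-neighbour majority
  vote on composite similarity recovers labels above chance at signal >= 2
  — this is the signal the graph pathway exploits and the ablation
  experiment measures. The AR(1) drift gives temporal attention structure
  to aggregate.
- **Missingness**: i.i.d. Bernoulli masks at a marginal rate (default
  12.4%), with at least one observed step per patient and modality; masked
  entries carry NaN sentinels, distinguishable from observed zeros.
  Missingness is completely at random — real clinical missingness is
  informative, and only marginal rates are modelled here.
- **Disease categories** follow a Zipf-like long-tail law (exponent 1.2,
  up to 156 categories), used as the grouping key for stratified median
  imputation.
- **Intervention targets** are drawn from risk-stratum-conditional token
  distributions under the compatibility matrix, with stochastic plan
  termination (continuation probability 0.65 per step, up to 8 actions) —
  this makes decoder training learnable and sequence-similarity scores
  meaningful.

What passing tests on this generator do **not** show: performance on real
cohorts. The generator has no disease-specific physiology, no informative
missingness, no inter-modality redundancy structure beyond the shared
cluster/label geometry, and cluster structure far cleaner than clinical
reality. Directional results (e.g., removing the graph pathway hurts) are
evidence about the architecture's mechanics, not about clinical accuracy.

## Preprocessing

- **LOCF** for temporally continuous series; leading gaps are back-filled
  from the first observation (preserves per-patient physiology; the
  alternative of group-median filling the head of the series was rejected
  as mixing patients into an individual trajectory). All-missing series are
  an error.
- **Disease-stratified median imputation** for labs, with a global-median
  fallback for categories with no observed value.
- **Masked-token imputation** for embedding-space modalities: a reserved
  constant vector at the data layer, replaced by the learned missing
  embedding inside the encoder.
- **Standardization** (zero mean, unit variance, population std) and
  **min-max scaling** are fit on the training partition only and applied
  unchanged elsewhere; constant features get scale 1 with a warning flag;
  out-of-range values under min-max clip to [0, 1]; a degenerate range maps
  to 0.5.
- **Outlier flagging** is contract-based: any scorer mapping a vector to
  [0, 1] plugs in; the default is a robust z-score `|x - median| /
  (1.4826 * MAD)` squashed through a logistic centred at z = 3 (scale 0.3),
  flag threshold 0.9. When the MAD collapses to zero on non-constant data
  (majority ties), the consistency-scaled mean absolute deviation
  (1.2533 * meanAD) substitutes; all-identical input yields no flags and a
  warning. Flags are *reported, never silently replaced* — automated
  replacement would fabricate the clinical-plausibility review such flags
  are meant to trigger.

## Evaluation protocol

- **Splits**: stratified 70/15/15 with largest-remainder integer
  apportionment per stratum (reproduces 1993/427/427 from a 2,847-patient
  cohort exactly), seeded tie-breaks.
- **Metrics**: accuracy, macro precision/recall/F1, Cohen's kappa, and
  macro one-vs-rest AUC (the natural multiclass extension when per-class
  discrimination matters; classes absent from the truth are excluded with
  a warning).
- **Uncertainty of metrics**: percentile bootstrap over resampled patient
  indices (1000 iterations, 95% by default); paired comparisons resample
  identical indices for both models.
- **Paired tests**: two-sided Wilcoxon signed-rank, exact for n <= 25
  pairs, normal approximation beyond; all-zero differences return p = 1
  with a warning. Bonferroni correction is reported both exact and rounded
  to 4 decimals. The signed-rank test operates over folds; a
  replicate-level mode is available through the same function.
- **BLEU** for plan similarity: modified n-gram precisions (max n = 4) with
  brevity penalty; zero higher-order precisions are smoothed add-eps
  (1e-9); zero 1-gram overlap scores 0. BLEU measures surface n-gram
  overlap only — it says nothing about clinical appropriateness, and the
  package documents it as such.
- **Ablations** share one seed, split and preprocessing pipeline across
  configurations; reported as macro-F1 deltas against the full model.

## Numerical choices and degenerate inputs

- float64 throughout; attention softmax subtracts the row max (as a
  constant) for stability; masked positions receive -1e30 before the
  softmax and are exactly zeroed by construction of the mask.
- Zero vectors have cosine similarity 0 by convention.
- Largest-remainder ties break by stable descending-remainder order after
  a seeded within-stratum permutation.
- The autodiff tape is single-use: backward releases intermediate nodes to
  bound memory; un-backpropagated graphs expose an explicit `release()`.
- Seeds: one master seed; per-stage child seeds derive via
  `SeedSequence(entropy=seed, spawn_key=(crc32(stage),))`, all below 2^31.

## Known limitations

- Validation on synthetic cohorts only; no claim of clinical performance.
- The graph is rebuilt by brute force (O(N^2)); no approximate
  nearest-neighbour acceleration, so cohorts beyond a few thousand patients
  become slow.
- Domain weights `omega_d` are configuration, selectable by validation
  search; no gradient path exists through the thresholded graph.
- Beam search is not implemented (greedy and seeded ancestral sampling
  only).
- The "knowledge-guided" element of decoding is exactly the compatibility
  mask; no richer clinical-knowledge ingestion exists.
- MICE-style multiple imputation and informative-missingness mechanisms
  are out of scope.
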