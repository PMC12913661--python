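# stratgraph

Dynamic risk stratification and constrained intervention planning for
longitudinal multimodal patient cohorts, built around a spatiotemporal
graph-attention encoder. The package targets the rehabilitation-nursing
setting — heterogeneous patients, weekly multimodal observations, frequent
missingness, four ordinal risk strata — where per-condition sample sizes
are too small for standalone learning and statistical strength must be
borrowed across clinically similar patients.

Because raw clinical cohorts of this kind are private, the package ships a
first-class synthetic cohort generator with *planted*, graph-recoverable
structure, so every stage — preprocessing, graph construction, encoding,
classification, uncertainty, constrained decoding, evaluation — is testable
end to end.

## The model

**Patient-similarity graph.** For patients i, j with feature-domain
profiles x^(d), composite similarity and edge weights are

    phi(i,j)  = sum_d omega_d * cos(x_i^(d), x_j^(d))
    w_ij      = exp(-||h_i - h_j||^2 / (2 sigma^2)) * 1[phi(i,j) > tau]

with kernel bandwidth sigma (default 2.0), sparsification threshold tau
(default 0.3), and a weight floor (default 0.01) below which edges are
dropped. The adjacency is rebuilt from current embeddings during training
(dynamic graph updates, no gradient flow through construction).

**Encoder** (three levels with skip merging):

1. per-modality two-layer perceptrons to a shared hidden space, learned
   missing-step embeddings, softmax fusion weights alpha_m;
2. three gated graph-convolution layers,
   `z_i = sigmoid(P H W + b) ⊙ tanh(P H U)` with
   `P = D~^{-1/2}(A+I)D~^{-1/2}`;
3. temporal self-attention with a learnable relative-position bias
   phi(t−t′), masked to observed steps;
4. multi-head cross-modal attention (modality m queries modality n) with
   residual connections;
5. hierarchical merge `H_global = Pool(H_local) + Transform(H^(L))`.

**Risk head.** Two hidden layers with batch normalization and dropout,
softmax over K=4 strata; Monte Carlo dropout (50 passes) yields predictive
entropy and the coefficient of variation of the predicted-class
probability.

**Intervention decoder.** Autoregressive plans
`p(I|h,y) = prod_t p(i_t | i_<t, h, y)` over a clinical action vocabulary,
with hard feasibility from a binary compatibility matrix C applied by
masked renormalization at every step — emitted plans satisfy C with rate
1.0 by construction, and the probabilities of all feasible bounded-length
plans sum to exactly one.

Training jointly optimizes
`L = lambda1·CE + lambda2·NLL + lambda3·||theta||^2` with early stopping.
All neural components run on a small reverse-mode autodiff engine over
numpy included in the package (`stratgraph.autodiff`), verified against
finite differences.

See `docs/methods.md` for assumptions, defaults, numerical choices and
limitations.

## Worked example

```python
import numpy as np
from stratgraph import CohortSpec, CompatibilityMatrix, EncoderConfig
from stratgraph.cohort import generate_cohort
from stratgraph.preprocessing import preprocess_cohort
from stratgraph.evaluation import split_cohort, classification_metrics
from stratgraph.training import StratModel, TrainConfig, LossWeights, train, predict
from stratgraph.risk import mc_dropout_predict
from stratgraph.decoder import decode

spec = CohortSpec(n_patients=150, n_steps=12, cluster_signal=2.0, seed=42)
compat = CompatibilityMatrix.random_feasible(np.random.default_rng(0))
cohort = generate_cohort(spec, compat)

assignment = split_cohort(150, strata=cohort.labels, seed=42)
train_idx, val_idx, test_idx = (np.flatnonzero(assignment == p) for p in range(3))
features, _ = preprocess_cohort(cohort, train_idx)

model = StratModel({n: x.shape[2] for n, x in cohort.features.items()},
                   n_classes=4,
                   config=EncoderConfig(hidden_dim=32, attention_heads=4),
                   vocab_compat=compat, seed=42)
fit = train(model, cohort, features, train_idx, val_idx,
            TrainConfig(learning_rate=1e-2, max_epochs=30, patience=30,
                        dropout=0.1, seed=42),
            weights=LossWeights(1.0, 0.2, 1e-5))
print(f"graph density: {fit['graph'].density:.3f}")

probs, pred = predict(model, features, cohort.masks, fit["graph"])
report = classification_metrics(cohort.labels[test_idx], pred[test_idx],
                                probs[test_idx])
print(f"test accuracy: {report.accuracy:.3f}  macro-F1: {report.macro_f1:.3f}  "
      f"kappa: {report.kappa:.3f}")

enc = model.embed(features, cohort.masks, fit["graph"])
unc = mc_dropout_predict(enc.h_global.data[test_idx[0]], model.head,
                         n_passes=50, seed=42)
print(f"patient {test_idx[0]}: mean probs {np.round(unc.mean_probs, 3)}, "
      f"entropy {unc.predictive_entropy:.3f} nats, "
      f"CoV {unc.coefficient_of_variation:.3f}")

plan = decode(model.decoder, enc.h_global.data[test_idx[0]],
              probs[test_idx[0]], compat, mode="sample", seed=7)
print("plan:", [compat.vocab.tokens[t] for t in plan.tokens])
```

Output:

```
graph density: 0.337
test accuracy: 1.000  macro-F1: 1.000  kappa: 1.000
patient 1: mean probs [0.005 0.001 0.991 0.002], entropy 0.059 nats, CoV 0.018
plan: ['monitoring_frequency_decrease', 'end_of_plan']
```

The cohort has strongly separated planted clusters (`cluster_signal=2.0`),
so the trained model classifies the held-out patients perfectly; the
MC-dropout summary shows a confident Moderate-Low prediction (probability
0.991, entropy far below the ln 4 ≈ 1.386 maximum), and the sampled plan
terminates with the reserved end token while respecting the compatibility
matrix.

## Command line

The same pipeline is scriptable:

```bash
stratgraph --config run.yaml simulate
stratgraph --config run.yaml preprocess
stratgraph --config run.yaml graph
stratgraph --config run.yaml train
stratgraph --config run.yaml predict
stratgraph --config run.yaml decode
stratgraph --config run.yaml evaluate
stratgraph --config run.yaml ablate
```

Each command writes its artifacts (cohort CSVs + JSON sidecar, TSV edge
list, checkpoint, predictions CSV, plans JSON-lines, metrics JSON) and a
manifest with the config hash and seed into `output_dir`. An empty config
file yields the full-scale defaults (hidden 256, 8 heads, lr 1e-4, batch
32, dropout 0.3); dotted overrides like `--set train.batch_size=16` adjust
individual fields.

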