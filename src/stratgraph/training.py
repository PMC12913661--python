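"""Joint training of risk classification and intervention generation.

The composite objective

    L = lambda1 * L_CE + lambda2 * L_NLL + lambda3 * L_reg

balances risk cross-entropy, plan negative log-likelihood (teacher forcing)
and a squared-norm regularizer.  Training is transductive: graph
convolution runs over the whole cohort's similarity graph, the loss is
evaluated on training patients only, and the adjacency is rebuilt from
current embeddings at a configurable cadence (default once per epoch)
without gradient flow.  Early stopping watches the validation total loss.

Desk-scale cohorts take full-cohort gradient steps (the graph couples all
patients within one adjacency), so the effective step size is configured
per run rather than tied to the minibatch default.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .actions import CompatibilityMatrix
from .autodiff import Tensor, softmax
from .cohort import SyntheticCohort, domain_feature_matrix
from .decoder import InterventionDecoder, batch_teacher_forcing_nll
from .encoder import Encoder, EncoderConfig
from .graph import GraphParams, SimilarityConfig, update_graph
from .nn import AdamW, Module
from .risk import RiskHead


@dataclass(frozen=True)
class LossWeights:
    lambda1: float = 1.0  # risk cross-entropy
    lambda2: float = 0.5  # plan negative log-likelihood
    lambda3: float = 1e-5  # squared-norm regularizer

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0 or self.lambda3 < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.lambda1 == self.lambda2 == self.lambda3 == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 20
    weight_decay: float = 1e-5
    dropout: float = 0.3
    graph_update_every: int = 1  # epochs; 0 = static graph
    seed: int = 0

    def __post_init__(self):
        for name in ("learning_rate", "batch_size", "max_epochs", "patience",
                     "weight_decay", "dropout"):
            if getattr(self, name) <= 0 and name != "dropout":
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")


def derive_seed(seed: int, label: str) -> int:
    """Stable per-stage child seed (< 2^31) from one master seed."""
    child = np.random.SeedSequence(entropy=seed,
                                   spawn_key=(zlib.crc32(label.encode()),))
    return int(child.generate_state(1)[0] % (2**31))


def set_global_seed(seed: int) -> dict[str, int]:
    """Funnel all stochastic components off one master seed; also seeds the
    legacy numpy global state for third-party code."""
    np.random.seed(seed % (2**32))
    return {stage: derive_seed(seed, stage)
            for stage in ("cohort", "model", "train", "dropout",
                          "mc_dropout", "decode", "bootstrap")}


class StratModel(Module):
    """Encoder + risk head + intervention decoder over a shared embedding."""

    def __init__(self, modality_dims: dict[str, int], n_classes: int,
                 config: EncoderConfig, vocab_compat: CompatibilityMatrix,
                 seed: int = 0, use_graph: bool = True,
                 use_temporal: bool = True, use_cross_modal: bool = True):
        rng = np.random.default_rng(derive_seed(seed, "model"))
        d = config.hidden_dim
        self.config = config
        self.n_classes = n_classes
        self.compat = vocab_compat
        self.encoder = Encoder(modality_dims, config, rng,
                               use_graph=use_graph, use_temporal=use_temporal,
                               use_cross_modal=use_cross_modal)
        self.head = RiskHead(d, n_classes, rng, dropout_rate=config.dropout)
        self.decoder = InterventionDecoder(
            d_embed=min(d, 32), d_hidden=min(d, 64), d_patient=d,
            n_classes=n_classes, vocab=vocab_compat.vocab, rng=rng)

    def embed(self, features, masks, graph, training=False, rng=None,
              collect_attention=False):
        return self.encoder.forward(features, masks, graph, training=training,
                                    rng=rng, collect_attention=collect_attention)


def joint_loss(risk_log_probs: Tensor, y_true: np.ndarray,
               plan_nll: Tensor | float | None,
               weights: LossWeights, model_params: list[Tensor]) -> Tensor:
    """lambda1 * CE + lambda2 * NLL + lambda3 * sum ||theta||^2."""
    if not np.isfinite(np.asarray(
            risk_log_probs.data if isinstance(risk_log_probs, Tensor)
            else risk_log_probs)).all():
        raise ValueError("non-finite risk predictions")
    y = np.asarray(y_true)
    n = len(y)
    ce = -(risk_log_probs[np.arange(n), y].sum()) * (1.0 / n)
    total = weights.lambda1 * ce
    if weights.lambda2 > 0 and plan_nll is not None:
        total = total + weights.lambda2 * plan_nll
    if weights.lambda3 > 0:
        reg = None
        for p in model_params:
            term = (p**2).sum()
            reg = term if reg is None else reg + term
        total = total + weights.lambda3 * reg
    return total


def _forward_loss(model: StratModel, features, masks, graph,
                  cohort: SyntheticCohort, idx: np.ndarray,
                  weights: LossWeights, training: bool,
                  rng: np.random.Generator) -> tuple[Tensor, Tensor]:
    enc = model.embed(features, masks, graph, training=training, rng=rng)
    h = enc.h_global
    logp = model.head.log_probs(h[idx], training=training, rng=rng)
    plan_nll = None
    if weights.lambda2 > 0:
        targets = [cohort.intervention_targets[i] for i in idx]
        y_onehot = np.eye(model.n_classes)[cohort.labels[idx]]
        plan_nll = batch_teacher_forcing_nll(
            model.decoder, targets, h[idx], Tensor(y_onehot))
    loss = joint_loss(logp, cohort.labels[idx], plan_nll, weights,
                      model.parameters())
    return loss, h


def _normalized(h: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(h, axis=1, keepdims=True)
    return h / np.where(norms == 0, 1.0, norms)


def train(model: StratModel, cohort: SyntheticCohort,
          features: dict[str, np.ndarray], train_idx: np.ndarray,
          val_idx: np.ndarray, config: TrainConfig,
          weights: LossWeights | None = None,
          sim_config: SimilarityConfig | None = None,
          graph_params: GraphParams | None = None,
          verbose: bool = False) -> dict:
    """Fit the model; returns a history dict with per-epoch losses, the
    final graph, and the best (early-stopping) epoch."""
    if len(train_idx) == 0:
        raise ValueError("empty training set")
    weights = weights or LossWeights()
    sim_config = sim_config or SimilarityConfig(
        domain_weights=tuple([1.0 / len(cohort.features)] * len(cohort.features)),
        domains=tuple(cohort.features))
    graph_params = graph_params or GraphParams()
    rng = np.random.default_rng(derive_seed(config.seed, "dropout"))
    masks = cohort.masks
    domains = domain_feature_matrix(cohort)
    # wrap once: constant input tensors shared across epochs
    features = {n: Tensor(np.nan_to_num(np.asarray(x, dtype=float)))
                for n, x in features.items()}

    opt = AdamW(model.parameters(), lr=config.learning_rate,
                weight_decay=config.weight_decay)

    # initial graph from the untrained encoder's embeddings
    graph = None
    if model.encoder.use_graph:
        enc0 = model.embed(features, masks, None, training=False)
        graph = update_graph(_normalized(enc0.h_global.data), domains,
                             sim_config, graph_params)
        enc0.h_global.release()

    history = {"epoch": [], "train_loss": [], "val_loss": [], "density": []}
    best_val, best_epoch, since_best = np.inf, 0, 0
    best_state = [p.data.copy() for p in model.parameters()]
    for epoch in range(1, config.max_epochs + 1):
        opt.zero_grad()
        loss, h = _forward_loss(model, features, masks, graph, cohort,
                                train_idx, weights, True, rng)
        loss.backward()
        opt.step()

        if (model.encoder.use_graph and config.graph_update_every > 0
                and epoch % config.graph_update_every == 0):
            graph = update_graph(_normalized(h.data), domains, sim_config,
                                 graph_params)

        val_loss, _ = _forward_loss(model, features, masks, graph, cohort,
                                    val_idx, weights, False, rng)
        val_loss.release()
        history["epoch"].append(epoch)
        history["train_loss"].append(float(loss.data))
        history["val_loss"].append(float(val_loss.data))
        history["density"].append(graph.density if graph is not None else 0.0)
        if verbose:
            print(f"epoch {epoch}: train {loss.data:.4f} "
                  f"val {val_loss.data:.4f}")
        if float(val_loss.data) < best_val - 1e-12:
            best_val, best_epoch, since_best = float(val_loss.data), epoch, 0
            best_state = [p.data.copy() for p in model.parameters()]
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    for p, s in zip(model.parameters(), best_state):
        p.data = s
    return {"history": history, "graph": graph, "best_epoch": best_epoch,
            "best_val_loss": best_val, "stopped_epoch": history["epoch"][-1]}


def save_checkpoint(model: StratModel, path) -> None:
    """Parameter arrays to one binary .npz plus a JSON sidecar describing
    how to rebuild the model."""
    import json
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    params = model.parameters()
    np.savez(path, **{f"p{i}": p.data for i, p in enumerate(params)},
             bn_state=np.concatenate([
                 model.head.bn1.running_mean, model.head.bn1.running_var,
                 model.head.bn2.running_mean, model.head.bn2.running_var]))
    meta = {
        "modality_dims": {n: int(e.d_in)
                          for n, e in model.encoder.encoders.items()},
        "n_classes": model.n_classes,
        "encoder": {"hidden_dim": model.config.hidden_dim,
                    "graph_layers": model.config.graph_layers,
                    "attention_heads": model.config.attention_heads,
                    "temporal_window": model.config.temporal_window,
                    "dropout": model.config.dropout},
        "flags": {"use_graph": model.encoder.use_graph,
                  "use_temporal": model.encoder.use_temporal,
                  "use_cross_modal": model.encoder.use_cross_modal},
        "compat": model.compat.to_json(),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path) -> StratModel:
    import json
    from pathlib import Path

    from .encoder import EncoderConfig

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    compat = CompatibilityMatrix.from_json(meta["compat"])
    model = StratModel(meta["modality_dims"], meta["n_classes"],
                       EncoderConfig(**meta["encoder"]), compat,
                       **meta["flags"])
    arrays = np.load(path if path.suffix == ".npz"
                     else path.with_suffix(".npz"))
    for i, p in enumerate(model.parameters()):
        p.data = arrays[f"p{i}"]
    bn = arrays["bn_state"]
    d = model.config.hidden_dim
    model.head.bn1.running_mean = bn[:d]
    model.head.bn1.running_var = bn[d:2 * d]
    model.head.bn2.running_mean = bn[2 * d:3 * d]
    model.head.bn2.running_var = bn[3 * d:]
    return model


def predict(model: StratModel, features, masks, graph) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic class probabilities and labels for every patient."""
    enc = model.embed(features, masks, graph, training=False)
    logits = model.head.logits(enc.h_global, training=False)
    probs = softmax(logits, axis=-1).data
    return probs, probs.argmax(axis=1)
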