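"""Risk stratification head with Monte Carlo dropout uncertainty.

The classifier maps global patient embeddings through two hidden layers
(with batch-style normalization and dropout) to a softmax over K risk
strata.  Uncertainty is estimated by repeated stochastic forward passes
with dropout active and normalization statistics frozen: the pass-averaged
probabilities, their predictive entropy (nats), and the coefficient of
variation of the predicted-class probability across passes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, dropout, log_softmax, softmax
from .nn import BatchNorm, Linear, Module


@dataclass
class RiskPrediction:
    probs: np.ndarray  # [K] (or [N, K]) rows summing to 1
    logits: np.ndarray
    predicted_class: np.ndarray | int


@dataclass
class UncertaintyEstimate:
    mean_probs: np.ndarray
    predictive_entropy: np.ndarray | float  # nats, <= ln K
    coefficient_of_variation: np.ndarray | float
    n_passes: int


def predictive_entropy(p: np.ndarray) -> np.ndarray | float:
    """-sum p log p in nats, with 0 log 0 = 0; p may be [K] or [N, K]."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("probabilities must be nonnegative")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=-1)
    return float(h) if h.ndim == 0 else h


class RiskHead(Module):
    """Two hidden layers of width d with normalization + dropout, then a
    K-way softmax."""

    def __init__(self, d: int, n_classes: int, rng: np.random.Generator,
                 dropout_rate: float = 0.3):
        self.fc1 = Linear(d, d, rng)
        self.bn1 = BatchNorm(d)
        self.fc2 = Linear(d, d, rng)
        self.bn2 = BatchNorm(d)
        self.out = Linear(d, n_classes, rng)
        self.dropout_rate = dropout_rate
        self.n_classes = n_classes

    def logits(self, h: Tensor, training: bool = False,
               rng: np.random.Generator | None = None,
               stochastic: bool | None = None) -> Tensor:
        """`training` controls batch-norm statistics; `stochastic` controls
        dropout (defaults to `training`; MC dropout sets it True with
        frozen normalization)."""
        stochastic = training if stochastic is None else stochastic
        rng = rng or np.random.default_rng(0)
        x = h if isinstance(h, Tensor) else Tensor(np.asarray(h, float))
        x = dropout(self.bn1(self.fc1(x), training).relu(),
                    self.dropout_rate, rng, stochastic)
        x = dropout(self.bn2(self.fc2(x), training).relu(),
                    self.dropout_rate, rng, stochastic)
        return self.out(x)

    def log_probs(self, h, training=False, rng=None, stochastic=None) -> Tensor:
        return log_softmax(self.logits(h, training, rng, stochastic), axis=-1)


def classify(h, head: RiskHead) -> RiskPrediction:
    """Deterministic prediction (dropout off, frozen normalization)."""
    arr = np.asarray(h.data if isinstance(h, Tensor) else h, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("non-finite embedding")
    single = arr.ndim == 1
    logits = head.logits(Tensor(arr.reshape(1, -1) if single else arr),
                         training=False).data
    probs = softmax(Tensor(logits), axis=-1).data
    if single:
        logits, probs = logits[0], probs[0]
        return RiskPrediction(probs, logits, int(np.argmax(probs)))
    return RiskPrediction(probs, logits, np.argmax(probs, axis=-1))


def mc_dropout_predict(h, head: RiskHead, n_passes: int = 50,
                       seed: int = 0) -> UncertaintyEstimate:
    """`n_passes` stochastic forward passes with independent dropout masks;
    batch-normalization statistics stay frozen (evaluation mode)."""
    if n_passes < 1:
        raise ValueError("n_passes must be >= 1")
    arr = np.asarray(h.data if isinstance(h, Tensor) else h, dtype=float)
    single = arr.ndim == 1
    x = Tensor(arr.reshape(1, -1) if single else arr)
    rng = np.random.default_rng(seed)
    passes = []
    for _ in range(n_passes):
        logits = head.logits(x, training=False, rng=rng, stochastic=True)
        passes.append(softmax(logits, axis=-1).data)
    stacked = np.stack(passes)  # [P, N, K]
    mean_probs = stacked.mean(axis=0)
    entropy = predictive_entropy(mean_probs)
    pred = np.argmax(mean_probs, axis=-1)
    chosen = np.take_along_axis(stacked, pred[None, :, None], axis=2)[:, :, 0]
    mean_c = chosen.mean(axis=0)
    std_c = chosen.std(axis=0) if n_passes >= 2 else np.zeros_like(mean_c)
    cov = np.where(mean_c > 0, std_c / mean_c, 0.0)
    if single:
        return UncertaintyEstimate(mean_probs[0], float(np.asarray(entropy).ravel()[0]),
                                   float(cov[0]), n_passes)
    return UncertaintyEstimate(mean_probs, entropy, cov, n_passes)
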