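"""Evaluation protocol: stratified splitting, classification metrics,
bootstrap confidence intervals, paired significance tests with Bonferroni
correction, BLEU for plan similarity, and the component-ablation harness.

BLEU here is documented as a surface-similarity metric only: it measures
n-gram overlap between a generated plan and reference plans, not clinical
appropriateness.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import (accuracy_score, cohen_kappa_score,
                             precision_recall_fscore_support, roc_auc_score)

from .cohort import SyntheticCohort
from .encoder import EncoderConfig
from .training import LossWeights, StratModel, TrainConfig, predict, train

BLEU_EPSILON = 1e-9  # add-eps smoothing for zero higher-order precisions


# ------------------------------------------------------------------ splits

def _largest_remainder(n: int, fractions: np.ndarray) -> np.ndarray:
    ideal = n * fractions
    sizes = np.floor(ideal).astype(int)
    rem = ideal - sizes
    order = np.argsort(-rem, kind="stable")
    for idx in order[: n - sizes.sum()]:
        sizes[idx] += 1
    return sizes


def split_cohort(n: int, fractions=(0.70, 0.15, 0.15),
                 strata: np.ndarray | None = None, seed: int = 0) -> np.ndarray:
    """Partition assignment (ints 0..P-1) by largest-remainder apportionment,
    stratified when `strata` is given; deterministic per seed."""
    fractions = np.asarray(fractions, dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    if strata is None:
        groups = [np.arange(n)]
    else:
        strata = np.asarray(strata)
        groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    for members in groups:
        members = rng.permutation(members)
        sizes = _largest_remainder(len(members), fractions)
        start = 0
        for part, size in enumerate(sizes):
            assignment[members[start:start + size]] = part
            start += size
    return assignment


# ----------------------------------------------------------------- metrics

@dataclass
class MetricReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_auc: float | None
    kappa: float
    per_class: dict = field(default_factory=dict)


def classification_metrics(y_true, y_pred, probs=None) -> MetricReport:
    """Macro-averaged multiclass metrics; AUC is one-vs-rest macro-averaged,
    with classes absent from y_true excluded (warning)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    acc = accuracy_score(y_true, y_pred)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, average="macro", zero_division=0)
        kappa = cohen_kappa_score(y_true, y_pred)
    auc = None
    if probs is not None:
        probs = np.asarray(probs, dtype=float)
        present = np.unique(y_true)
        if len(present) < probs.shape[1]:
            warnings.warn("classes absent from y_true excluded from macro-AUC",
                          stacklevel=2)
            aucs = []
            for k in present:
                aucs.append(roc_auc_score((y_true == k).astype(int),
                                          probs[:, k]))
            auc = float(np.mean(aucs))
        else:
            auc = float(roc_auc_score(y_true, probs, multi_class="ovr",
                                      average="macro"))
    classes, counts = np.unique(y_true, return_counts=True)
    pc_prec, pc_rec, pc_f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0)
    per_class = {int(k): {"precision": float(p), "recall": float(r),
                          "f1": float(f), "support": int(c)}
                 for k, p, r, f, c in zip(classes, pc_prec, pc_rec, pc_f1,
                                          counts)}
    return MetricReport(float(acc), float(prec), float(rec), float(f1),
                        auc, float(kappa), per_class)


# --------------------------------------------------------------- bootstrap

def bootstrap_ci(metric_fn, y_true, y_pred_or_probs, n_boot: int = 1000,
                 level: float = 0.95, seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap interval over resampled patient indices."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    y_true = np.asarray(y_true)
    other = np.asarray(y_pred_or_probs)
    rng = np.random.default_rng(seed)
    n = len(y_true)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        vals[b] = metric_fn(y_true[idx], other[idx])
    if np.ptp(vals) == 0:
        warnings.warn("degenerate metric: zero-width interval", stacklevel=2)
    alpha = (1 - level) / 2
    return (float(np.quantile(vals, alpha)),
            float(np.quantile(vals, 1 - alpha)))


def paired_bootstrap_ci(metric_fn, y_true, pred_a, pred_b,
                        n_boot: int = 1000, level: float = 0.95,
                        seed: int = 0) -> tuple[float, float]:
    """CI on the metric difference (a - b), both models evaluated on the
    *same* resampled indices."""
    y_true = np.asarray(y_true)
    pred_a, pred_b = np.asarray(pred_a), np.asarray(pred_b)
    rng = np.random.default_rng(seed)
    n = len(y_true)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        diffs[b] = (metric_fn(y_true[idx], pred_a[idx])
                    - metric_fn(y_true[idx], pred_b[idx]))
    alpha = (1 - level) / 2
    return (float(np.quantile(diffs, alpha)),
            float(np.quantile(diffs, 1 - alpha)))


# ------------------------------------------------------------ paired tests

def paired_test(metric_a, metric_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired per-fold metrics
    (exact for n <= 25, normal approximation otherwise)."""
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    if np.all(d == 0):
        warnings.warn("all paired differences are zero: p = 1", stacklevel=2)
        return 1.0
    method = "exact" if len(a) <= 25 else "approx"
    return float(stats.wilcoxon(a, b, alternative="two-sided",
                                method=method).pvalue)


def bonferroni_threshold(alpha: float, n_tests: int) -> tuple[float, float]:
    """(exact, rounded-to-4-dp) corrected significance threshold."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    exact = alpha / n_tests
    return exact, round(exact, 4)


# -------------------------------------------------------------------- BLEU

def _ngram_counts(seq, n):
    return Counter(tuple(seq[i:i + n]) for i in range(len(seq) - n + 1))


def bleu(candidate, references, max_n: int = 4) -> float:
    """Geometric mean of modified n-gram precisions with brevity penalty.

    Zero higher-order precisions are smoothed by add-eps (1e-9); a zero
    1-gram precision scores 0.  Surface similarity only.
    """
    if len(candidate) == 0:
        raise ValueError("empty candidate")
    references = [list(r) for r in references]
    if len(references) == 0:
        raise ValueError("empty reference set")
    candidate = list(candidate)
    log_precisions = []
    for n in range(1, max_n + 1):
        cand = _ngram_counts(candidate, n)
        total = sum(cand.values())
        if total == 0:  # candidate shorter than n
            log_precisions.append(np.log(BLEU_EPSILON))
            continue
        max_ref = Counter()
        for ref in references:
            for g, c in _ngram_counts(ref, n).items():
                max_ref[g] = max(max_ref[g], c)
        clipped = sum(min(c, max_ref[g]) for g, c in cand.items())
        if clipped == 0:
            if n == 1:
                return 0.0
            log_precisions.append(np.log(BLEU_EPSILON))
        else:
            log_precisions.append(np.log(clipped / total))
    c_len = len(candidate)
    r_len = min((len(r) for r in references),
                key=lambda rl: (abs(rl - c_len), rl))
    bp = 1.0 if c_len >= r_len else np.exp(1.0 - r_len / c_len)
    return float(bp * np.exp(np.mean(log_precisions)))


# ---------------------------------------------------------------- ablation

@dataclass(frozen=True)
class AblationConfig:
    name: str = "full"
    use_graph: bool = True
    use_temporal: bool = True
    use_cross_modal: bool = True
    dynamic_graph: bool = True
    modalities: tuple[str, ...] | None = None  # None = all

    def __post_init__(self):
        if not (self.use_graph or self.use_temporal or self.use_cross_modal):
            raise ValueError("at least one pathway must stay enabled")


def run_ablation(configs: list[AblationConfig], cohort: SyntheticCohort,
                 features: dict[str, np.ndarray], assignment: np.ndarray,
                 encoder_config: EncoderConfig, train_config: TrainConfig,
                 compat, weights: LossWeights | None = None) -> dict[str, dict]:
    """Train one model per configuration on identical splits and pipeline;
    returns test-set MetricReports plus macro-F1 deltas vs. the first
    (reference) configuration."""
    train_idx = np.flatnonzero(assignment == 0)
    val_idx = np.flatnonzero(assignment == 1)
    test_idx = np.flatnonzero(assignment == 2)
    results: dict[str, dict] = {}
    ref_f1 = None
    for cfg in configs:
        names = list(cfg.modalities) if cfg.modalities else list(cohort.features)
        dims = {n: cohort.features[n].shape[2] for n in names}
        model = StratModel(dims, cohort.spec.n_risk_classes, encoder_config,
                           compat, seed=train_config.seed,
                           use_graph=cfg.use_graph,
                           use_temporal=cfg.use_temporal,
                           use_cross_modal=cfg.use_cross_modal)
        tc = TrainConfig(
            learning_rate=train_config.learning_rate,
            batch_size=train_config.batch_size,
            max_epochs=train_config.max_epochs,
            patience=train_config.patience,
            weight_decay=train_config.weight_decay,
            dropout=train_config.dropout,
            graph_update_every=(train_config.graph_update_every
                                if cfg.dynamic_graph else 0),
            seed=train_config.seed)
        feats = {n: features[n] for n in names}
        masks = {n: cohort.masks[n] for n in names}
        sub_cohort = cohort if cfg.modalities is None else _subset(cohort, names)
        fit = train(model, sub_cohort, feats, train_idx, val_idx, tc,
                    weights=weights)
        probs, pred = predict(model, feats, masks, fit["graph"])
        report = classification_metrics(cohort.labels[test_idx],
                                        pred[test_idx], probs[test_idx])
        entry = {"report": report, "config": cfg,
                 "best_epoch": fit["best_epoch"]}
        if ref_f1 is None:
            ref_f1 = report.macro_f1
        entry["delta_f1"] = report.macro_f1 - ref_f1
        results[cfg.name] = entry
    return results


def _subset(cohort: SyntheticCohort, names: list[str]) -> SyntheticCohort:
    return SyntheticCohort(
        features={n: cohort.features[n] for n in names},
        masks={n: cohort.masks[n] for n in names},
        labels=cohort.labels, clusters=cohort.clusters,
        categories=cohort.categories,
        intervention_targets=cohort.intervention_targets, spec=cohort.spec)
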