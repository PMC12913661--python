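"""Synthetic multimodal longitudinal cohort generator.

Real rehabilitation cohorts of this kind are private, so every downstream
stage of the package is exercised on synthetic cohorts with *planted*,
graph-recoverable structure:

* four default modalities generated directly in feature/embedding space
  (vitals 12-d, labs 48-d, imaging 512-d, text 768-d) over T weekly steps;
* a Gaussian cluster-centroid model with label-dependent mean shifts, so
  patients sharing a cluster (and a risk stratum) are more similar in
  cosine terms than cross-cluster pairs, with separation controlled by
  ``cluster_signal``;
* per-step AR(1) temporal drift (coefficient 0.8) so temporal attention has
  signal to exploit;
* missing-completely-at-random observation masks at a configurable marginal
  rate, with at least one observed step per patient and modality;
* long-tail disease-category assignments and risk strata apportioned to the
  configured class mixture;
* intervention target sequences drawn from risk-stratum-conditional token
  distributions under a pairwise compatibility matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .actions import ActionVocabulary, CompatibilityMatrix

AR_COEFFICIENT = 0.8  # temporal drift of the within-patient noise process
_SENTINEL = np.nan  # masked entries; distinguishable from observed zeros

DEFAULT_CLASS_MIX = (0.183, 0.241, 0.312, 0.264)  # High .. Low risk strata
DEFAULT_MISSING_RATE = 0.124

RISK_STRATA = ("high", "moderate_high", "moderate_low", "low")


@dataclass(frozen=True)
class ModalitySpec:
    name: str
    dim: int
    cadence: str = "per-step"  # per-step | irregular | static
    preprocessing: str = "none"  # zscore | minmax | none

    def __post_init__(self):
        if self.dim < 1:
            raise ValueError(f"modality '{self.name}': dim must be >= 1")
        if self.cadence not in ("per-step", "irregular", "static"):
            raise ValueError(f"unknown cadence '{self.cadence}'")
        if self.preprocessing not in ("zscore", "minmax", "none"):
            raise ValueError(f"unknown preprocessing '{self.preprocessing}'")


def default_modalities() -> tuple[ModalitySpec, ...]:
    """The four core modalities (imaging/text arrive pre-embedded)."""
    return (
        ModalitySpec("vitals", 12, "per-step", "zscore"),
        ModalitySpec("labs", 48, "irregular", "minmax"),
        ModalitySpec("imaging", 512, "per-step", "none"),
        ModalitySpec("text", 768, "irregular", "none"),
    )


@dataclass(frozen=True)
class CohortSpec:
    n_patients: int
    n_steps: int = 12
    modalities: tuple[ModalitySpec, ...] = field(default_factory=default_modalities)
    n_risk_classes: int = 4
    class_mix: tuple[float, ...] = DEFAULT_CLASS_MIX
    missing_rate: float = DEFAULT_MISSING_RATE
    n_clusters: int = 8
    cluster_signal: float = 2.0
    category_tail_exponent: float = 1.2
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1 or self.n_steps < 1:
            raise ValueError("n_patients and n_steps must be positive")
        if len(self.class_mix) != self.n_risk_classes:
            raise ValueError("class_mix length must equal n_risk_classes")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_clusters > self.n_patients:
            raise ValueError("n_clusters must not exceed n_patients")
        if self.cluster_signal < 0:
            raise ValueError("cluster_signal must be nonnegative")
        if self.category_tail_exponent <= 0:
            raise ValueError("category_tail_exponent must be positive")


@dataclass
class SyntheticCohort:
    features: dict[str, np.ndarray]  # name -> [N, T, F_m]; masked entries NaN
    masks: dict[str, np.ndarray]  # name -> [N, T] boolean (True = observed)
    labels: np.ndarray  # [N] ints in {0..K-1}; 0 = High risk
    clusters: np.ndarray
    categories: np.ndarray
    intervention_targets: list[list[int]]
    spec: CohortSpec

    @property
    def n_patients(self) -> int:
        return self.spec.n_patients

    def observed_fraction(self) -> float:
        total = sum(m.size for m in self.masks.values())
        return sum(m.sum() for m in self.masks.values()) / total


def _apportion(n: int, probs: np.ndarray) -> np.ndarray:
    """Largest-remainder integer apportionment of n among len(probs) bins."""
    ideal = n * np.asarray(probs, dtype=float)
    counts = np.floor(ideal).astype(int)
    remainder = ideal - counts
    for idx in np.argsort(-remainder)[: n - counts.sum()]:
        counts[idx] += 1
    return counts


def assign_long_tail_categories(n: int, exponent: float, seed: int,
                                n_categories: int | None = None) -> np.ndarray:
    """Draw disease-category labels under a Zipf-like long-tail law."""
    if n <= 0:
        raise ValueError("n must be positive")
    if exponent <= 0:
        raise ValueError("exponent must be positive")
    rng = np.random.default_rng(seed)
    k = n_categories if n_categories is not None else min(n, 156)
    with np.errstate(over="ignore", under="ignore"):
        weights = np.arange(1, k + 1, dtype=float) ** (-exponent)
    weights = np.where(np.isfinite(weights), weights, 0.0)
    if weights.sum() == 0:  # degenerate: exponent so large everything underflows
        weights[0] = 1.0
    probs = weights / weights.sum()
    return rng.choice(k, size=n, p=probs)


def generate_intervention_targets(labels: np.ndarray,
                                  compat: CompatibilityMatrix,
                                  vocab: ActionVocabulary,
                                  seed: int,
                                  max_len: int = 8) -> list[list[int]]:
    """Risk-stratum-conditional action sequences respecting `compat`.

    Each sequence holds at least one action, every unordered token pair is
    compatible, and the reserved end token terminates the plan.
    """
    rng = np.random.default_rng(seed)
    k = int(labels.max()) + 1 if len(labels) else 0
    n_actions = vocab.end_index
    class_logits = rng.normal(scale=1.5, size=(k, n_actions))
    targets: list[list[int]] = []
    for y in labels:
        prefs = np.exp(class_logits[y] - class_logits[y].max())
        seq: list[int] = []
        for step in range(max_len):
            mask = compat.feasible_mask(seq)[:n_actions]
            p = prefs * mask
            if p.sum() == 0:  # no feasible action remains
                break
            if step > 0 and rng.random() < 0.35:  # stochastic plan termination
                break
            seq.append(int(rng.choice(n_actions, p=p / p.sum())))
        seq.append(vocab.end_index)
        targets.append(seq)
    return targets


def generate_cohort(spec: CohortSpec,
                    compat: CompatibilityMatrix | None = None) -> SyntheticCohort:
    """Generate a cohort with planted cluster/label structure (deterministic
    for a fixed ``spec.seed``)."""
    rng = np.random.default_rng(spec.seed)
    n, t = spec.n_patients, spec.n_steps
    compat = compat or CompatibilityMatrix.fully_compatible()

    # Risk strata: apportion N to the class mixture (largest remainder), then
    # permute — stratified assignment reproduces the configured proportions.
    counts = _apportion(n, np.asarray(spec.class_mix))
    labels = rng.permutation(np.repeat(np.arange(spec.n_risk_classes), counts))

    clusters = rng.integers(0, spec.n_clusters, size=n)
    categories = assign_long_tail_categories(
        n, spec.category_tail_exponent, seed=int(rng.integers(2**31)))

    features: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    for mod in spec.modalities:
        f = mod.dim
        centroids = rng.normal(size=(spec.n_clusters, f))
        label_shift = rng.normal(size=(spec.n_risk_classes, f))
        base = spec.cluster_signal * (centroids[clusters] + label_shift[labels])
        # stationary AR(1) noise, unit marginal variance
        noise = np.empty((n, t, f))
        noise[:, 0, :] = rng.normal(size=(n, f))
        innov_scale = np.sqrt(1.0 - AR_COEFFICIENT**2)
        for step in range(1, t):
            noise[:, step, :] = (AR_COEFFICIENT * noise[:, step - 1, :]
                                 + innov_scale * rng.normal(size=(n, f)))
        x = base[:, None, :] + noise

        observed = rng.random((n, t)) >= spec.missing_rate
        all_missing = ~observed.any(axis=1)
        if all_missing.any():  # every patient keeps >= 1 observed step
            forced = rng.integers(0, t, size=int(all_missing.sum()))
            observed[np.flatnonzero(all_missing), forced] = True
        x[~observed] = _SENTINEL
        features[mod.name] = x
        masks[mod.name] = observed

    targets = generate_intervention_targets(
        labels, compat, compat.vocab, seed=int(rng.integers(2**31)))

    return SyntheticCohort(features=features, masks=masks, labels=labels,
                           clusters=clusters, categories=categories,
                           intervention_targets=targets, spec=spec)


def domain_feature_matrix(cohort: SyntheticCohort) -> dict[str, np.ndarray]:
    """Per-modality patient profiles (observed time-mean), the feature-domain
    inputs of the composite patient-similarity function."""
    out: dict[str, np.ndarray] = {}
    for name, x in cohort.features.items():
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(x, axis=1)
        out[name] = np.nan_to_num(mean)
    return out


# ---------------------------------------------------------------------- io

def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Serialize a cohort: one long-format CSV per modality, mask CSV,
    labels CSV, JSON-lines targets and a JSON sidecar for the spec."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, x in cohort.features.items():
        n, t, f = x.shape
        obs = cohort.masks[name]
        pid, step = np.nonzero(obs)
        rows = {
            "patient_id": np.repeat(pid, f),
            "step": np.repeat(step, f),
            "feature_index": np.tile(np.arange(f), len(pid)),
            "value": x[pid, step].ravel(),
        }
        pd.DataFrame(rows).to_csv(outdir / f"modality_{name}.csv", index=False)
    mask_rows = []
    for name, m in cohort.masks.items():
        pid, step = np.meshgrid(np.arange(m.shape[0]), np.arange(m.shape[1]),
                                indexing="ij")
        mask_rows.append(pd.DataFrame({
            "patient_id": pid.ravel(), "step": step.ravel(),
            "modality": name, "observed": m.ravel().astype(int)}))
    pd.concat(mask_rows, ignore_index=True).to_csv(outdir / "masks.csv", index=False)
    pd.DataFrame({
        "patient_id": np.arange(cohort.n_patients),
        "label": cohort.labels, "cluster": cohort.clusters,
        "category": cohort.categories,
    }).to_csv(outdir / "labels.csv", index=False)
    with open(outdir / "targets.jsonl", "w") as fh:
        for i, seq in enumerate(cohort.intervention_targets):
            fh.write(json.dumps({"patient_id": i, "tokens": seq}) + "\n")
    sidecar = {
        "n_patients": cohort.spec.n_patients, "n_steps": cohort.spec.n_steps,
        "modalities": [vars(m).copy() for m in cohort.spec.modalities],
        "n_risk_classes": cohort.spec.n_risk_classes,
        "class_mix": list(cohort.spec.class_mix),
        "missing_rate": cohort.spec.missing_rate,
        "n_clusters": cohort.spec.n_clusters,
        "cluster_signal": cohort.spec.cluster_signal,
        "category_tail_exponent": cohort.spec.category_tail_exponent,
        "seed": cohort.spec.seed,
    }
    with open(outdir / "spec.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_cohort(indir: str | Path) -> SyntheticCohort:
    indir = Path(indir)
    with open(indir / "spec.json") as fh:
        d = json.load(fh)
    mods = tuple(ModalitySpec(**m) for m in d.pop("modalities"))
    d["class_mix"] = tuple(d["class_mix"])
    spec = CohortSpec(modalities=mods, **d)
    n, t = spec.n_patients, spec.n_steps

    mask_df = pd.read_csv(indir / "masks.csv")
    masks, features = {}, {}
    for mod in mods:
        m = np.zeros((n, t), dtype=bool)
        sub = mask_df[mask_df["modality"] == mod.name]
        m[sub["patient_id"], sub["step"]] = sub["observed"].astype(bool)
        masks[mod.name] = m
        x = np.full((n, t, mod.dim), _SENTINEL)
        df = pd.read_csv(indir / f"modality_{mod.name}.csv")
        x[df["patient_id"], df["step"], df["feature_index"]] = df["value"]
        features[mod.name] = x

    lab = pd.read_csv(indir / "labels.csv").sort_values("patient_id")
    targets: list[list[int]] = [[] for _ in range(n)]
    with open(indir / "targets.jsonl") as fh:
        for line in fh:
            rec = json.loads(line)
            targets[rec["patient_id"]] = list(rec["tokens"])
    return SyntheticCohort(features=features, masks=masks,
                           labels=lab["label"].to_numpy(),
                           clusters=lab["cluster"].to_numpy(),
                           categories=lab["category"].to_numpy(),
                           intervention_targets=targets, spec=spec)
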