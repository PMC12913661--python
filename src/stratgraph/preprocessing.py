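"""Imputation, scaling and outlier flagging for longitudinal cohorts.

The rules implemented here follow standard leakage-free practice:

* last-observation-carried-forward (LOCF) for temporally continuous series,
  with leading gaps back-filled from the first observation;
* median imputation computed within disease-category groups, with a global
  median fallback for groups that are entirely missing;
* z-standardization fit on the training partition only, then applied
  unchanged to validation/test data;
* min-max scaling to [0, 1] with training-fit extremes and clipping of
  out-of-range values;
* outlier *flagging* (never silent replacement) through a pluggable anomaly
  scorer; the default is a robust z-score (|x - median| / (1.4826 * MAD))
  mapped through a logistic.  Flagged values are reported for review.

Embedding-space modalities (imaging/text) use a reserved constant "missing"
vector instead of value imputation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import expit

from .cohort import SyntheticCohort

MAD_CONSISTENCY = 1.4826  # normal-consistency factor for the MAD
MEANAD_CONSISTENCY = 1.2533  # ... for the mean absolute deviation fallback


# ------------------------------------------------------------- imputation

def impute_locf(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Carry the last observed value forward; back-fill leading gaps.

    `values` and `mask` are length-T (or [..., T]) arrays; mask True/1 marks
    observed entries.  Raises on an all-missing series.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if values.shape[-1] != mask.shape[-1]:
        raise ValueError("values and mask lengths differ")
    if not mask.any(axis=-1).all():
        raise ValueError("all-missing series cannot be imputed by LOCF")
    t = values.shape[-1]
    idx = np.where(mask, np.arange(t), -1)
    idx = np.maximum.accumulate(idx, axis=-1)  # last observed index so far
    first = np.argmax(mask, axis=-1)  # back-fill source for leading gaps
    idx = np.where(idx < 0, first[..., None] if values.ndim > 1 else first, idx)
    return np.take_along_axis(values, idx, axis=-1) if values.ndim > 1 \
        else values[idx]


def impute_group_median(values: np.ndarray, mask: np.ndarray,
                        groups: np.ndarray) -> np.ndarray:
    """Replace missing entries by the observed median of their group,
    falling back to the global observed median for empty groups."""
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    groups = np.asarray(groups)
    if not mask.any():
        raise ValueError("no observed values at all")
    out = values.copy()
    global_median = np.median(values[mask])
    for g in np.unique(groups):
        in_g = groups == g
        missing = in_g & ~mask
        if not missing.any():
            continue
        observed = in_g & mask
        fill = np.median(values[observed]) if observed.any() else global_median
        out[missing] = fill
    return out


@dataclass(frozen=True)
class ImputationPolicy:
    """Per-modality imputation rule; `mask_token` substitutes the reserved
    missing-embedding vector (zeros by convention) for unobserved steps."""

    rules: dict[str, str] = field(default_factory=lambda: {
        "vitals": "locf", "labs": "group_median",
        "imaging": "mask_token", "text": "mask_token"})
    group_key: str = "category"

    VALID = ("locf", "group_median", "mask_token", "none")

    def __post_init__(self):
        for name, rule in self.rules.items():
            if rule not in self.VALID:
                raise ValueError(f"unknown imputation rule '{rule}' for '{name}'")


def impute_cohort(cohort: SyntheticCohort,
                  policy: ImputationPolicy | None = None) -> dict[str, np.ndarray]:
    """Apply the per-modality policy; returns filled [N, T, F] arrays."""
    policy = policy or ImputationPolicy()
    filled: dict[str, np.ndarray] = {}
    for name, x in cohort.features.items():
        rule = policy.rules.get(name, "mask_token")
        obs = cohort.masks[name]  # [N, T]
        out = x.copy()
        if rule == "locf":
            # [N, T, F] -> impute along T per feature
            out = np.swapaxes(impute_locf(
                np.swapaxes(x, 1, 2), np.broadcast_to(
                    obs[:, None, :], (x.shape[0], x.shape[2], x.shape[1]))), 1, 2)
        elif rule == "group_median":
            for f in range(x.shape[2]):
                for t in range(x.shape[1]):
                    col, m = x[:, t, f], obs[:, t]
                    if m.all():
                        continue
                    if m.any():
                        out[:, t, f] = impute_group_median(
                            np.nan_to_num(col), m, cohort.categories)
                    else:  # step unobserved everywhere: global observed median
                        out[:, t, f] = np.median(x[:, :, f][obs])
        elif rule == "mask_token":
            out[~obs] = 0.0  # reserved missing vector; encoder swaps in its own
        elif rule == "none":
            pass
        filled[name] = out
    return filled


# --------------------------------------------------------- standardization

@dataclass
class StandardizationParams:
    mean: np.ndarray
    scale: np.ndarray  # population std; constant features get scale 1
    constant_features: np.ndarray  # boolean flags
    fit_partition: str = "train"

    def to_json(self) -> str:
        return json.dumps({"mean": self.mean.tolist(),
                           "scale": self.scale.tolist(),
                           "constant_features": self.constant_features.tolist(),
                           "fit_partition": self.fit_partition})

    @classmethod
    def from_json(cls, s: str) -> "StandardizationParams":
        d = json.loads(s)
        return cls(np.asarray(d["mean"]), np.asarray(d["scale"]),
                   np.asarray(d["constant_features"], dtype=bool),
                   d["fit_partition"])


def fit_standardizer(train_features: np.ndarray,
                     fit_partition: str = "train") -> StandardizationParams:
    """Per-feature location/scale from the training partition only."""
    x = np.asarray(train_features, dtype=float)
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    constant = std < 1e-12
    if constant.any():
        warnings.warn("constant feature(s) found: scale set to 1", stacklevel=2)
    scale = np.where(constant, 1.0, std)
    return StandardizationParams(mean, scale, constant, fit_partition)


def apply_standardizer(params: StandardizationParams,
                       features: np.ndarray) -> np.ndarray:
    if params is None:
        raise RuntimeError("standardizer must be fit before application")
    return (np.asarray(features, dtype=float) - params.mean) / params.scale


# ------------------------------------------------------------ min-max scale

def fit_minmax(train_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(train_values, dtype=float)
    return x.min(axis=0), x.max(axis=0)


def minmax_scale(values: np.ndarray, fitted_min, fitted_max) -> np.ndarray:
    """Affine map of the fitted range onto [0, 1]; out-of-range values clip.
    A degenerate range (max == min) maps to a constant 0.5."""
    values = np.asarray(values, dtype=float)
    lo = np.asarray(fitted_min, dtype=float)
    hi = np.asarray(fitted_max, dtype=float)
    span = hi - lo
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = (values - lo) / span
    scaled = np.where(span > 0, scaled, 0.5)
    return np.clip(scaled, 0.0, 1.0)


# ---------------------------------------------------------- outlier flags

def preprocess_cohort(cohort: SyntheticCohort, train_idx: np.ndarray,
                      policy: ImputationPolicy | None = None
                      ) -> tuple[dict[str, np.ndarray], dict[str, object]]:
    """Impute, then scale each modality per its declared preprocessing rule.

    Scaling parameters are fit on the training patients only and applied
    unchanged everywhere else (leakage-free).  Returns (features, params).
    """
    filled = impute_cohort(cohort, policy)
    train_idx = np.asarray(train_idx)
    out: dict[str, np.ndarray] = {}
    fitted: dict[str, object] = {}
    for mod in cohort.spec.modalities:
        x = filled[mod.name]
        n, t, f = x.shape
        flat_train = x[train_idx].reshape(-1, f)
        if mod.preprocessing == "zscore":
            params = fit_standardizer(flat_train)
            out[mod.name] = apply_standardizer(
                params, x.reshape(-1, f)).reshape(n, t, f)
            fitted[mod.name] = params
        elif mod.preprocessing == "minmax":
            lo, hi = fit_minmax(flat_train)
            out[mod.name] = minmax_scale(
                x.reshape(-1, f), lo, hi).reshape(n, t, f)
            fitted[mod.name] = (lo, hi)
        else:
            out[mod.name] = x
            fitted[mod.name] = None
    return out, fitted


def robust_z_scorer(values: np.ndarray) -> np.ndarray:
    """Default anomaly scorer: logistic-squashed robust z-scores in [0, 1].

    Scale is 1.4826*MAD; when the MAD collapses to zero on non-constant data
    (more than half the entries tie), the consistency-scaled mean absolute
    deviation substitutes.  All-identical input scores 0 with a warning.
    """
    x = np.asarray(values, dtype=float)
    med = np.median(x)
    dev = np.abs(x - med)
    mad = np.median(dev)
    if mad > 0:
        scale = MAD_CONSISTENCY * mad
    elif dev.max() > 0:
        scale = MEANAD_CONSISTENCY * dev.mean()
    else:
        warnings.warn("zero dispersion: no outlier flags", stacklevel=2)
        return np.zeros_like(x)
    z = dev / scale
    return expit((z - 3.0) / 0.3)


def flag_outliers(values: np.ndarray,
                  scorer: Callable[[np.ndarray], np.ndarray] | None = None,
                  threshold: float = 0.9) -> np.ndarray:
    """Flag (never replace) entries whose anomaly score exceeds `threshold`."""
    scorer = scorer or robust_z_scorer
    scores = np.asarray(scorer(np.asarray(values, dtype=float)))
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scorer must return scores in [0, 1]")
    return scores > threshold
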