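"""Intervention action vocabulary and pairwise compatibility constraints.

An intervention plan is a finite sequence of discrete clinical actions
(medication changes, therapy adjustments, monitoring changes, consultations)
terminated by a reserved end-of-plan token.  Clinical feasibility rules are
encoded as a binary symmetric compatibility matrix C: C[i, j] = 0 declares
that actions i and j may not co-occur within one plan.  The end token is
compatible with everything so that decoding can always terminate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

END_TOKEN = "end_of_plan"

DEFAULT_ACTIONS = [
    "medication_dose_increase",
    "medication_dose_decrease",
    "medication_substitution",
    "therapy_intensity_increase",
    "therapy_intensity_decrease",
    "monitoring_frequency_increase",
    "monitoring_frequency_decrease",
    "specialist_consultation",
    "nutritional_support",
    "psychosocial_support",
    "caregiver_education",
    "discharge_planning",
]


@dataclass(frozen=True)
class ActionVocabulary:
    """Ordered action labels plus the reserved end-of-plan token (last)."""

    actions: tuple[str, ...] = tuple(DEFAULT_ACTIONS)

    def __post_init__(self):
        if len(self.actions) < 1:
            raise ValueError("vocabulary needs at least one action")
        if END_TOKEN in self.actions:
            raise ValueError(f"'{END_TOKEN}' is reserved")

    @property
    def tokens(self) -> tuple[str, ...]:
        return self.actions + (END_TOKEN,)

    @property
    def size(self) -> int:
        return len(self.actions) + 1

    @property
    def end_index(self) -> int:
        return len(self.actions)

    def index(self, token: str) -> int:
        return self.tokens.index(token)


@dataclass
class CompatibilityMatrix:
    """Binary symmetric matrix over the vocabulary; diagonal and end row = 1."""

    C: np.ndarray
    vocab: ActionVocabulary = field(default_factory=ActionVocabulary)

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=np.int8)
        n = self.vocab.size
        if self.C.shape != (n, n):
            raise ValueError(f"compatibility matrix must be {n}x{n}")
        if not np.array_equal(self.C, self.C.T):
            raise ValueError("compatibility matrix must be symmetric")
        if not set(np.unique(self.C)) <= {0, 1}:
            raise ValueError("compatibility entries must be binary")
        if not np.all(np.diag(self.C) == 1):
            raise ValueError("diagonal must be 1 (an action is self-compatible)")
        e = self.vocab.end_index
        if not (np.all(self.C[e, :] == 1) and np.all(self.C[:, e] == 1)):
            raise ValueError("end token must be compatible with every action")

    @classmethod
    def fully_compatible(cls, vocab: ActionVocabulary | None = None):
        vocab = vocab or ActionVocabulary()
        return cls(np.ones((vocab.size, vocab.size), dtype=np.int8), vocab)

    @classmethod
    def random_feasible(cls, rng: np.random.Generator,
                        vocab: ActionVocabulary | None = None,
                        incompat_rate: float = 0.25):
        """Random constraints over action pairs; end token stays universal,
        so every prefix always has a feasible continuation."""
        vocab = vocab or ActionVocabulary()
        n = vocab.size
        C = np.ones((n, n), dtype=np.int8)
        a = vocab.end_index  # actions are indices < a
        for i in range(a):
            for j in range(i + 1, a):
                if rng.random() < incompat_rate:
                    C[i, j] = C[j, i] = 0
        return cls(C, vocab)

    def feasible_mask(self, prefix: list[int]) -> np.ndarray:
        """Boolean mask of tokens compatible with every token in `prefix`."""
        mask = np.ones(self.vocab.size, dtype=bool)
        for s in prefix:
            mask &= self.C[s, :].astype(bool)
        return mask

    def plan_is_valid(self, tokens: list[int]) -> bool:
        for i, a in enumerate(tokens):
            for b in tokens[i + 1:]:
                if self.C[a, b] == 0:
                    return False
        return True

    # ------------------------------------------------------------------- io
    def to_json(self) -> str:
        return json.dumps({"actions": list(self.vocab.actions),
                           "C": self.C.tolist()})

    @classmethod
    def from_json(cls, s: str) -> "CompatibilityMatrix":
        d = json.loads(s)
        return cls(np.asarray(d["C"]), ActionVocabulary(tuple(d["actions"])))
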