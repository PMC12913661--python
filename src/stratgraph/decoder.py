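"""Constrained autoregressive intervention-plan decoder.

Plans factorize autoregressively, p(I | h, y) = prod_t p(i_t | i_<t, h, y),
with a single-layer gated recurrent cell over learned token embeddings
concatenated with the patient embedding h and risk distribution y.  Hard
feasibility constraints from a pairwise compatibility matrix C are applied
at every step by masked renormalization: tokens incompatible with *any*
token already in the plan receive probability exactly zero and the rest
renormalize.  The reserved end-of-plan token is compatible with everything,
so decoding always terminates; after ``max_len`` actions the feasible set
collapses to the end token alone, which makes the probabilities of all
feasible bounded-length sequences sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .actions import ActionVocabulary, CompatibilityMatrix
from .autodiff import Tensor, concat, log_softmax, softmax, tensor
from .nn import Linear, Module, glorot


@dataclass
class InterventionPlan:
    tokens: list[int]  # ends with the end-of-plan token
    step_logprobs: list[float]
    patient_id: int | None = None

    @property
    def total_logprob(self) -> float:
        return float(sum(self.step_logprobs))


class DecodingError(RuntimeError):
    pass


class InterventionDecoder(Module):
    """GRU-style cell conditioned on [token embedding + h + y]."""

    BOS = -1  # start-of-plan pseudo-token (its own learned embedding)

    def __init__(self, d_embed: int, d_hidden: int, d_patient: int,
                 n_classes: int, vocab: ActionVocabulary,
                 rng: np.random.Generator):
        self.vocab = vocab
        v = vocab.size
        d_in = d_embed + d_patient + n_classes
        self.token_emb = Tensor(rng.normal(scale=0.1, size=(v + 1, d_embed)),
                                requires_grad=True)  # last row: BOS
        self.w_z = glorot(rng, d_in + d_hidden, d_hidden)
        self.w_r = glorot(rng, d_in + d_hidden, d_hidden)
        self.w_h = glorot(rng, d_in + d_hidden, d_hidden)
        self.b_z = Tensor(np.zeros(d_hidden), requires_grad=True)
        self.b_r = Tensor(np.zeros(d_hidden), requires_grad=True)
        self.b_h = Tensor(np.zeros(d_hidden), requires_grad=True)
        self.out = Linear(d_hidden, v, rng)
        self.d_hidden = d_hidden

    def _cell(self, x: Tensor, state: Tensor) -> Tensor:
        xs = concat([x, state], axis=-1)
        z = (xs @ self.w_z + self.b_z).sigmoid()
        r = (xs @ self.w_r + self.b_r).sigmoid()
        cand = (concat([x, state * r], axis=-1) @ self.w_h + self.b_h).tanh()
        return (1.0 - z) * state + z * cand

    def init_state(self, batch: int) -> Tensor:
        return Tensor(np.zeros((batch, self.d_hidden)))

    def step(self, prev_tokens: np.ndarray, state: Tensor, h: Tensor,
             y: Tensor) -> tuple[Tensor, Tensor]:
        """One decoder step; `prev_tokens` uses BOS index for plan starts.
        Returns (logits [B, V], new state)."""
        idx = np.where(np.asarray(prev_tokens) == self.BOS,
                       self.vocab.size, np.asarray(prev_tokens))
        emb = self.token_emb[idx]
        x = concat([emb, tensor(h), tensor(y)], axis=-1)
        state = self._cell(x, state)
        return self.out(state), state


def step_distribution(decoder: InterventionDecoder, prefix: list[int],
                      h: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Unconstrained next-token distribution after `prefix` (deterministic
    given parameters)."""
    h = np.asarray(h, float).reshape(1, -1)
    y = np.asarray(y, float).reshape(1, -1)
    state = decoder.init_state(1)
    logits = None
    tokens = [decoder.BOS] + list(prefix)
    for tok in tokens:
        logits, state = decoder.step(np.array([tok]), state, Tensor(h), Tensor(y))
    return softmax(logits, axis=-1).data[0]


def mask_renormalize(p: np.ndarray, prefix: list[int],
                     compat: CompatibilityMatrix) -> np.ndarray:
    """Zero out tokens incompatible with any prefix token; renormalize."""
    p = np.asarray(p, dtype=float)
    mask = compat.feasible_mask(list(prefix))
    masked = p * mask
    total = masked.sum()
    if total <= 0:
        raise DecodingError("no feasible token remains for this prefix")
    return masked / total


def _masked_step(decoder: InterventionDecoder, p: np.ndarray,
                 prefix: list[int], compat: CompatibilityMatrix,
                 n_actions_so_far: int, max_len: int) -> np.ndarray:
    """Compatibility mask plus the length rule: once `max_len` actions have
    been emitted only the end token stays feasible."""
    mask = compat.feasible_mask(list(prefix))
    if n_actions_so_far >= max_len:
        length_mask = np.zeros_like(mask)
        length_mask[decoder.vocab.end_index] = True
        mask = mask & length_mask
    masked = np.asarray(p, float) * mask
    total = masked.sum()
    if total <= 0:
        raise DecodingError("no feasible token remains for this prefix")
    return masked / total


def decode(decoder: InterventionDecoder, h: np.ndarray, y: np.ndarray,
           compat: CompatibilityMatrix, mode: str = "greedy",
           max_len: int = 8, seed: int = 0,
           patient_id: int | None = None) -> InterventionPlan:
    """Generate one plan; every emitted plan satisfies the compatibility
    matrix by construction and terminates with the end token."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if mode not in ("greedy", "sample"):
        raise ValueError("mode must be 'greedy' or 'sample'")
    rng = np.random.default_rng(seed)
    h = np.asarray(h, float).reshape(1, -1)
    y = np.asarray(y, float).reshape(1, -1)
    state = decoder.init_state(1)
    prev = np.array([decoder.BOS])
    tokens: list[int] = []
    logprobs: list[float] = []
    end = decoder.vocab.end_index
    while True:
        logits, state = decoder.step(prev, state, Tensor(h), Tensor(y))
        p = softmax(logits, axis=-1).data[0]
        n_actions = len(tokens)
        p = _masked_step(decoder, p, tokens, compat, n_actions, max_len)
        if mode == "greedy":
            tok = int(np.argmax(p))
        else:
            tok = int(rng.choice(len(p), p=p))
        tokens.append(tok)
        logprobs.append(float(np.log(p[tok])))
        if tok == end:
            break
        prev = np.array([tok])
    return InterventionPlan(tokens, logprobs, patient_id)


def sequence_logprob(decoder: InterventionDecoder, plan: list[int],
                     h: np.ndarray, y: np.ndarray,
                     compat: CompatibilityMatrix, max_len: int = 8) -> float:
    """Log probability of `plan` (which must end with the end token) under
    the masked-renormalized autoregressive factorization."""
    end = decoder.vocab.end_index
    if not plan or plan[-1] != end:
        raise ValueError("plan must terminate with the end token")
    body = [t for t in plan[:-1]]
    if end in body:
        raise ValueError("end token may only appear terminally")
    if not compat.plan_is_valid(body):
        raise DecodingError("constraint-violating plan has probability zero")
    h = np.asarray(h, float).reshape(1, -1)
    y = np.asarray(y, float).reshape(1, -1)
    state = decoder.init_state(1)
    prev = np.array([decoder.BOS])
    total = 0.0
    prefix: list[int] = []
    for tok in plan:
        logits, state = decoder.step(prev, state, Tensor(h), Tensor(y))
        p = softmax(logits, axis=-1).data[0]
        p = _masked_step(decoder, p, prefix, compat, len(prefix), max_len)
        if p[tok] <= 0:
            raise DecodingError("plan step infeasible under constraints")
        total += float(np.log(p[tok]))
        prefix.append(tok)
        prev = np.array([tok])
    return total


def batch_teacher_forcing_nll(decoder: InterventionDecoder,
                              targets: list[list[int]],
                              h: Tensor, y: Tensor) -> Tensor:
    """Differentiable mean negative log-likelihood of target plans
    (teacher forcing, unconstrained softmax — constraints only shape
    inference-time decoding)."""
    n = len(targets)
    max_t = max(len(t) for t in targets)
    state = decoder.init_state(n)
    prev = np.full(n, decoder.BOS)
    loss = None
    count = 0
    for step in range(max_t):
        logits, state = decoder.step(prev, state, h, y)
        logp = log_softmax(logits, axis=-1)
        active = np.array([step < len(t) for t in targets])
        tok = np.array([t[step] if step < len(t) else 0 for t in targets])
        picked = logp[np.arange(n), tok] * Tensor(active.astype(float))
        term = -picked.sum()
        loss = term if loss is None else loss + term
        count += int(active.sum())
        prev = tok
    return loss * (1.0 / max(count, 1))


def constraint_satisfaction_rate(plans: list[InterventionPlan | list[int]],
                                 compat: CompatibilityMatrix) -> float:
    """Fraction of plans whose every unordered token pair is compatible.
    An empty set is defined as 1.0 (with a warning)."""
    if len(plans) == 0:
        import warnings

        warnings.warn("empty plan set: satisfaction rate defined as 1.0",
                      stacklevel=2)
        return 1.0
    ok = 0
    for plan in plans:
        tokens = plan.tokens if isinstance(plan, InterventionPlan) else plan
        body = [t for t in tokens if t != compat.vocab.end_index]
        ok += compat.plan_is_valid(body)
    return ok / len(plans)
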