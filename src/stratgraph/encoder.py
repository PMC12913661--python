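"""Spatiotemporal graph-attention encoder.

Multimodal sequences become patient embeddings through a fixed three-level
stack:

1. modality-specific two-layer perceptron encoders project each stream to a
   shared hidden dimension; unobserved steps receive a learned missing
   embedding; streams fuse through softmax-parameterized modality weights
   ``alpha_m``;
2. level 1 — three gated graph-convolution layers propagate information over
   the patient-similarity graph at every time step (sigmoid gate times tanh
   content stream, symmetric degree normalization with self-loops);
3. level 2 — temporal self-attention with an additive relative-position bias
   ``phi(t - t')`` (a learnable scalar per signed lag) aggregates each
   patient's trajectory;
4. level 3 — multi-head cross-modal attention lets each modality stream
   attend to every other, with residual connections preserving
   modality-specific information;
5. a hierarchical skip merge pools the local stream over time and adds an
   affine transform of the final graph-level states.

Graph structure is treated as a constant (no gradients through adjacency
construction).  All attention rows are valid probability distributions with
masked positions exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, dropout, softmax, tensor
from .graph import PatientGraph, convolution_operator
from .nn import MLP, Linear, Module, dense, glorot


@dataclass(frozen=True)
class EncoderConfig:
    hidden_dim: int = 256
    graph_layers: int = 3
    attention_heads: int = 8
    temporal_window: int = 12
    dropout: float = 0.3

    def __post_init__(self):
        if self.hidden_dim % self.attention_heads != 0:
            raise ValueError("hidden_dim must be divisible by attention_heads")

    @property
    def key_dim(self) -> int:
        return self.hidden_dim // self.attention_heads


@dataclass
class EncoderOutput:
    h_global: Tensor  # [N, d] fused patient embeddings
    fused: Tensor  # [N, T, d] post-fusion stream
    layer_states: list  # graph-level hidden states H^(l)
    temporal_beta: np.ndarray | None  # [N, T, T]
    fusion_alphas: np.ndarray  # [M]
    cross_attention: dict  # (m, n) -> [N, T, T] head-averaged maps


class FusionWeights(Module):
    """Softmax-parameterized modality weights alpha_m (sum to 1)."""

    def __init__(self, n_modalities: int):
        if n_modalities < 1:
            raise ValueError("need at least one modality")
        self.logits = Tensor(np.zeros(n_modalities), requires_grad=True)

    def alphas(self) -> Tensor:
        return softmax(self.logits, axis=-1)


def fuse_modalities(encodings: list[Tensor], weights: FusionWeights) -> Tensor:
    """h = sum_m alpha_m * g_m(x^(m))."""
    if len(encodings) == 0:
        raise ValueError("no modality encodings to fuse")
    if len(encodings) != weights.logits.shape[0]:
        raise ValueError("encodings and fusion weights disagree on M")
    alphas = weights.alphas()
    out = None
    for m, enc in enumerate(encodings):
        term = tensor(enc) * alphas[m]
        out = term if out is None else out + term
    return out


class ModalityEncoder(Module):
    """Two-layer perceptron g_m mapping raw features to R^d, with a learned
    missing-step embedding substituted where the observation mask is 0."""

    def __init__(self, d_in: int, d: int, rng: np.random.Generator):
        self.d_in = d_in
        self.mlp = MLP(d_in, d, d, rng)
        self.missing = Tensor(rng.normal(scale=0.1, size=d), requires_grad=True)

    def __call__(self, x, mask: np.ndarray | None = None) -> Tensor:
        if not isinstance(x, Tensor):  # pre-wrapped inputs skip the NaN scrub
            x = Tensor(np.nan_to_num(np.asarray(x, dtype=float)))
        if x.shape[-1] != self.d_in:
            raise ValueError(f"expected feature dim {self.d_in}, got {x.shape[-1]}")
        enc = self.mlp(x)
        if mask is None:
            return enc
        m = np.asarray(mask, dtype=float)[..., None]
        return enc * Tensor(m) + self.missing * Tensor(1.0 - m)


def gcn_layer(h, graph: PatientGraph, w, activation: str = "relu") -> Tensor:
    """First-order propagation sigma(D~^{-1/2} (A + I) D~^{-1/2} H W)."""
    p = convolution_operator(graph)
    out = dense(h, w).graph_prop(p)
    if activation == "relu":
        return out.relu()
    if activation == "linear":
        return out
    raise ValueError(f"unknown activation '{activation}'")


def gated_graph_layer(h, graph: PatientGraph, w, u, b) -> Tensor:
    """Gated aggregation: sigmoid(P H W + b) * tanh(P H U), with the
    neighbourhood including the node itself (self-loop convention).  Every
    output entry lies strictly inside (-1, 1)."""
    p = convolution_operator(graph)
    h = tensor(h)
    gate = (dense(h, w).graph_prop(p) + tensor(b)).sigmoid()
    content = dense(h, u).graph_prop(p).tanh()
    return gate * content


def relative_position_index(t: int) -> np.ndarray:
    """idx[t, t'] into a (2T-1)-entry bias table, lag clipped at |T-1|."""
    lags = np.arange(t)[:, None] - np.arange(t)[None, :]
    return lags + t - 1


def temporal_attention(h_seq, w_q, w_k, w_v, bias_table,
                       step_mask: np.ndarray | None = None
                       ) -> tuple[Tensor, Tensor]:
    """Position-aware temporal self-attention.

    ``h_seq`` is [T, d] or batched [N, T, d]; ``bias_table`` holds one scalar
    per signed lag (length 2T-1).  Masked (unobserved) steps are excluded
    from the softmax as keys; rows sum to 1 over unmasked positions.
    Returns (beta, aggregated states).
    """
    h = tensor(h_seq)
    squeeze = h.ndim == 2
    if squeeze:
        h = h.reshape(1, *h.shape)
    n, t, d = h.shape
    if step_mask is not None:
        step_mask = np.asarray(step_mask, dtype=bool).reshape(n, t)
        if not step_mask.any(axis=1).all():
            raise ValueError("a patient has no observed steps")
    q = dense(h, w_q)
    k = dense(h, w_k)
    scores = (q @ k.T) * (1.0 / np.sqrt(d))
    idx = relative_position_index(t)
    scores = scores + tensor(bias_table)[idx]
    key_mask = None if step_mask is None else step_mask[:, None, :]
    beta = softmax(scores, axis=-1, mask=key_mask)
    out = beta @ dense(h, w_v)
    if squeeze:
        return beta.reshape(t, t), out.reshape(t, d)
    return beta, out


class MultiHeadAttention(Module):
    """Scaled dot-product attention in h parallel subspaces, concatenated
    and projected by W^O."""

    def __init__(self, d: int, heads: int, rng: np.random.Generator):
        if d % heads != 0:
            raise ValueError("dimension must be divisible by head count")
        self.d, self.heads, self.dk = d, heads, d // heads
        self.w_q = glorot(rng, d, d)
        self.w_k = glorot(rng, d, d)
        self.w_v = glorot(rng, d, d)
        self.w_o = glorot(rng, d, d)

    def _split(self, x: Tensor) -> Tensor:
        b, t, _ = x.shape
        return x.reshape(b, t, self.heads, self.dk).swapaxes(1, 2)

    def project_q(self, x) -> Tensor:
        return self._split(dense(tensor(x), self.w_q))

    def project_kv(self, x) -> tuple[Tensor, Tensor]:
        x = tensor(x)
        return self._split(dense(x, self.w_k)), self._split(dense(x, self.w_v))

    def core(self, q: Tensor, k: Tensor, v: Tensor,
             key_mask: np.ndarray | None = None,
             return_weights: bool = False):
        """Attention on pre-split [b, h, t, dk] projections."""
        b, _, tq, _ = q.shape
        scores = (q @ k.T) * (1.0 / np.sqrt(self.dk))  # [b, h, tq, tk]
        mask = None if key_mask is None else key_mask[:, None, None, :]
        attn = softmax(scores, axis=-1, mask=mask)
        out = dense((attn @ v).swapaxes(1, 2).reshape(b, tq, self.d), self.w_o)
        if return_weights:
            return out, attn.data.mean(axis=1)  # head-averaged maps
        return out

    def __call__(self, q_in, k_in, v_in, key_mask: np.ndarray | None = None,
                 return_weights: bool = False):
        q = self.project_q(q_in)
        k, v = self.project_kv(tensor(k_in)) if k_in is v_in else (
            self._split(dense(tensor(k_in), self.w_k)),
            self._split(dense(tensor(v_in), self.w_v)))
        return self.core(q, k, v, key_mask, return_weights)


class CrossModalAttention(Module):
    """Modality m attends to modality n; the residual connection preserves
    the m-stream."""

    def __init__(self, d: int, heads: int, rng: np.random.Generator):
        self.mha = MultiHeadAttention(d, heads, rng)

    def __call__(self, x_m, x_n, key_mask=None, return_weights=False):
        if return_weights:
            out, w = self.mha(x_m, x_n, x_n, key_mask, return_weights=True)
            return tensor(x_m) + out, w
        return tensor(x_m) + self.mha(x_m, x_n, x_n, key_mask)


def hierarchical_merge(h_local, h_final_layer, transform: Linear) -> Tensor:
    """H_global = Pool(H_local) + Transform(H^(L)); Pool = temporal mean."""
    return tensor(h_local).mean(axis=1) + transform(tensor(h_final_layer))


class Encoder(Module):
    """The full three-level stack.  Ablation switches disable individual
    pathways (the disabled level becomes the identity)."""

    def __init__(self, modality_dims: dict[str, int], config: EncoderConfig,
                 rng: np.random.Generator,
                 use_graph: bool = True, use_temporal: bool = True,
                 use_cross_modal: bool = True):
        if not (use_graph or use_temporal or use_cross_modal):
            raise ValueError("at least one encoder pathway must stay enabled")
        d = config.hidden_dim
        self.config = config
        self.use_graph, self.use_temporal = use_graph, use_temporal
        self.use_cross_modal = use_cross_modal
        self.modality_names = list(modality_dims)
        self.encoders = {name: ModalityEncoder(dim, d, rng)
                         for name, dim in modality_dims.items()}
        self.fusion = FusionWeights(len(modality_dims))
        self.gw = [glorot(rng, d, d) for _ in range(config.graph_layers)]
        self.gu = [glorot(rng, d, d) for _ in range(config.graph_layers)]
        self.gb = [Tensor(np.zeros(d), requires_grad=True)
                   for _ in range(config.graph_layers)]
        self.w_q = glorot(rng, d, d)
        self.w_k = glorot(rng, d, d)
        self.w_v = glorot(rng, d, d)
        self.rel_bias = Tensor(np.zeros(2 * config.temporal_window - 1),
                               requires_grad=True)
        self.cross = CrossModalAttention(d, config.attention_heads, rng)
        self.transform = Linear(d, d, rng)

    def forward(self, features: dict[str, np.ndarray],
                masks: dict[str, np.ndarray],
                graph: PatientGraph | None,
                training: bool = False,
                rng: np.random.Generator | None = None,
                collect_attention: bool = False) -> EncoderOutput:
        cfg = self.config
        rng = rng or np.random.default_rng(0)
        names = [n for n in self.modality_names if n in features]
        if not names:
            raise ValueError("no modality streams supplied")
        streams = {n: self.encoders[n](features[n], masks.get(n))
                   for n in names}
        alphas = softmax(Tensor(self.fusion.logits.data[
            [self.modality_names.index(n) for n in names]],
            requires_grad=False), axis=-1) if len(names) != len(
            self.modality_names) else self.fusion.alphas()
        # re-index fusion weights when a modality subset is selected
        if len(names) == len(self.modality_names):
            fused = fuse_modalities([streams[n] for n in names], self.fusion)
        else:
            fused = None
            for m, n in enumerate(names):
                term = streams[n] * alphas[m]
                fused = term if fused is None else fused + term
        h = fused  # [N, T, d]

        layer_states = [h]
        if self.use_graph and graph is not None:
            for w, u, b in zip(self.gw, self.gu, self.gb):
                h = gated_graph_layer(h, graph, w, u, b)
                layer_states.append(h)
            h = dropout(h, cfg.dropout, rng, training)
        h_graph = h

        step_mask = np.zeros(next(iter(masks.values())).shape, dtype=bool)
        for n in names:
            step_mask |= np.asarray(masks[n], dtype=bool)
        beta_np = None
        if self.use_temporal:
            beta, h = temporal_attention(h, self.w_q, self.w_k, self.w_v,
                                         self.rel_bias, step_mask)
            h = dropout(h, cfg.dropout, rng, training)
            beta_np = beta.data if collect_attention else None

        cross_maps: dict = {}
        if self.use_cross_modal and len(names) > 1:
            mha = self.cross.mha
            q_proj = {n: mha.project_q(streams[n]) for n in names}
            kv_proj = {n: mha.project_kv(streams[n]) for n in names}
            enriched = []
            for m in names:
                acc = None
                for n in names:
                    if n == m:
                        continue
                    k, v = kv_proj[n]
                    if collect_attention:
                        out, w = mha.core(q_proj[m], k, v,
                                          np.asarray(masks[n], bool),
                                          return_weights=True)
                        cross_maps[(m, n)] = w
                    else:
                        out = mha.core(q_proj[m], k, v,
                                       np.asarray(masks[n], bool))
                    out = streams[m] + out  # residual preserves the m-stream
                    acc = out if acc is None else acc + out
                enriched.append(acc * (1.0 / (len(names) - 1)))
            x_cm = None
            for m, e in enumerate(enriched):
                term = e * alphas[m]
                x_cm = term if x_cm is None else x_cm + term
            h = h + dropout(x_cm, cfg.dropout, rng, training)

        h_global = hierarchical_merge(h, h_graph.mean(axis=1), self.transform)
        return EncoderOutput(h_global=h_global, fused=fused,
                             layer_states=layer_states,
                             temporal_beta=beta_np,
                             fusion_alphas=alphas.data.copy(),
                             cross_attention=cross_maps)
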