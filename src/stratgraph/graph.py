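"""Patient-relationship graph construction and spectral utilities.

Edges connect clinically similar patients.  A composite similarity
``phi(i, j) = sum_d omega_d * cos(x_i^(d), x_j^(d))`` over feature domains
gates a Gaussian kernel of embedding distance:

    w_ij = exp(-||h_i - h_j||^2 / (2 sigma^2)) * 1[phi(i, j) > tau]

with an additional weight floor ``eps_w``: kernel weights below the floor
are dropped, so the bandwidth ``sigma`` also influences graph density (a
small sigma shrinks far-pair weights under the floor).  Construction is
brute-force over all pairs and non-differentiable; training treats the
adjacency as a constant between scheduled updates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SimilarityConfig:
    """Domain weights and the feature-group selectors they apply to."""

    domain_weights: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    domains: tuple[str, ...] = ("diagnosis", "laboratory", "medication",
                                "functional")

    def __post_init__(self):
        w = np.asarray(self.domain_weights, dtype=float)
        if len(w) == 0 or len(w) != len(self.domains):
            raise ValueError("domain_weights and domains must align, nonempty")
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("domain weights must be nonnegative and sum to 1")


@dataclass(frozen=True)
class GraphParams:
    sigma: float = 2.0  # kernel bandwidth
    tau: float = 0.3  # composite-similarity sparsification threshold
    weight_floor: float = 0.01  # kernel weights below this are dropped
    add_self_loops: bool = False  # self-loops live in the convolution, not here

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must lie in [0, 1]")
        if self.weight_floor < 0:
            raise ValueError("weight_floor must be nonnegative")


@dataclass
class PatientGraph:
    weights: np.ndarray  # symmetric [N, N], zero diagonal, entries in [0, 1]
    params: GraphParams

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    @property
    def density(self) -> float:
        n = self.n
        if n < 2:
            return 0.0
        connected = np.count_nonzero(np.triu(self.weights, k=1))
        return connected / (n * (n - 1) / 2)


def domain_similarity(x_i: np.ndarray, x_j: np.ndarray) -> float:
    """Cosine similarity within one feature domain; zero vectors score 0."""
    x_i = np.asarray(x_i, dtype=float).ravel()
    x_j = np.asarray(x_j, dtype=float).ravel()
    if x_i.shape != x_j.shape:
        raise ValueError("domain vectors must share a dimension")
    ni, nj = np.linalg.norm(x_i), np.linalg.norm(x_j)
    if ni == 0 or nj == 0:
        return 0.0
    return float(np.clip(x_i @ x_j / (ni * nj), -1.0, 1.0))


def composite_similarity(patient_i: dict[str, np.ndarray],
                         patient_j: dict[str, np.ndarray],
                         config: SimilarityConfig) -> float:
    """phi(i, j): domain-weighted sum of per-domain cosines, in [-1, 1]."""
    return float(sum(
        w * domain_similarity(patient_i[d], patient_j[d])
        for w, d in zip(config.domain_weights, config.domains)))


def edge_weight(h_i: np.ndarray, h_j: np.ndarray, phi_ij: float,
                params: GraphParams) -> float:
    """Gaussian kernel of embedding distance, gated by 1[phi > tau] and the
    weight floor."""
    h_i = np.asarray(h_i, dtype=float)
    h_j = np.asarray(h_j, dtype=float)
    if h_i.shape != h_j.shape:
        raise ValueError("embeddings must share a dimension")
    if phi_ij <= params.tau:
        return 0.0
    w = float(np.exp(-np.sum((h_i - h_j) ** 2) / (2.0 * params.sigma**2)))
    return w if w >= params.weight_floor else 0.0


def _cosine_matrix(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    c = (x / safe[:, None]) @ (x / safe[:, None]).T
    c[norms == 0, :] = 0.0
    c[:, norms == 0] = 0.0
    return np.clip(c, -1.0, 1.0)


def composite_similarity_matrix(domain_features: dict[str, np.ndarray],
                                config: SimilarityConfig) -> np.ndarray:
    """All-pairs phi; each domain contributes an [N, N] cosine matrix."""
    if not config.domains:
        raise ValueError("empty domain list")
    phi = None
    for w, d in zip(config.domain_weights, config.domains):
        c = w * _cosine_matrix(np.asarray(domain_features[d], dtype=float))
        phi = c if phi is None else phi + c
    return phi


def build_graph(embeddings: np.ndarray,
                domain_features: dict[str, np.ndarray],
                sim_config: SimilarityConfig,
                params: GraphParams) -> PatientGraph:
    """Evaluate all N(N-1)/2 pairs (vectorized brute force)."""
    h = np.asarray(embeddings, dtype=float)
    n = h.shape[0]
    if n < 2:
        raise ValueError("need at least two patients")
    phi = composite_similarity_matrix(domain_features, sim_config)
    sq = np.sum(h**2, axis=1)
    dist2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (h @ h.T), 0.0)
    w = np.exp(-dist2 / (2.0 * params.sigma**2))
    w = w * (phi > params.tau)
    w[w < params.weight_floor] = 0.0
    np.fill_diagonal(w, 0.0)
    w = np.minimum(w, w.T)  # enforce exact symmetry against float noise
    return PatientGraph(weights=w, params=params)


def update_graph(h_t: np.ndarray,
                 domain_features: dict[str, np.ndarray],
                 sim_config: SimilarityConfig,
                 params: GraphParams) -> PatientGraph:
    """Recompute the adjacency from current (time-t) embeddings.  Same
    contract as :func:`build_graph`; no gradients flow through it."""
    return build_graph(h_t, domain_features, sim_config, params)


def normalized_laplacian(a: np.ndarray) -> np.ndarray:
    """L = I - D^{-1/2} A D^{-1/2}; isolated nodes use the D^{-1/2} = 0
    convention, so their Laplacian row is the identity row.  Eigenvalues of
    the result lie in [0, 2]."""
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if (a < 0).any():
        raise ValueError("adjacency must be nonnegative")
    deg = a.sum(axis=1)
    inv_sqrt = np.zeros_like(deg)
    np.divide(1.0, np.sqrt(deg), out=inv_sqrt, where=deg > 0)
    lap = np.eye(a.shape[0]) - inv_sqrt[:, None] * a * inv_sqrt[None, :]
    return (lap + lap.T) / 2.0


def convolution_operator(graph: PatientGraph) -> np.ndarray:
    """Symmetric-normalized propagation operator with self-loops,
    D~^{-1/2} (A + I) D~^{-1/2} — the constant matrix used by graph layers."""
    a = graph.weights + np.eye(graph.n)
    deg = a.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(deg)
    return inv_sqrt[:, None] * a * inv_sqrt[None, :]


# ------------------------------------------------------------------- io

def write_graph(graph: PatientGraph, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    i, j = np.nonzero(np.triu(graph.weights, k=1))
    pd.DataFrame({"i": i, "j": j, "w": graph.weights[i, j]}).to_csv(
        outdir / "edges.tsv", sep="\t", index=False)
    with open(outdir / "graph_params.json", "w") as fh:
        json.dump({"sigma": graph.params.sigma, "tau": graph.params.tau,
                   "weight_floor": graph.params.weight_floor,
                   "add_self_loops": graph.params.add_self_loops,
                   "n": graph.n, "density": graph.density}, fh, indent=2)


def read_graph(indir: str | Path) -> PatientGraph:
    indir = Path(indir)
    with open(indir / "graph_params.json") as fh:
        meta = json.load(fh)
    params = GraphParams(meta["sigma"], meta["tau"], meta["weight_floor"],
                         meta["add_self_loops"])
    w = np.zeros((meta["n"], meta["n"]))
    edges = pd.read_csv(indir / "edges.tsv", sep="\t")
    w[edges["i"], edges["j"]] = edges["w"]
    w = w + w.T
    return PatientGraph(weights=w, params=params)
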