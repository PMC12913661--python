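"""Neural building blocks (linear maps, MLPs, batch-style normalization,
AdamW) shared by the encoder, risk head and intervention decoder."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, tensor


def dense(x, w) -> Tensor:
    """x @ w with leading axes flattened into one GEMM (same result as the
    batched product, markedly faster for [N, T, F] inputs)."""
    x, w = tensor(x), tensor(w)
    if x.ndim <= 2:
        return x @ w
    lead = x.shape[:-1]
    out = x.reshape(-1, x.shape[-1]) @ w
    return out.reshape(*lead, w.shape[-1])


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Module:
    """Tiny parameter container; subclasses register Tensors / sub-modules."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
                    elif isinstance(item, Module):
                        params.extend(item.parameters())
            elif isinstance(v, dict):
                for item in v.values():
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias=True):
        self.W = glorot(rng, d_in, d_out)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = dense(x, self.W)
        return out + self.b if self.b is not None else out


class MLP(Module):
    """Two-layer perceptron with ReLU hidden activation."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int, rng):
        self.fc1 = Linear(d_in, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class BatchNorm(Module):
    """Batch normalization over the leading axis with running statistics.

    In evaluation (and Monte Carlo dropout) mode the stored running mean and
    variance are used as constants; only dropout stays stochastic downstream.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training and x.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data[0]
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data[0]
            )
            xhat = (x - mu) / (var + self.eps) ** 0.5
        else:
            xhat = (x - Tensor(self.running_mean)) / Tensor(
                np.sqrt(self.running_var + self.eps)
            )
        return xhat * self.gamma + self.beta


class AdamW:
    """Adaptive-moment gradient descent with decoupled weight decay."""

    def __init__(self, params: list[Tensor], lr=1e-4, betas=(0.9, 0.999),
                 eps=1e-8, weight_decay=0.0):
        self.params = params
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)
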