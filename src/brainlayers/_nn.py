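"""Minimal feedforward neural-network machinery on NumPy.

Implements exactly the pieces the domain-adversarial classifier needs —
fully connected layers, batch normalization, ReLU, inverted dropout, sigmoid,
a gradient-reversal layer and the adam optimizer — with explicit, seeded
randomness.  Every stochastic choice (initialization, dropout masks) is drawn
from a generator the caller passes in, so training runs are bit-reproducible.

Gradients accumulate into ``Param.grad`` so one optimizer step can combine
the label-path and domain-path backward passes of adversarial training.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Linear",
    "BatchNorm1d",
    "ReLU",
    "Dropout",
    "Sigmoid",
    "Stack",
    "GradientReversal",
    "Adam",
]


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray) -> None:
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class Linear:
    """Affine map with He-normal weight initialization."""

    def __init__(self, fan_in: int, fan_out: int, rng: np.random.Generator) -> None:
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
        self.b = Param(np.zeros(fan_out))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x, *, train, rng, update_stats):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class BatchNorm1d:
    """Batch normalization with learned scale/shift and running statistics.

    Training mode normalizes with batch statistics; ``update_stats`` controls
    whether the running exponential moving averages advance (the adversarial
    trainer updates them on the labeled pass only, so the extractor's
    evaluation behaviour is independent of the domain pass).
    """

    def __init__(self, width: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = Param(np.ones(width))
        self.beta = Param(np.zeros(width))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(width)
        self.running_var = np.ones(width)
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x, *, train, rng, update_stats):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            if update_stats:
                self.running_mean = (
                    (1 - self.momentum) * self.running_mean + self.momentum * mu
                )
                self.running_var = (
                    (1 - self.momentum) * self.running_var + self.momentum * var
                )
        else:
            mu, var = self.running_mean, self.running_var
        inv_sd = 1.0 / np.sqrt(var + self.eps)
        x_hat = (x - mu) * inv_sd
        self._cache = (x_hat, inv_sd, train, x.shape[0])
        return self.gamma.value * x_hat + self.beta.value

    def backward(self, grad):
        x_hat, inv_sd, train, n = self._cache
        self.gamma.grad += (grad * x_hat).sum(axis=0)
        self.beta.grad += grad.sum(axis=0)
        g = grad * self.gamma.value
        if not train:
            return g * inv_sd
        return (
            inv_sd / n * (n * g - g.sum(axis=0) - x_hat * (g * x_hat).sum(axis=0))
        )


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x, *, train, rng, update_stats):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout:
    """Inverted dropout; the mask comes from the caller's generator stream."""

    def __init__(self, p: float) -> None:
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self._mask: np.ndarray | float = 1.0

    def params(self) -> list[Param]:
        return []

    def forward(self, x, *, train, rng, update_stats):
        if not train or self.p == 0.0:
            self._mask = 1.0
            return x
        keep = 1.0 - self.p
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Sigmoid:
    def __init__(self) -> None:
        self._out: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x, *, train, rng, update_stats):
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._out = out
        return out

    def backward(self, grad):
        return grad * self._out * (1.0 - self._out)


class GradientReversal:
    """Identity forward; multiplies the backward sensitivity by −λ."""

    def __init__(self, lambda_grl: float) -> None:
        if lambda_grl < 0.0:
            raise ValueError("lambda_grl must be nonnegative")
        self.lambda_grl = lambda_grl

    def params(self) -> list[Param]:
        return []

    def forward(self, x, *, train=True, rng=None, update_stats=True):
        return x

    def backward(self, grad):
        return -self.lambda_grl * grad


class Stack:
    """A plain sequential container."""

    def __init__(self, layers: list) -> None:
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, *, train, rng=None, update_stats=True):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng, update_stats=update_stats)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """adam with the standard bias-corrected first/second moment estimates."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 0.001,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        for k, p in enumerate(self.params):
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad**2
            m_hat = self.m[k] / (1 - self.b1**self.t)
            v_hat = self.v[k] / (1 - self.b2**self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
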