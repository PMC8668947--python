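"""Minimal feed-forward / recurrent building blocks with reverse-mode gradients.

All models in this package (GAN generator/discriminator, the 1-D CNN, the MLP
and the LSTM classifier) are small enough that plain NumPy with hand-written
backward passes is fast on one CPU and keeps training bit-reproducible under
a seeded ``numpy.random.Generator``. Parameters are flat lists of
``Param`` objects updated by a shared Adam optimizer.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-7  # probability clamp for log terms


class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)


class Adam:
    """Adam with the standard beta/epsilon constants."""

    def __init__(self, params: list[Param], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p in self.params:
            p.m = b1 * p.m + (1 - b1) * p.grad
            p.v = b2 * p.v + (1 - b2) * p.grad**2
            mhat = p.m / (1 - b1**self.t)
            vhat = p.v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He-style init; works for both ReLU and leaky-ReLU stacks
        scale = np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0.0, scale, (n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class BatchNorm(Layer):
    """Batch normalization over the sample axis with running statistics.

    Training uses batch statistics and updates exponential running averages;
    inference (``train=False``) uses the running averages, so sampling from a
    trained generator is deterministic.
    """

    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(n))
        self.beta = Param(np.zeros(n))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._train = train
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, grad):
        self.gamma.grad += (grad * self._xhat).sum(axis=0)
        self.beta.grad += grad.sum(axis=0)
        gx = grad * self.gamma.value
        if not self._train:
            return gx / self._std
        n = grad.shape[0]
        # standard batch-norm backward through batch mean/var
        return (gx - gx.mean(axis=0) - self._xhat * (gx * self._xhat).mean(axis=0)) / self._std


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.alpha * grad)


class Sigmoid(Layer):
    def forward(self, x, train):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def minibatches(n: int, batch_size: int, rng: np.random.Generator):
    """Yield shuffled index batches covering all n samples."""
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]
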