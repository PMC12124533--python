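"""Minimal neural-network kernel (numpy, float64, manual backprop).

Just enough machinery for the domain-adversarial classifier: 3x3
convolutions, ReLU, 2x2 average pooling, dense layers, softmax
cross-entropy, and Adam.  Everything is deterministic given the
``numpy.random.Generator`` used for initialization and batching, and
gradients are exact (they are verified against finite differences in the
test suite), which is what makes the gradient-reversal contract checkable.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv3x3",
    "ReLU",
    "AvgPool2",
    "Flatten",
    "Dense",
    "Sequential",
    "softmax_cross_entropy",
    "Adam",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero padding 1 (NCHW layout)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.W = Param(rng.normal(0.0, scale, (c_out, c_in, 3, 3)))
        self.b = Param(np.zeros(c_out))
        self._xpad: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xpad = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        self._xpad = xpad
        out = np.zeros((n, self.W.value.shape[0], h, w))
        for di in range(3):
            for dj in range(3):
                patch = xpad[:, :, di : di + h, dj : dj + w]
                out += np.einsum("nchw,oc->nohw", patch, self.W.value[:, :, di, dj],
                                 optimize=True)
        return out + self.b.value[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xpad = self._xpad
        n, _, hp, wp = xpad.shape
        h, w = hp - 2, wp - 2
        self.b.grad += grad.sum(axis=(0, 2, 3))
        gx_pad = np.zeros_like(xpad)
        for di in range(3):
            for dj in range(3):
                patch = xpad[:, :, di : di + h, dj : dj + w]
                self.W.grad[:, :, di, dj] += np.einsum(
                    "nohw,nchw->oc", grad, patch, optimize=True
                )
                gx_pad[:, :, di : di + h, dj : dj + w] += np.einsum(
                    "nohw,oc->nchw", grad, self.W.value[:, :, di, dj], optimize=True
                )
        return gx_pad[:, :, 1:-1, 1:-1]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Tanh(Layer):
    """Bounded activation; used on the latent layer so adversarial pressure
    cannot inflate feature magnitudes without limit."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * (1.0 - self._y**2)


class AvgPool2(Layer):
    """2x2 average pooling, stride 2."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        g = np.repeat(np.repeat(grad, 2, axis=2), 2, axis=3) / 4.0
        return g


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class BatchNorm1d(Layer):
    """Batch normalization over feature vectors with learnable affine.

    Forces nonzero per-dimension variance in the latent space, which rules
    out the degenerate 'constant features' solution of adversarial
    training.  Uses batch statistics while ``training`` and running
    averages at inference.
    """

    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(n))
        self.beta = Param(np.zeros(n))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.training = True

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, std = self._xhat, self._std
        n = grad.shape[0]
        self.gamma.grad += (grad * xhat).sum(axis=0)
        self.beta.grad += grad.sum(axis=0)
        g = grad * self.gamma.value
        if not self.training:
            return g / std
        return (g - g.mean(axis=0) - xhat * (g * xhat).mean(axis=0)) / std


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def set_training(self, flag: bool) -> None:
        for layer in self.layers:
            if hasattr(layer, "training"):
                layer.training = flag
            if isinstance(layer, Sequential):
                layer.set_training(flag)


def softmax_cross_entropy(
    logits: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of integer labels and its gradient wrt logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    expz = np.exp(z)
    probs = expz / expz.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.mean(np.log(probs[np.arange(n), y] + 1e-300)))
    grad = probs.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    """Adam with optional global gradient-norm clipping and weight decay."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 clip_norm: float | None = None, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        if self.clip_norm is not None:
            total = np.sqrt(sum(float(np.sum(p.grad**2)) for p in self.params))
            if total > self.clip_norm:
                scale = self.clip_norm / total
                for p in self.params:
                    p.grad *= scale
        if self.weight_decay:
            for p in self.params:
                p.grad += self.weight_decay * p.value
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
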