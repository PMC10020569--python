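"""Minimal numpy neural-net kernel: dense/conv1d layers, ReLU, Adam.

Layers are functional: ``forward`` returns ``(output, cache)`` and
``backward`` consumes that cache, so the same layer object can be applied to
several inputs in one step (required for the weight-shared Siamese branches,
where gradients from both branches accumulate into one parameter set).
Parameter gradients accumulate until :meth:`Sequential.zero_grad`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "Conv1d", "ReLU", "Flatten", "Sequential", "Adam"]


def _he_init(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = _he_init(rng, n_in, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x):
        return x @ self.W + self.b, x

    def backward(self, dy, cache):
        x = cache
        self.gW += x.T @ dy
        self.gb += dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def zero_grad(self):
        self.gW[:] = 0.0
        self.gb[:] = 0.0


class Conv1d:
    """1-D convolution, stride 1, no padding.  Input (n, ch_in, L)."""

    def __init__(self, ch_in: int, ch_out: int, kernel: int, rng: np.random.Generator):
        self.k = kernel
        self.W = _he_init(rng, ch_in * kernel, (ch_out, ch_in, kernel))
        self.b = np.zeros(ch_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x):
        n, ci, L = x.shape
        Lo = L - self.k + 1
        y = np.zeros((n, self.W.shape[0], Lo))
        for j in range(self.k):
            # y[n,o,l] += sum_c W[o,c,j] * x[n,c,l+j]
            y += np.einsum("oc,ncl->nol", self.W[:, :, j], x[:, :, j : j + Lo])
        y += self.b[None, :, None]
        return y, x

    def backward(self, dy, cache):
        x = cache
        n, ci, L = x.shape
        Lo = dy.shape[2]
        dx = np.zeros_like(x)
        for j in range(self.k):
            self.gW[:, :, j] += np.einsum("nol,ncl->oc", dy, x[:, :, j : j + Lo])
            dx[:, :, j : j + Lo] += np.einsum("oc,nol->ncl", self.W[:, :, j], dy)
        self.gb += dy.sum(axis=(0, 2))
        return dx

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def zero_grad(self):
        self.gW[:] = 0.0
        self.gb[:] = 0.0


class ReLU:
    def forward(self, x):
        return np.maximum(x, 0.0), x > 0

    def backward(self, dy, cache):
        return dy * cache

    def params(self):
        return []

    def zero_grad(self):
        pass


class Flatten:
    def forward(self, x):
        return x.reshape(x.shape[0], -1), x.shape

    def backward(self, dy, cache):
        return dy.reshape(cache)

    def params(self):
        return []

    def zero_grad(self):
        pass


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x):
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x)
            caches.append(c)
        return x, caches

    def forward_upto(self, x, n_layers: int):
        """Apply only the first ``n_layers`` layers (inference, no caches)."""
        for layer in self.layers[:n_layers]:
            x, _ = layer.forward(x)
        return x

    def backward(self, dy, caches):
        for layer, c in zip(reversed(self.layers), reversed(caches)):
            dy = layer.backward(dy, c)
        return dy

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for (p, _), s in zip(self.params(), state):
            p[:] = s


class Adam:
    """Adam optimizer over (param, grad) array pairs (arrays updated in place)."""

    def __init__(self, params, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
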