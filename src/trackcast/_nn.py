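"""Neural-network building blocks over the autodiff core.

Layers hold their parameters as ``Tensor``s with ``requires_grad=True`` and
expose ``parameters()`` for the optimizer.  Initialisation follows the usual
fan-in uniform scheme and is driven by an explicit ``numpy.random.Generator``
so that full training runs are reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch on load")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch on load")
            p.data = np.asarray(a, dtype=np.float64)


def _uniform(rng: np.random.Generator, fan_in: int, shape) -> Tensor:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.w = _uniform(rng, in_dim, (in_dim, out_dim))
        self.b = _uniform(rng, in_dim, (1, out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.matmul(x, self.w) + self.b


class MLP(Module):
    """Stack of Linear layers with ReLU between them (none after the last)."""

    def __init__(self, dims: list[int], rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = ad.relu(x)
        return x


class LSTMCell(Module):
    """Standard LSTM cell; gate order [input, forget, cell, output]."""

    def __init__(self, in_dim: int, hidden_dim: int, rng: np.random.Generator):
        self.hidden_dim = hidden_dim
        self.wx = _uniform(rng, in_dim, (in_dim, 4 * hidden_dim))
        self.wh = _uniform(rng, hidden_dim, (hidden_dim, 4 * hidden_dim))
        self.b = _uniform(rng, hidden_dim, (1, 4 * hidden_dim))

    def __call__(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        H = self.hidden_dim
        gates = ad.matmul(x, self.wx) + ad.matmul(h, self.wh) + self.b
        hc = ad.lstm_activation(gates, c)
        return hc[:, :H], hc[:, H:]

    def zero_state(self, batch: int) -> tuple[Tensor, Tensor]:
        z = np.zeros((batch, self.hidden_dim))
        return Tensor(z), Tensor(z.copy())


class Conv1d(Module):
    """Length-preserving 1-D convolution layer (odd kernel, zero padding)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        fan_in = in_ch * kernel
        bound = 1.0 / np.sqrt(fan_in)
        self.w = Tensor(rng.uniform(-bound, bound, (out_ch, in_ch, kernel)),
                        requires_grad=True)
        self.b = Tensor(rng.uniform(-bound, bound, out_ch), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv1d(x, self.w, self.b)


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def clip_gradients(self, max_norm: float) -> None:
        """Scale all gradients so their global L2 norm is at most max_norm."""
        total = 0.0
        for p in self.params:
            if p.grad is not None:
                total += float((p.grad ** 2).sum())
        total = np.sqrt(total)
        if total > max_norm:
            scale = max_norm / total
            for p in self.params:
                if p.grad is not None:
                    p.grad *= scale

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
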