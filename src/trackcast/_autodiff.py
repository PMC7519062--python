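"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package trains small recurrent/adversarial networks on CPU; this module
provides exactly the tensor operations those networks need (dense matmul,
elementwise nonlinearities, concatenation, slicing, 1-D convolution, reductions
and a numerically stable binary cross-entropy on logits) with gradients
accumulated on a dynamically built tape.  All arrays are float64; gradient
correctness is enforced by central-difference checks in the test suite.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _tracking(*tensors: "Tensor") -> bool:
    return _GRAD_ENABLED and any(t.requires_grad for t in tensors)


class Tensor:
    """A numpy array plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- bookkeeping ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
            if self.grad.shape != self.data.shape:  # scalar from 0-d
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, neg(_as_tensor(other)))

    def __rsub__(self, other):
        return add(_as_tensor(other), neg(self))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape)

    def sum(self):
        return tsum(self)

    def mean(self):
        return tmean(self)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `g` down to `shape` (reverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def _make(out_data, parents, backward) -> Tensor:
    out = Tensor(out_data)
    if _tracking(*parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


# -- primitive operations ----------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), backward)


def neg(a: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(-g)

    return _make(-a.data, (a,), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return _make(a.data @ b.data, (a, b), backward)


def tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (1.0 - out_data ** 2))

    return _make(out_data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    out_data = 0.5 * (1.0 + np.tanh(0.5 * a.data))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return _make(np.where(mask, a.data, 0.0), (a,), backward)


def square(a: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(g * 2.0 * a.data)

    return _make(a.data ** 2, (a,), backward)


def tsum(a: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(np.full_like(a.data, float(g)))

    return _make(a.data.sum(), (a,), backward)


def tmean(a: Tensor) -> Tensor:
    n = a.data.size

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.full_like(a.data, float(g) / n))

    return _make(a.data.mean(), (a,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def reshape(a: Tensor, shape) -> Tensor:
    old_shape = a.data.shape

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(old_shape))

    return _make(a.data.reshape(shape), (a,), backward)


def getitem(a: Tensor, idx) -> Tensor:
    # basic indexing selects without repeats, so in-place add is exact;
    # advanced (array) indexing may repeat and needs np.add.at
    basic = isinstance(idx, (int, slice)) or (
        isinstance(idx, tuple) and all(isinstance(e, (int, slice)) for e in idx))

    def backward(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            if basic:
                full[idx] += g
            else:
                np.add.at(full, idx, g)
            a._accumulate(full)

    return _make(a.data[idx], (a,), backward)


def row_scatter_sum(h: Tensor, src_idx: np.ndarray, dst_idx: np.ndarray,
                    n_out: int) -> Tensor:
    """out[dst_idx[k], :] += h[src_idx[k], :] into an (n_out, d) zero matrix.

    The index pairs are constants (gradients do not flow through them);
    gradients flow to the gathered rows of ``h``.
    """
    out_data = np.zeros((n_out, h.data.shape[1]))
    if len(src_idx):
        np.add.at(out_data, dst_idx, h.data[src_idx])

    def backward(g):
        if h.requires_grad:
            gh = np.zeros_like(h.data)
            if len(src_idx):
                np.add.at(gh, src_idx, g[dst_idx])
            h._accumulate(gh)

    return _make(out_data, (h,), backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]

    def backward(g):
        parts = np.moveaxis(g, axis, 0)
        for t, part in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(part)

    return _make(np.stack([t.data for t in tensors], axis=axis), tensors, backward)


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Length-preserving 1-D convolution.

    x: (B, C_in, T); w: (C_out, C_in, K) with odd K (zero padding K//2);
    b: (C_out,).  Returns (B, C_out, T).
    """
    B, c_in, T = x.data.shape
    c_out, _, K = w.data.shape
    pad = K // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    out_data = np.zeros((B, c_out, T))
    for k in range(K):
        # (B, C_in, T) x (C_out, C_in) contribution at tap k
        out_data += np.einsum("bct,oc->bot", xp[:, :, k:k + T], w.data[:, :, k])
    out_data += b.data[None, :, None]

    def backward(g):
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2)))
        if w.requires_grad:
            gw = np.zeros_like(w.data)
            for k in range(K):
                gw[:, :, k] = np.einsum("bot,bct->oc", g, xp[:, :, k:k + T])
            w._accumulate(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for k in range(K):
                gxp[:, :, k:k + T] += np.einsum("bot,oc->bct", g, w.data[:, :, k])
            x._accumulate(gxp[:, :, pad:pad + T])

    return _make(out_data, (x, w, b), backward)


def lstm_activation(gates: Tensor, c: Tensor) -> Tensor:
    """Fused LSTM gate nonlinearity.

    ``gates``: (B, 4H) pre-activations in [input, forget, cell, output]
    order; ``c``: (B, H) previous cell state.  Returns (B, 2H) holding
    ``[h_new, c_new]`` side by side (split by the caller).
    """
    B, H4 = gates.data.shape
    H = H4 // 4
    z = gates.data
    sig = lambda v: 0.5 * (1.0 + np.tanh(0.5 * v))
    i = sig(z[:, :H])
    f = sig(z[:, H:2 * H])
    g = np.tanh(z[:, 2 * H:3 * H])
    o = sig(z[:, 3 * H:])
    c_new = f * c.data + i * g
    tc = np.tanh(c_new)
    h_new = o * tc
    out_data = np.concatenate([h_new, c_new], axis=1)

    def backward(grad):
        gh, gc_direct = grad[:, :H], grad[:, H:]
        gc = gc_direct + gh * o * (1.0 - tc ** 2)
        if gates.requires_grad:
            dg = np.empty_like(z)
            dg[:, :H] = gc * g * i * (1.0 - i)
            dg[:, H:2 * H] = gc * c.data * f * (1.0 - f)
            dg[:, 2 * H:3 * H] = gc * i * (1.0 - g ** 2)
            dg[:, 3 * H:] = gh * tc * o * (1.0 - o)
            gates._accumulate(dg)
        if c.requires_grad:
            c._accumulate(gc * f)

    return _make(out_data, (gates, c), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw scores, numerically stable."""
    t = np.asarray(targets, dtype=np.float64)
    z = logits.data
    loss = np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))
    n = z.size

    def backward(g):
        if logits.requires_grad:
            p = 0.5 * (1.0 + np.tanh(0.5 * z))
            logits._accumulate(float(g) * (p - t) / n)

    return _make(loss.mean(), (logits,), backward)
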