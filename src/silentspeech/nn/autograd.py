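"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the 1D-convolutional networks in this package:
elementwise arithmetic with broadcasting, matrix products, tanh, rectified
hinge, reductions, reshape/concat, a 1D convolution primitive (im2col), a
fixed-weight pooling product, and a fused softmax cross-entropy.  Tensors
record their parents; :meth:`Tensor.backward` runs a topological sweep.

The engine is deliberately small: single-threaded, float64, no in-place
graph mutation, no higher-order gradients.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    # -- graph construction -------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=float), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     parents=(self, other))
        def bwd(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, requires_grad=self.requires_grad,
                     parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     parents=(self, other))
        def bwd(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        p = float(exponent)
        out = Tensor(self.data ** p, requires_grad=self.requires_grad,
                     parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1.0))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(np.matmul(self.data, other.data),
                     requires_grad=self.requires_grad or other.requires_grad,
                     parents=(self, other))
        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))
        out._backward = bwd
        return out

    # -- nonlinearities and reductions --------------------------------------
    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, requires_grad=self.requires_grad, parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - y ** 2))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, requires_grad=self.requires_grad,
                     parents=(self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     requires_grad=self.requires_grad, parents=(self,))
        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else \
            int(np.prod([self.data.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape),
                     requires_grad=self.requires_grad, parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, requires_grad=any(t.requires_grad for t in tensors),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])
    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# network primitives
# ---------------------------------------------------------------------------

def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None,
           padding: int) -> Tensor:
    """1D convolution (cross-correlation), stride 1.

    x: (B, C_in, L); weight: (C_out, C_in, K); output (B, C_out, L_out)
    with L_out = L + 2*padding - K + 1.
    """
    B, Cin, L = x.shape
    Cout, Cin_w, K = weight.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input {Cin}, weight {Cin_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding)))
    Lp = xp.shape[2]
    Lout = Lp - K + 1
    if Lout < 1:
        raise ValueError(f"input length {L} too short for kernel {K}")
    # (B, Cin, Lout, K) strided view -> (B, Lout, Cin*K)
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)
    cols = win.transpose(0, 2, 1, 3).reshape(B, Lout, Cin * K)
    Wmat = weight.data.reshape(Cout, Cin * K)
    out_data = np.matmul(cols, Wmat.T)                # (B, Lout, Cout)
    if bias is not None:
        out_data = out_data + bias.data
    out_data = out_data.transpose(0, 2, 1)            # (B, Cout, Lout)

    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_data, requires_grad=any(p.requires_grad for p in parents),
                 parents=parents)

    def bwd(g):
        gl = g.transpose(0, 2, 1)                     # (B, Lout, Cout)
        if bias is not None and bias.requires_grad:
            bias._accum(gl.sum(axis=(0, 1)))
        if weight.requires_grad:
            gW = np.einsum("blo,blk->ok", gl, cols)
            weight._accum(gW.reshape(Cout, Cin, K))
        if x.requires_grad:
            gcols = np.matmul(gl, Wmat)               # (B, Lout, Cin*K)
            gcols = gcols.reshape(B, Lout, Cin, K).transpose(0, 2, 1, 3)
            gxp = np.zeros_like(xp)
            for k in range(K):                        # K is small
                gxp[:, :, k:k + Lout] += gcols[:, :, :, k]
            x._accum(gxp[:, :, padding:Lp - padding] if padding else gxp)
    out._backward = bwd
    return out


_POOL_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _pool_matrix(L: int, M: int) -> np.ndarray:
    """(M, L) averaging matrix for adaptive mean pooling L -> M bins.

    Bin i averages samples floor(i*L/M) .. ceil((i+1)*L/M)-1, so output
    shape depends only on M, never on L.
    """
    key = (L, M)
    A = _POOL_CACHE.get(key)
    if A is None:
        A = np.zeros((M, L))
        for i in range(M):
            a = (i * L) // M
            b = -(-((i + 1) * L) // M)  # ceil
            A[i, a:b] = 1.0 / (b - a)
        _POOL_CACHE[key] = A
    return A


def adaptive_avg_pool1d(x: Tensor, output_length: int) -> Tensor:
    """Adaptive average pooling of (B, C, L) to (B, C, output_length)."""
    L = x.shape[-1]
    if output_length > L:
        raise ValueError(
            f"cannot pool length {L} up to {output_length}")
    A = _pool_matrix(L, output_length)
    out = Tensor(np.matmul(x.data, A.T), requires_grad=x.requires_grad,
                 parents=(x,))
    out._backward = lambda g: x._accum(np.matmul(g, A))
    return out


def softmax_cross_entropy(logits: Tensor, target_idx: np.ndarray) -> Tensor:
    """Mean cross-entropy of (B, C) logits against integer class indices."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    B = len(target_idx)
    nll = -np.log(np.clip(p[np.arange(B), target_idx], 1e-300, None))
    out = Tensor(nll.mean(), requires_grad=logits.requires_grad,
                 parents=(logits,))
    def bwd(g):
        gp = p.copy()
        gp[np.arange(B), target_idx] -= 1.0
        logits._accum(g * gp / B)
    out._backward = bwd
    return out


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)
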