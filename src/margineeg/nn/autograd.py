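"""Minimal reverse-mode automatic differentiation over numpy arrays.

The deep-learning stack in this package (channels-as-depth CNN, bidirectional
LSTM, attention layers, transformer blocks) is small enough that a compact
tensor autograd engine is sufficient: every operation stores its parents and a
closure that accumulates gradients into them.  Arrays are kept in float64 so
analytic gradients can be validated against central finite differences at
tight tolerance.

Only the operations the model zoo actually needs are implemented; each
backward rule is exercised by the finite-difference tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "conv_time"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._backward = None
        self._parents = _parents

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        # iterative topological sort (post-order DFS without recursion)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = bw
        return out

    # ------------------------------------------------------------- elementwise
    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out.data)

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = bw
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out.data ** 2))

        out._backward = bw
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out.data * (1.0 - out.data))

        out._backward = bw
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                # subgradient 0 at the kink, matching max(0, .) convention
                self._accum(g * (self.data > 0.0))

        out._backward = bw
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * np.sign(self.data))

        out._backward = bw
        return out

    def sqrt(self):
        return self ** 0.5

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------ shape moves
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = bw
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = bw
        return out

    # --------------------------------------------------------------- softmax
    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accum(s * (g - dot))

        out._backward = bw
        return out

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = bw
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))

    def bw(g):
        parts = np.split(g, len(tensors), axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(np.squeeze(p, axis=axis))

    out._backward = bw
    return out


def _same_ceil_pad(t_in: int, k: int, stride: int) -> tuple[int, int]:
    """Left/right zero padding so out = ceil(t_in / stride) (TF 'same' rule)."""
    t_out = -(-t_in // stride)
    total = max((t_out - 1) * stride + k - t_in, 0)
    left = total // 2
    return left, total - left


def conv_time(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 2) -> Tensor:
    """Temporal convolution with kernel (1, k) and 'same-ceil' padding.

    x: (batch, in_depth, height, time); height is 1 in channels-as-depth mode
    and the preserved electrode axis otherwise.  w: (out_depth, in_depth, k).
    Output time = ceil(time / stride).
    """
    B, Cin, H, T = x.data.shape
    Cout, Cin_w, k = w.data.shape
    if Cin != Cin_w:
        raise ValueError(f"conv depth mismatch: input {Cin} vs kernel {Cin_w}")
    left, right = _same_ceil_pad(T, k, stride)
    t_out = -(-T // stride)
    xp = np.pad(x.data, ((0, 0), (0, 0), (0, 0), (left, right)))
    sB, sC, sH, sT = xp.strides
    patches = np.lib.stride_tricks.as_strided(
        xp, shape=(B, Cin, H, t_out, k),
        strides=(sB, sC, sH, sT * stride, sT), writeable=False)
    y = np.einsum("bihtk,oik->boht", patches, w.data, optimize=True)
    if b is not None:
        y = y + b.data.reshape(1, Cout, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, _parents=parents)

    def bw(g):
        if w.requires_grad:
            gw = np.einsum("boht,bihtk->oik", g, patches, optimize=True)
            w._accum(gw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gp = np.einsum("boht,oik->bihtk", g, w.data, optimize=True)
            gxp = np.zeros_like(xp)
            for kk in range(k):
                gxp[..., kk:kk + stride * t_out:stride] += gp[..., kk]
            gx = gxp[..., left:left + T]
            x._accum(gx)

    out._backward = bw
    return out
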