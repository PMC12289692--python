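"""Neural-network layers built on the autograd engine.

Everything is deliberately small-scale: the decoding networks in this package
have 10^4–10^5 parameters and train full- or large-batch on a CPU.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, conv_time

__all__ = [
    "Module", "Linear", "ConvTemporal", "BatchNorm", "LayerNorm",
    "BiLSTM", "MultiHeadSelfAttention", "MLP", "abs_tanh_tensor",
]


class Module:
    """Base class: parameter discovery, train/eval mode, seeding left to callers."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for v in self.__dict__.values():
            for p in _collect(v):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self) -> None:
        for m in self.modules():
            m.training = True

    def eval(self) -> None:
        for m in self.modules():
            m.training = False

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat parameter snapshot for checkpointing (order = parameters())."""
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data[...] = state[f"p{i}"]


def _collect(v) -> list[Tensor]:
    if isinstance(v, Tensor) and v.requires_grad:
        return [v]
    if isinstance(v, Module):
        return v.parameters()
    if isinstance(v, (list, tuple)):
        out: list[Tensor] = []
        for item in v:
            out.extend(_collect(item))
        return out
    return []


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, zero_init: bool = False):
        super().__init__()
        w = np.zeros((d_in, d_out)) if zero_init else _glorot(rng, (d_in, d_out), d_in, d_out)
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.w
        return y + self.b if self.b is not None else y


class ConvTemporal(Module):
    """Conv with kernel (1, k), stride (1, 2), same-ceil padding (out=ceil(in/2))."""

    def __init__(self, in_depth: int, out_depth: int, k: int,
                 rng: np.random.Generator, stride: int = 2):
        super().__init__()
        fan_in = in_depth * k
        self.w = Tensor(_glorot(rng, (out_depth, in_depth, k), fan_in, out_depth),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_depth), requires_grad=True)
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return conv_time(x, self.w, self.b, stride=self.stride)


class BatchNorm(Module):
    """Normalizes over all axes except the depth axis (axis 1 of a 4-D input)."""

    def __init__(self, n_depth: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(n_depth), requires_grad=True)
        self.beta = Tensor(np.zeros(n_depth), requires_grad=True)
        self.momentum = momentum
        self.eps = eps
        self.run_mean = np.zeros(n_depth)
        self.run_var = np.ones(n_depth)

    def __call__(self, x: Tensor) -> Tensor:
        axes = tuple(a for a in range(x.ndim) if a != 1)
        bshape = [1] * x.ndim
        bshape[1] = -1
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            self.run_mean = ((1 - self.momentum) * self.run_mean
                             + self.momentum * mu.data.reshape(-1))
            self.run_var = ((1 - self.momentum) * self.run_var
                            + self.momentum * var.data.reshape(-1))
            xn = xc * (var + self.eps) ** -0.5
        else:
            mu = self.run_mean.reshape(bshape)
            sd = np.sqrt(self.run_var + self.eps).reshape(bshape)
            xn = (x - Tensor(mu)) * Tensor(1.0 / sd)
        return xn * self.gamma.reshape(bshape) + self.beta.reshape(bshape)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc * (var + self.eps) ** -0.5
        return xn * self.gamma + self.beta


class BiLSTM(Module):
    """Bidirectional LSTM over (batch, time, features).

    `last_hidden` gives the many-to-one readout: final forward and final
    backward hidden states concatenated (2*hidden).  `sequence` gives the
    per-timestep concatenated states (batch, time, 2*hidden) for attention.
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden

        def gate_params():
            wx = Tensor(_glorot(rng, (d_in, 4 * hidden), d_in, hidden), requires_grad=True)
            wh = Tensor(_glorot(rng, (hidden, 4 * hidden), hidden, hidden), requires_grad=True)
            b = np.zeros(4 * hidden)
            b[hidden:2 * hidden] = 1.0  # forget-gate bias
            return wx, wh, Tensor(b, requires_grad=True)

        self.fwd = gate_params()
        self.bwd = gate_params()

    def _run(self, x: Tensor, params, reverse: bool) -> list[Tensor]:
        wx, wh, b = params
        B, T, _ = x.shape
        h = Tensor(np.zeros((B, self.hidden)))
        c = Tensor(np.zeros((B, self.hidden)))
        order = range(T - 1, -1, -1) if reverse else range(T)
        hs: list[Tensor] = [None] * T
        n = self.hidden
        for t in order:
            z = x[:, t, :] @ wx + h @ wh + b
            i = z[:, 0:n].sigmoid()
            f = z[:, n:2 * n].sigmoid()
            g = z[:, 2 * n:3 * n].tanh()
            o = z[:, 3 * n:4 * n].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            hs[t] = h
        return hs

    def sequence(self, x: Tensor) -> Tensor:
        hf = self._run(x, self.fwd, reverse=False)
        hb = self._run(x, self.bwd, reverse=True)
        from .autograd import stack
        seq_f = stack(hf, axis=1)
        seq_b = stack(hb, axis=1)
        return concat([seq_f, seq_b], axis=-1)

    def last_hidden(self, x: Tensor) -> Tensor:
        hf = self._run(x, self.fwd, reverse=False)
        hb = self._run(x, self.bwd, reverse=True)
        return concat([hf[-1], hb[0]], axis=-1)


class MultiHeadSelfAttention(Module):
    """Standard softmax multi-head self-attention for (batch, tokens, d) input."""

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator,
                 zero_out: bool = False):
        super().__init__()
        if d % n_heads:
            raise ValueError("n_heads must divide the model dimension")
        self.n_heads = n_heads
        self.d_head = d // n_heads
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng, zero_init=zero_out)

    def _split(self, t: Tensor, B: int, T: int) -> Tensor:
        return t.reshape(B, T, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor, return_weights: bool = False):
        B, T, d = x.shape
        q = self._split(self.wq(x), B, T)
        k = self._split(self.wk(x), B, T)
        v = self._split(self.wv(x), B, T)
        logits = (q @ k.transpose(0, 1, 3, 2)) * (self.d_head ** -0.5)
        w = logits.softmax(axis=-1)
        ctx = (w @ v).transpose(0, 2, 1, 3).reshape(B, T, d)
        out = self.wo(ctx)
        if return_weights:
            return out, w
        return out


def abs_tanh_tensor(x: Tensor) -> Tensor:
    """|x|*tanh(x): odd, monotone, dampens small activations."""
    return x.abs() * x.tanh()


class MLP(Module):
    def __init__(self, d_in: int, hidden: list[int], d_out: int,
                 rng: np.random.Generator, activation: str = "relu",
                 zero_out: bool = False):
        super().__init__()
        dims = [d_in] + list(hidden)
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.out = Linear(dims[-1], d_out, rng, zero_init=zero_out)
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        for lay in self.layers:
            x = lay(x)
            x = abs_tanh_tensor(x) if self.activation == "abs_tanh" else x.relu()
        return self.out(x)
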