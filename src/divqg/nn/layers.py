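"""Neural-network building blocks on top of :mod:`divqg.nn.tensor`.

All weights are initialized from an explicit ``numpy.random.Generator``
so that every model build is reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, concat

__all__ = [
    "Module",
    "Parameter",
    "Linear",
    "Embedding",
    "MLP",
    "Conv2d",
    "max_pool2x2",
    "LSTM",
]


def Parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


class Module:
    """Container with recursive parameter registration and state dicts."""

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_modules", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def parameters(self):
        for p in self.__dict__.get("_params", {}).values():
            yield p
        for m in self.__dict__.get("_modules", {}).values():
            yield from m.parameters()

    def state_dict(self, prefix: str = "") -> dict:
        out = {}
        for name, p in self.__dict__.get("_params", {}).items():
            out[prefix + name] = p.data.copy()
        for name, m in self.__dict__.get("_modules", {}).items():
            out.update(m.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state: dict, prefix: str = ""):
        for name, p in self.__dict__.get("_params", {}).items():
            key = prefix + name
            if key not in state:
                raise KeyError(f"missing parameter {key!r} in state dict")
            arr = np.asarray(state[key], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {key!r}: {arr.shape} vs {p.data.shape}"
                )
            p.data = arr.copy()
        for name, m in self.__dict__.get("_modules", {}).items():
            m.load_state_dict(state, prefix + name + ".")

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.w = Parameter(_glorot(rng, in_features, out_features, (in_features, out_features)))
        self.b = Parameter(np.zeros(out_features))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Embedding(Module):
    def __init__(self, num_embeddings: int, dim: int, rng: np.random.Generator):
        self.weight = Parameter(rng.normal(0.0, 1.0, size=(num_embeddings, dim)))

    def __call__(self, indices: np.ndarray) -> Tensor:
        return self.weight.take_rows(np.asarray(indices, dtype=np.int64))


class MLP(Module):
    """Fully connected network with ReLU between layers (default depth 3)."""

    def __init__(
        self,
        in_features: int,
        hidden: int,
        out_features: int,
        rng: np.random.Generator,
        depth: int = 3,
    ):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        dims = [in_features] + [hidden] * (depth - 1) + [out_features]
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x


class Conv2d(Module):
    """3x3 same-padding convolution via im2col matmul."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, kernel: int = 3):
        fan_in = in_ch * kernel * kernel
        fan_out = out_ch * kernel * kernel
        self.w = Parameter(_glorot(rng, fan_in, fan_out, (out_ch, in_ch, kernel, kernel)))
        self.b = Parameter(np.zeros(out_ch))
        self.kernel = kernel
        self.pad = kernel // 2

    def __call__(self, x: Tensor) -> Tensor:
        w, b, k, pad = self.w, self.b, self.kernel, self.pad
        B, C, H, W = x.data.shape
        O = w.data.shape[0]
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        # (B, C, H, W, k, k) -> (B, H*W, C*k*k)
        windows = sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(B, H * W, C * k * k)
        w_col = w.data.reshape(O, C * k * k)
        out_data = cols @ w_col.T + b.data  # (B, H*W, O)
        out_data = out_data.transpose(0, 2, 1).reshape(B, O, H, W)

        def backward(g):
            g2 = g.reshape(B, O, H * W).transpose(0, 2, 1)  # (B, H*W, O)
            if b.requires_grad:
                b._accum(g2.sum(axis=(0, 1)))
            if w.requires_grad:
                dw = np.tensordot(g2, cols, axes=([0, 1], [0, 1]))  # (O, C*k*k)
                w._accum(dw.reshape(w.data.shape))
            if x.requires_grad:
                dcols = (g2 @ w_col).reshape(B, H, W, C, k, k)
                dxp = np.zeros_like(xp)
                for i in range(k):
                    for j in range(k):
                        dxp[:, :, i : i + H, j : j + W] += dcols[:, :, :, :, i, j].transpose(
                            0, 3, 1, 2
                        )
                x._accum(dxp[:, :, pad : pad + H, pad : pad + W])

        return Tensor._make(out_data, (x, w, b), backward)


def max_pool2x2(x: Tensor) -> Tensor:
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("max_pool2x2 requires even spatial dimensions")
    Ho, Wo = H // 2, W // 2
    r = x.data.reshape(B, C, Ho, 2, Wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        B, C, Ho, Wo, 4
    )
    idx = r.argmax(axis=-1)
    out_data = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        dr = np.zeros_like(r)
        np.put_along_axis(dr, idx[..., None], g[..., None], axis=-1)
        dx = dr.reshape(B, C, Ho, Wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            B, C, H, W
        )
        x._accum(dx)

    return Tensor._make(out_data, (x,), backward)


class LSTMLayer(Module):
    def __init__(self, input_size: int, hidden: int, rng: np.random.Generator):
        self.w_ih = Parameter(_glorot(rng, input_size, 4 * hidden, (input_size, 4 * hidden)))
        self.w_hh = Parameter(_glorot(rng, hidden, 4 * hidden, (hidden, 4 * hidden)))
        bias = np.zeros(4 * hidden)
        bias[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.b = Parameter(bias)
        self.hidden = hidden

    def step(self, x: Tensor, h: Tensor, c: Tensor):
        hdim = self.hidden
        gates = x @ self.w_ih + h @ self.w_hh + self.b
        i = gates[:, :hdim].sigmoid()
        f = gates[:, hdim : 2 * hdim].sigmoid()
        g = gates[:, 2 * hdim : 3 * hdim].tanh()
        o = gates[:, 3 * hdim :].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new


class LSTM(Module):
    """Multi-layer LSTM exposed as a single-timestep cell stack."""

    def __init__(self, input_size: int, hidden: int, layers: int, rng: np.random.Generator):
        self.cells = [
            LSTMLayer(input_size if i == 0 else hidden, hidden, rng)
            for i in range(layers)
        ]
        self.hidden = hidden
        self.num_layers = layers

    def step(self, x: Tensor, states: list):
        """Advance one timestep; ``states`` is a list of (h, c) per layer."""
        new_states = []
        inp = x
        for cell, (h, c) in zip(self.cells, states):
            h, c = cell.step(inp, h, c)
            new_states.append((h, c))
            inp = h
        return inp, new_states
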