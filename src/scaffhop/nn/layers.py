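"""Neural-network building blocks on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor, concat, gather_rows

__all__ = ["Module", "Linear", "Embedding", "GRUCell", "GRUStack"]


class Module:
    """Base class with named-parameter discovery over attributes."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.W = Parameter(_glorot(rng, d_in, d_out))
        self.b = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        self.table = Parameter(rng.normal(0.0, 0.1, size=(n_tokens, dim)))

    def __call__(self, idx) -> Tensor:
        return gather_rows(self.table, idx)


class GRUCell(Module):
    """Single GRU layer.

    Gate equations (f = update gate, r = reset gate):
        f_t = sigmoid(W_f x_t + U_f h_{t-1} + b_f)
        r_t = sigmoid(W_r x_t + U_r h_{t-1} + b_r)
        hhat = tanh(W_h x_t + U_h (r_t * h_{t-1}) + b_h)
        h_t  = (1 - f_t) * h_{t-1} + f_t * hhat
    """

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.d_hidden = d_hidden
        self.Wf = Parameter(_glorot(rng, d_in, d_hidden))
        self.Uf = Parameter(_glorot(rng, d_hidden, d_hidden))
        self.bf = Parameter(np.zeros(d_hidden))
        self.Wr = Parameter(_glorot(rng, d_in, d_hidden))
        self.Ur = Parameter(_glorot(rng, d_hidden, d_hidden))
        self.br = Parameter(np.zeros(d_hidden))
        self.Wh = Parameter(_glorot(rng, d_in, d_hidden))
        self.Uh = Parameter(_glorot(rng, d_hidden, d_hidden))
        self.bh = Parameter(np.zeros(d_hidden))

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        f = (x @ self.Wf + h @ self.Uf + self.bf).sigmoid()
        r = (x @ self.Wr + h @ self.Ur + self.br).sigmoid()
        hhat = (x @ self.Wh + (r * h) @ self.Uh + self.bh).tanh()
        return (1.0 - f) * h + f * hhat


class GRUStack(Module):
    """Multi-layer GRU; the hidden state of layer i feeds layer i+1."""

    def __init__(self, d_in: int, d_hidden: int, n_layers: int, rng: np.random.Generator):
        self.layers = [
            GRUCell(d_in if i == 0 else d_hidden, d_hidden, rng) for i in range(n_layers)
        ]
        self.d_hidden = d_hidden
        self.n_layers = n_layers

    def step(self, x: Tensor, hs: list) -> tuple:
        """One time step for a batch. `hs` is a list of per-layer hidden states
        (each batch x d_hidden); returns (top output, new hidden list)."""
        new_hs = []
        inp = x
        for cell, h in zip(self.layers, hs):
            h_new = cell(inp, h)
            new_hs.append(h_new)
            inp = h_new
        return inp, new_hs


def one_hot(idx: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((len(idx), n))
    out[np.arange(len(idx)), idx] = 1.0
    return out
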