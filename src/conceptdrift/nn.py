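"""Small neural building blocks: linear maps, MLPs, a gated recurrent cell,
functional time encoding, multi-head cross-attention and Adam."""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from ._tensor import Tensor, concat

__all__ = [
    "Module",
    "Linear",
    "MLP",
    "GRUCell",
    "TimeEncoder",
    "MultiHeadAttention",
    "Adam",
]


class Module:
    """Parameter container; children are discovered via attributes."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def visit(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in obj.__dict__.values():
                    visit(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    visit(v)

        visit(self)
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}

        def visit(obj, prefix):
            if isinstance(obj, Tensor):
                if obj.requires_grad:
                    out[prefix] = obj.data
            elif isinstance(obj, Module):
                for k, v in obj.__dict__.items():
                    visit(v, f"{prefix}.{k}" if prefix else k)
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    visit(v, f"{prefix}.{i}")

        visit(self, "")
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        current = self._named_params()
        missing = set(current) ^ set(state)
        if missing:
            raise ValueError(f"state mismatch on keys: {sorted(missing)}")
        for k, p in current.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = arr.copy()

    def _named_params(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}

        def visit(obj, prefix):
            if isinstance(obj, Tensor):
                if obj.requires_grad:
                    out[prefix] = obj
            elif isinstance(obj, Module):
                for k, v in obj.__dict__.items():
                    visit(v, f"{prefix}.{k}" if prefix else k)
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    visit(v, f"{prefix}.{i}")

        visit(self, "")
        return out


def _param(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> Tensor:
    scale = 1.0 / math.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        self.W = _param(rng, (n_in, n_out), n_in)
        self.b = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = Tensor._wrap(x) @ self.W
        return y + self.b if self.b is not None else y


class MLP(Module):
    """Feed-forward stack with tanh between layers, linear output."""

    def __init__(self, dims: Sequence[int], rng: np.random.Generator):
        if len(dims) < 2:
            raise ValueError("MLP needs at least input and output dims")
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        h = Tensor._wrap(x)
        for layer in self.layers[:-1]:
            h = layer(h).tanh()
        return self.layers[-1](h)


class GRUCell(Module):
    """Gated recurrent cell.

    r = sig(Wr x + Ur h + br); u = sig(Wu x + Uu h + bu)
    n = tanh(Wn x + r*(Un h) + bn); h' = (1-u)*n + u*h
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_in = n_in
        self.n_hidden = n_hidden
        self.Wr = _param(rng, (n_in, n_hidden), n_in)
        self.Ur = _param(rng, (n_hidden, n_hidden), n_hidden)
        self.br = Tensor(np.zeros(n_hidden), requires_grad=True)
        self.Wu = _param(rng, (n_in, n_hidden), n_in)
        self.Uu = _param(rng, (n_hidden, n_hidden), n_hidden)
        self.bu = Tensor(np.zeros(n_hidden), requires_grad=True)
        self.Wn = _param(rng, (n_in, n_hidden), n_in)
        self.Un = _param(rng, (n_hidden, n_hidden), n_hidden)
        self.bn = Tensor(np.zeros(n_hidden), requires_grad=True)

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        x = Tensor._wrap(x)
        h = Tensor._wrap(h)
        if x.shape[-1] != self.n_in or h.shape[-1] != self.n_hidden:
            raise ValueError(
                f"GRU expects input {self.n_in}/hidden {self.n_hidden}, "
                f"got {x.shape[-1]}/{h.shape[-1]}"
            )
        r = (x @ self.Wr + h @ self.Ur + self.br).sigmoid()
        u = (x @ self.Wu + h @ self.Uu + self.bu).sigmoid()
        n = (x @ self.Wn + r * (h @ self.Un) + self.bn).tanh()
        return (1.0 - u) * n + u * h


class TimeEncoder(Module):
    """Functional time encoding: [w0*x + b0, cos(w1*x + b1), ...].

    Frequencies follow a geometric ladder at init (Time2Vec-style) and are
    learnable.
    """

    def __init__(self, d_time: int, rng: np.random.Generator | None = None):
        if d_time < 1:
            raise ValueError("d_time must be >= 1")
        self.d_time = d_time
        freqs = np.ones(d_time)
        if d_time > 1:
            freqs[1:] = 1.0 / 10 ** np.linspace(0.0, 1.5, d_time - 1)
        self.omega = Tensor(freqs, requires_grad=True)
        self.phase = Tensor(np.zeros(d_time), requires_grad=True)

    def __call__(self, x) -> Tensor:
        """Encode times `x` (scalar or shape (B,)) to shape (B, d_time)."""
        xv = np.atleast_1d(np.asarray(x, dtype=np.float64))[:, None]
        u = self.omega * xv + self.phase
        if self.d_time == 1:
            return u
        return concat([u[:, :1], u[:, 1:].cos()], axis=-1)

    def encode(self, x) -> np.ndarray:
        """Untraced convenience wrapper returning a plain array."""
        out = self(x).data
        return out[0] if np.isscalar(x) or np.ndim(x) == 0 else out


class MultiHeadAttention(Module):
    """Single-query multi-head scaled dot-product attention with key padding.

    Queries have shape (B, d_q); keys/values (B, N, d_q); `mask` is a boolean
    (B, N) array flagging valid neighbor slots.  Rows whose mask is entirely
    False produce the zero vector.
    """

    def __init__(self, d_q: int, d_attn: int, n_heads: int,
                 rng: np.random.Generator):
        if d_attn % n_heads != 0:
            raise ValueError("attention dim must be divisible by head count")
        self.d_q = d_q
        self.d_attn = d_attn
        self.n_heads = n_heads
        self.d_head = d_attn // n_heads
        self.Wq = _param(rng, (d_q, d_attn), d_q)
        self.Wk = _param(rng, (d_q, d_attn), d_q)
        self.Wv = _param(rng, (d_q, d_attn), d_q)
        self.Wo = _param(rng, (d_attn, d_attn), d_attn)

    def __call__(self, q: Tensor, kv: Tensor, mask: np.ndarray,
                 return_weights: bool = False):
        q = Tensor._wrap(q)
        kv = Tensor._wrap(kv)
        if q.shape[-1] != self.d_q or kv.shape[-1] != self.d_q:
            raise ValueError(
                f"attention expects feature dim {self.d_q}, got "
                f"{q.shape[-1]} / {kv.shape[-1]}"
            )
        B, N = kv.shape[0], kv.shape[1]
        H, dh = self.n_heads, self.d_head
        mask = np.asarray(mask, dtype=bool).reshape(B, N)

        qh = (q @ self.Wq).reshape(B, H, 1, dh)
        kh = (kv @ self.Wk).reshape(B, N, H, dh).transpose(0, 2, 1, 3)
        vh = (kv @ self.Wv).reshape(B, N, H, dh).transpose(0, 2, 1, 3)

        scores = qh @ kh.transpose(0, 1, 3, 2) * (1.0 / math.sqrt(dh))
        bias = np.where(mask, 0.0, -1e30)[:, None, None, :]
        weights = (scores + bias).softmax(axis=-1)

        out = (weights @ vh).reshape(B, H * dh) @ self.Wo
        nonempty = mask.any(axis=1).astype(np.float64)[:, None]
        out = out * nonempty
        if return_weights:
            w = weights.data.reshape(B, H, N) * nonempty[:, None]
            return out, w
        return out


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
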