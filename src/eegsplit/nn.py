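"""Minimal NumPy neural-network core with explicit backpropagation.

The split-learning protocol exchanges activations and their gradients at a
cut layer, so the package needs direct access to dL/dz; these modules make
that gradient a first-class value. The library is intentionally small:
linear layers, ReLU, layer normalization, multi-head self-attention,
transformer encoder blocks, mean pooling, an MLP builder, softmax
cross-entropy and squared-error losses, and Adam.

Conventions
-----------
* Modules cache whatever the backward pass needs during ``forward``; each
  forward is therefore paired with exactly one backward (sufficient for
  plain minibatch training loops).
* ``backward(dout)`` accumulates parameter gradients in ``Parameter.grad``
  and returns the gradient with respect to the module input.
* All parameters are float64; constructors draw initial weights from an
  explicit ``numpy.random.Generator`` so training is seed-deterministic.

Every module's backward pass is validated against central finite
differences in the test suite.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import ConfigError, InputError


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Module:
    """Base class: forward/backward plus parameter bookkeeping."""

    def parameters(self) -> list[Parameter]:
        raise NotImplementedError

    def forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def snapshot(self) -> list[np.ndarray]:
        """Copies of all parameter values (for no-op / determinism checks)."""
        return [p.value.copy() for p in self.parameters()]

    def load(self, values: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(values) != len(params):
            raise InputError("snapshot length does not match parameter count")
        for p, v in zip(params, values):
            p.value[...] = v


class Linear(Module):
    """Affine map on the last axis: y = x @ W + b."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.W = Parameter(rng.normal(0.0, 1.0 / np.sqrt(d_in), size=(d_in, d_out)))
        self.b = Parameter(np.zeros(d_out)) if bias else None
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.W.value
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        d2 = dout.reshape(-1, dout.shape[-1])
        self.W.grad += x2.T @ d2
        if self.b is not None:
            self.b.grad += d2.sum(axis=0)
        return dout @ self.W.value.T


class ReLU(Module):
    def __init__(self):
        self._mask: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def parameters(self) -> list[Parameter]:
        return [p for m in self.modules for p in m.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for m in self.modules:
            x = m.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for m in reversed(self.modules):
            dout = m.backward(dout)
        return dout


class LayerNorm(Module):
    """Normalization over the last axis with learned scale and shift."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return xhat * self.gamma.value + self.beta.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        axes = tuple(range(dout.ndim - 1))
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value
        # standard layer-norm backward over the last axis
        return inv * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        )


def _softmax_last(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention with H heads and output projection.

    Input and output have shape ``(batch, tokens, d_model)``.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads != 0:
            raise ConfigError(f"d_model={d_model} not divisible by n_heads={n_heads}")
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_k = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return (
            self.wq.parameters() + self.wk.parameters()
            + self.wv.parameters() + self.wo.parameters()
        )

    def _split(self, x: np.ndarray) -> np.ndarray:
        b, t, _ = x.shape
        return x.reshape(b, t, self.n_heads, self.d_k).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        b, h, t, dk = x.shape
        return x.transpose(0, 2, 1, 3).reshape(b, t, h * dk)

    def forward(self, x: np.ndarray) -> np.ndarray:
        q = self._split(self.wq.forward(x))
        k = self._split(self.wk.forward(x))
        v = self._split(self.wv.forward(x))
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(self.d_k)
        attn = _softmax_last(scores)
        out = attn @ v
        self._cache = (q, k, v, attn)
        return self.wo.forward(self._merge(out))

    def attention_weights(self, x: np.ndarray) -> np.ndarray:
        """Per-head attention matrices for an input, shape (B, H, T, T)."""
        q = self._split(x @ self.wq.W.value + self.wq.b.value)
        k = self._split(x @ self.wk.W.value + self.wk.b.value)
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(self.d_k)
        return _softmax_last(scores)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        q, k, v, attn = self._cache
        dmerged = self.wo.backward(dout)
        dhead = self._split(dmerged)
        dattn = dhead @ v.transpose(0, 1, 3, 2)
        dv = attn.transpose(0, 1, 3, 2) @ dhead
        # softmax backward, rowwise over the last axis
        dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dscores /= np.sqrt(self.d_k)
        dq = dscores @ k
        dk = dscores.transpose(0, 1, 3, 2) @ q
        dx = self.wq.backward(self._merge(dq))
        dx = dx + self.wk.backward(self._merge(dk))
        dx = dx + self.wv.backward(self._merge(dv))
        return dx


class TransformerBlock(Module):
    """Post-norm encoder block: LN(x + MHSA(x)) then LN(y + FFN(y))."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int, rng: np.random.Generator):
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.ln1 = LayerNorm(d_model)
        self.ff = Sequential(Linear(d_model, d_ff, rng), ReLU(), Linear(d_ff, d_model, rng))
        self.ln2 = LayerNorm(d_model)

    def parameters(self) -> list[Parameter]:
        return (
            self.attn.parameters() + self.ln1.parameters()
            + self.ff.parameters() + self.ln2.parameters()
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.ln1.forward(x + self.attn.forward(x))
        return self.ln2.forward(y + self.ff.forward(y))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dy = self.ln2.backward(dout)
        dy = dy + self.ff.backward(dy)
        dx = self.ln1.backward(dy)
        return dx + self.attn.backward(dx)


class MeanPool(Module):
    """Mean over the token axis: (B, T, D) -> (B, D)."""

    def __init__(self):
        self._t = None

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._t = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.repeat(dout[:, None, :], self._t, axis=1) / self._t


class TransformerBackbone(Module):
    """Token embedding + learned positional encodings + encoder stack + pool.

    Maps ``(batch, n_tokens, token_dim)`` inputs to ``(batch, d_model)``
    latent vectors.
    """

    def __init__(
        self,
        n_tokens: int,
        token_dim: int,
        d_model: int,
        n_heads: int,
        n_layers: int,
        d_ff: int,
        rng: np.random.Generator,
    ):
        self.n_tokens = n_tokens
        self.token_dim = token_dim
        self.d_model = d_model
        self.embed = Linear(token_dim, d_model, rng)
        self.pos = Parameter(rng.normal(0.0, 0.02, size=(n_tokens, d_model)))
        self.blocks = [TransformerBlock(d_model, n_heads, d_ff, rng) for _ in range(n_layers)]
        self.pool = MeanPool()

    def parameters(self) -> list[Parameter]:
        out = self.embed.parameters() + [self.pos]
        for b in self.blocks:
            out += b.parameters()
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 3 or x.shape[1] != self.n_tokens or x.shape[2] != self.token_dim:
            raise InputError(
                f"expected input (batch, {self.n_tokens}, {self.token_dim}), "
                f"got {x.shape}"
            )
        h = self.embed.forward(x) + self.pos.value
        for b in self.blocks:
            h = b.forward(h)
        return self.pool.forward(h)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dh = self.pool.backward(dout)
        for b in reversed(self.blocks):
            dh = b.backward(dh)
        self.pos.grad += dh.sum(axis=0)
        return self.embed.backward(dh)


def mlp(
    sizes: Sequence[int],
    rng: np.random.Generator,
    hidden_activation: type[Module] | None = ReLU,
) -> Sequential:
    """Fully connected stack; activation after every layer except the last."""
    layers: list[Module] = []
    for i in range(len(sizes) - 1):
        layers.append(Linear(sizes[i], sizes[i + 1], rng))
        if hidden_activation is not None and i < len(sizes) - 2:
            layers.append(hidden_activation())
    return Sequential(*layers)


def softmax_cross_entropy(
    logits: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    if logits.ndim != 2 or logits.shape[0] != len(y):
        raise InputError("logits must be (batch, classes) aligned with y")
    n = logits.shape[0]
    p = _softmax_last(logits)
    eps = 1e-300
    loss = -np.mean(np.log(p[np.arange(n), y] + eps))
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), dlogits / n


def squared_error(x: np.ndarray, xhat: np.ndarray) -> tuple[float, np.ndarray]:
    """Reconstruction loss mean_b ||x_b - xhat_b||^2 and d loss / d xhat."""
    if x.shape != xhat.shape:
        raise InputError("x and xhat must share a shape")
    n = x.shape[0]
    diff = xhat - x
    loss = float(np.sum(diff**2) / n)
    return loss, 2.0 * diff / n


class Adam:
    """Adam optimizer over a fixed parameter list (elementwise updates)."""

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
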