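"""Minimal NumPy neural-network layers with explicit backpropagation.

Implements exactly what the estimators need — linear layers, layer
normalisation, dropout, scaled dot-product and multi-head self-attention,
position-wise feedforward blocks, vanilla RNN and LSTM cells — plus an Adam
optimiser.  Every layer caches its forward activations and exposes a
``backward`` consuming the upstream gradient; gradients are accumulated on
:class:`Parameter` objects.  All randomness flows through explicit
``numpy.random.Generator`` instances, so training is bit-deterministic for a
given seed.

Shapes follow the (batch, time, feature) convention throughout.
"""

from __future__ import annotations

import numpy as np

from .trace import ValidationError


class Parameter:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Module:
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for attr in vars(self).values():
            if isinstance(attr, Parameter):
                params.append(attr)
            elif isinstance(attr, Module):
                params.extend(attr.parameters())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.value.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.value[...] = state[f"p{i}"]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear(Module):
    """Affine map on the last axis: ``y = x @ W + b``."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Parameter(_glorot(rng, d_in, d_out), "W")
        self.b = Parameter(np.zeros(d_out), "b")
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        self.W.grad += np.tensordot(
            x.reshape(-1, x.shape[-1]), dout.reshape(-1, dout.shape[-1]), axes=(0, 0)
        )
        self.b.grad += dout.reshape(-1, dout.shape[-1]).sum(axis=0)
        return dout @ self.W.value.T


class LayerNorm(Module):
    """Normalisation over the last axis with learned gain and bias."""

    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(d), "gamma")
        self.beta = Parameter(np.zeros(d), "beta")
        self.eps = eps
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        d = xhat.shape[-1]
        self.gamma.grad += (dout * xhat).reshape(-1, d).sum(axis=0)
        self.beta.grad += dout.reshape(-1, d).sum(axis=0)
        dxhat = dout * self.gamma.value
        return inv * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        )


class Dropout(Module):
    """Inverted dropout; identity when ``train`` is False or ``p == 0``."""

    def __init__(self, p: float):
        if not (0 <= p < 1):
            raise ValidationError("dropout must be in [0, 1)")
        self.p = p
        self._mask: np.ndarray | float = 1.0

    def forward(
        self, x: np.ndarray, train: bool, rng: np.random.Generator | None
    ) -> np.ndarray:
        if not train or self.p == 0:
            self._mask = 1.0
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


def softmax(scores: np.ndarray) -> np.ndarray:
    """Row softmax over the last axis, safe against -inf masked entries."""
    m = scores.max(axis=-1, keepdims=True)
    e = np.exp(scores - m)
    return e / e.sum(axis=-1, keepdims=True)


def scaled_dot_attention(
    Q: np.ndarray,
    K: np.ndarray,
    V: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Single attention application: ``softmax(Q K^T / sqrt(d_k)) V``.

    ``Q`` is (n, d_k), ``K`` (m, d_k), ``V`` (m, d_v); ``mask`` an optional
    boolean (m,) vector where False marks keys to exclude (their weights are
    exactly zero).  Returns ``(output, weights)``.
    """
    Q, K, V = (np.asarray(a, dtype=np.float64) for a in (Q, K, V))
    if Q.ndim != 2 or K.ndim != 2 or V.ndim != 2:
        raise ValidationError("Q, K, V must be 2-D")
    if Q.shape[1] != K.shape[1]:
        raise ValidationError("Q and K disagree on d_k")
    if K.shape[0] != V.shape[0]:
        raise ValidationError("K and V disagree on m")
    scores = Q @ K.T / np.sqrt(K.shape[1])
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (K.shape[0],):
            raise ValidationError("mask must be a length-m boolean vector")
        if not mask.any():
            raise ValidationError("all key positions masked; softmax undefined")
        scores = np.where(mask[None, :], scores, -np.inf)
    weights = softmax(scores)
    return weights @ V, weights


class MultiHeadSelfAttention(Module):
    """Self-attention with ``n_heads`` contiguous head splits of ``d_model``.

    Per-head projections are slices of joint ``d_model x d_model`` query /
    key / value maps; head outputs are concatenated in stable head order and
    passed through the output projection.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValidationError(
                f"d_model={d_model} not divisible by n_heads={n_heads}"
            )
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)
        self._cache: tuple | None = None

    def _split(self, x: np.ndarray) -> np.ndarray:
        b, t, _ = x.shape
        return x.reshape(b, t, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def _join(self, x: np.ndarray) -> np.ndarray:
        b, h, t, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(b, t, h * dh)

    def forward(self, x: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        if mask is not None and not mask.any(axis=1).all():
            raise ValidationError("an example has all positions masked")
        q = self._split(self.wq.forward(x))
        k = self._split(self.wk.forward(x))
        v = self._split(self.wv.forward(x))
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(self.d_head)
        if mask is not None:
            scores = np.where(mask[:, None, None, :], scores, -np.inf)
        attn = softmax(scores)  # (B, h, T, T)
        ctx = attn @ v
        out = self.wo.forward(self._join(ctx))
        self._cache = (q, k, v, attn)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        q, k, v, attn = self._cache
        dctx = self._split(self.wo.backward(dout))
        dattn = dctx @ v.transpose(0, 1, 3, 2)
        dv = attn.transpose(0, 1, 3, 2) @ dctx
        dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        scale = 1.0 / np.sqrt(self.d_head)
        dq = dscores @ k * scale
        dk = dscores.transpose(0, 1, 3, 2) @ q * scale
        dx = self.wq.backward(self._join(dq))
        dx += self.wk.backward(self._join(dk))
        dx += self.wv.backward(self._join(dv))
        return dx


class FeedForward(Module):
    """Position-wise two-layer ReLU network."""

    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator):
        self.fc1 = Linear(d_model, d_ff, rng)
        self.fc2 = Linear(d_ff, d_model, rng)
        self._pre: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._pre = self.fc1.forward(x)
        return self.fc2.forward(np.maximum(self._pre, 0.0))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dh = self.fc2.backward(dout)
        return self.fc1.backward(dh * (self._pre > 0))


class EncoderLayer(Module):
    """Post-norm encoder block: LN(x + MHSA(x)) then LN(h + FFN(h))."""

    def __init__(
        self, d_model: int, n_heads: int, d_ff: int, dropout: float,
        rng: np.random.Generator,
    ):
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.ln1 = LayerNorm(d_model)
        self.ff = FeedForward(d_model, d_ff, rng)
        self.ln2 = LayerNorm(d_model)
        self.drop1 = Dropout(dropout)
        self.drop2 = Dropout(dropout)

    def forward(
        self,
        x: np.ndarray,
        mask: np.ndarray | None = None,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        h = self.ln1.forward(x + self.drop1.forward(self.attn.forward(x, mask), train, rng))
        return self.ln2.forward(h + self.drop2.forward(self.ff.forward(h), train, rng))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dh = self.ln2.backward(dout)
        dh = dh + self.ff.backward(self.drop2.backward(dh))
        dx = self.ln1.backward(dh)
        return dx + self.attn.backward(self.drop1.backward(dx))


class RNNCellSequence(Module):
    """Single-layer vanilla (tanh) RNN unrolled over the time axis."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.wx = Parameter(_glorot(rng, d_in, d_hidden), "wx")
        self.wh = Parameter(_glorot(rng, d_hidden, d_hidden), "wh")
        self.b = Parameter(np.zeros(d_hidden), "b")
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, t, _ = x.shape
        d = self.b.value.size
        hs = np.zeros((b, t + 1, d))
        for i in range(t):
            hs[:, i + 1] = np.tanh(
                x[:, i] @ self.wx.value + hs[:, i] @ self.wh.value + self.b.value
            )
        self._cache = (x, hs)
        return hs[:, 1:]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, hs = self._cache
        b, t, _ = x.shape
        dx = np.zeros_like(x)
        dh_next = np.zeros((b, self.b.value.size))
        for i in range(t - 1, -1, -1):
            dh = dout[:, i] + dh_next
            dpre = dh * (1 - hs[:, i + 1] ** 2)
            self.wx.grad += x[:, i].T @ dpre
            self.wh.grad += hs[:, i].T @ dpre
            self.b.grad += dpre.sum(axis=0)
            dx[:, i] = dpre @ self.wx.value.T
            dh_next = dpre @ self.wh.value.T
        return dx


class LSTMCellSequence(Module):
    """Single-layer LSTM unrolled over the time axis (gate order i, f, g, o)."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.wx = Parameter(_glorot(rng, d_in, 4 * d_hidden), "wx")
        self.wh = Parameter(_glorot(rng, d_hidden, 4 * d_hidden), "wh")
        self.b = Parameter(np.zeros(4 * d_hidden), "b")
        self.d_hidden = d_hidden
        self._cache: list | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, t, _ = x.shape
        d = self.d_hidden
        h = np.zeros((b, d))
        c = np.zeros((b, d))
        out = np.zeros((b, t, d))
        cache = []
        for step in range(t):
            z = x[:, step] @ self.wx.value + h @ self.wh.value + self.b.value
            i = _sigmoid(z[:, :d])
            f = _sigmoid(z[:, d : 2 * d])
            g = np.tanh(z[:, 2 * d : 3 * d])
            o = _sigmoid(z[:, 3 * d :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            cache.append((x[:, step], h, c, i, f, g, o, c_new, tanh_c))
            h, c = h_new, c_new
            out[:, step] = h
        self._cache = cache
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, t, _ = dout.shape
        d = self.d_hidden
        dx = np.zeros((b, t, self.wx.value.shape[0]))
        dh_next = np.zeros((b, d))
        dc_next = np.zeros((b, d))
        for step in range(t - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, c_new, tanh_c = self._cache[step]
            dh = dout[:, step] + dh_next
            do = dh * tanh_c
            dc = dc_next + dh * o * (1 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            self.wx.grad += xt.T @ dz
            self.wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, step] = dz @ self.wx.value.T
            dh_next = dz @ self.wh.value.T
            dc_next = dc * f
        return dx


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class Adam:
    """Adam optimiser over a list of :class:`Parameter`."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
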