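"""A compact transformer-encoder classifier for fixed-length epochs, in NumPy.

Architecture (the "Erp-Transformer"): sinusoidal positional encoding added to
the ``(seq_len, n_channels)`` input, dropout, a stack of identical encoder
blocks — multi-head self-attention (shared Q/K/V input projections plus
per-head weight matrices, scores scaled by ``num_heads**-0.5``), output
projection, dropout, residual, LayerNorm, then a two-layer position-wise
feedforward with ReLU, dropout, residual, LayerNorm — followed by flattening
and a single linear map to the two class logits.  Softmax cross-entropy is
the training loss.

All layers implement explicit ``forward``/``backward`` passes; gradients are
exact and verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["positional_encoding", "ErpTransformerNet", "Adam",
           "softmax", "softmax_cross_entropy"]


def positional_encoding(seq_len: int, dim: int) -> np.ndarray:
    """Sinusoidal position matrix ``(seq_len, dim)``.

    Entry ``(t, 2k) = sin(w_k t)`` and ``(t, 2k+1) = cos(w_k t)`` with the
    geometric frequency schedule ``w_k = 10000**(-2k/dim)``; row 0 is 0 at
    even and 1 at odd indices.
    """
    if seq_len < 1 or dim < 1:
        raise ValueError("seq_len and dim must be >= 1")
    t = np.arange(seq_len, dtype=np.float64)[:, None]
    even = np.arange(0, dim, 2, dtype=np.float64)[None, :]
    omega = 10000.0 ** (-even / dim)          # w_k = 10000^(-2k/dim)
    pe = np.zeros((seq_len, dim))
    pe[:, 0::2] = np.sin(t * omega)
    if dim > 1:
        pe[:, 1::2] = np.cos(t * omega[:, : dim // 2])
    return pe


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy and gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -float(np.mean(np.log(p[np.arange(n), y] + 1e-300)))
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


def _glorot(rng, *shape):
    fan_in, fan_out = shape[-2], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape)


class Dense:
    def __init__(self, rng, d_in, d_out, bias=True):
        self.W = Param(_glorot(rng, d_in, d_out))
        self.b = Param(np.zeros(d_out)) if bias else None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x):
        self._x = x
        y = x @ self.W.value
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, g):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        g2 = g.reshape(-1, g.shape[-1])
        self.W.grad += x2.T @ g2
        if self.b is not None:
            self.b.grad += g2.sum(axis=0)
        return g @ self.W.value.T


class Dropout:
    def __init__(self, p):
        self.p = p

    def forward(self, x, train, rng):
        if not train or self.p <= 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class LayerNorm:
    def __init__(self, dim, eps=1e-5):
        self.gamma = Param(np.ones(dim))
        self.beta = Param(np.zeros(dim))
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, g):
        xhat, inv = self._xhat, self._inv
        lead = tuple(range(g.ndim - 1))
        self.gamma.grad += (g * xhat).sum(axis=lead)
        self.beta.grad += g.sum(axis=lead)
        dxhat = g * self.gamma.value
        return inv * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        )


class MultiHeadAttention:
    """Self-attention with shared input projections and per-head maps.

    The three shared linear layers L1/L2/L3 map channels to channels; each
    head ``a`` applies its own ``W_Q/W_K/W_V`` of shape ``(dim, head_dim)``,
    the per-head attention outputs are concatenated and linearly projected
    back to ``dim``.
    """

    def __init__(self, rng, dim, num_heads, head_dim, scale):
        self.h, self.d = num_heads, head_dim
        self.scale = scale
        self.l1 = Dense(rng, dim, dim)
        self.l2 = Dense(rng, dim, dim)
        self.l3 = Dense(rng, dim, dim)
        self.WQ = Param(_glorot(rng, num_heads, dim, head_dim))
        self.WK = Param(_glorot(rng, num_heads, dim, head_dim))
        self.WV = Param(_glorot(rng, num_heads, dim, head_dim))
        self.out = Dense(rng, num_heads * head_dim, dim)

    def params(self):
        return (self.l1.params() + self.l2.params() + self.l3.params()
                + [self.WQ, self.WK, self.WV] + self.out.params())

    @staticmethod
    def _project(x, w):
        # (B,T,C) x (h,C,d) -> (B,h,T,d), via BLAS-backed tensordot
        return np.tensordot(x, w, axes=([2], [1])).transpose(0, 2, 1, 3)

    def forward(self, x):
        # x: (B, T, C)
        self._q0 = self.l1.forward(x)
        self._k0 = self.l2.forward(x)
        self._v0 = self.l3.forward(x)
        q = self._project(self._q0, self.WQ.value)
        k = self._project(self._k0, self.WK.value)
        v = self._project(self._v0, self.WV.value)
        scores = (q @ k.swapaxes(-1, -2)) * self.scale
        attn = softmax(scores)                          # rows sum to 1
        o = attn @ v                                    # (B,h,T,d)
        b, t = x.shape[0], x.shape[1]
        self._q, self._k, self._v, self._attn = q, k, v, attn
        concat = o.transpose(0, 2, 1, 3).reshape(b, t, self.h * self.d)
        return self.out.forward(concat)

    def attention_weights(self):
        """Softmax score tensor ``(B, heads, T, T)`` from the last forward."""
        return self._attn

    def _weight_grad(self, x0, dproj):
        # sum_bt x0[b,t,c] * dproj[b,h,t,d] -> (h,c,d)
        x2 = x0.reshape(-1, x0.shape[-1])               # (BT, C)
        d2 = dproj.transpose(1, 0, 2, 3).reshape(self.h, -1, self.d)
        return np.matmul(x2.T[None, :, :], d2)          # (h, C, d)

    def backward(self, g):
        b, t = g.shape[0], g.shape[1]
        dconcat = self.out.backward(g)
        do = dconcat.reshape(b, t, self.h, self.d).transpose(0, 2, 1, 3)
        dattn = do @ self._v.swapaxes(-1, -2)
        dv = self._attn.swapaxes(-1, -2) @ do
        ds = self._attn * (dattn - (dattn * self._attn).sum(axis=-1, keepdims=True))
        ds *= self.scale
        dq = ds @ self._k
        dk = ds.swapaxes(-1, -2) @ self._q
        self.WQ.grad += self._weight_grad(self._q0, dq)
        self.WK.grad += self._weight_grad(self._k0, dk)
        self.WV.grad += self._weight_grad(self._v0, dv)
        # (B,h,T,d) x (h,C,d) summed over h,d -> (B,T,C)
        dq0 = np.tensordot(dq, self.WQ.value, axes=([1, 3], [0, 2]))
        dk0 = np.tensordot(dk, self.WK.value, axes=([1, 3], [0, 2]))
        dv0 = np.tensordot(dv, self.WV.value, axes=([1, 3], [0, 2]))
        return (self.l1.backward(dq0) + self.l2.backward(dk0)
                + self.l3.backward(dv0))


class EncoderBlock:
    def __init__(self, rng, dim, num_heads, head_dim, ffn_hidden, dropout_p,
                 scale):
        self.mha = MultiHeadAttention(rng, dim, num_heads, head_dim, scale)
        self.drop1 = Dropout(dropout_p)
        self.ln1 = LayerNorm(dim)
        self.fc1 = Dense(rng, dim, ffn_hidden)
        self.relu = ReLU()
        self.fc2 = Dense(rng, ffn_hidden, dim)
        self.drop2 = Dropout(dropout_p)
        self.ln2 = LayerNorm(dim)

    def params(self):
        return (self.mha.params() + self.ln1.params() + self.fc1.params()
                + self.fc2.params() + self.ln2.params())

    def forward(self, x, train, rng):
        a = self.drop1.forward(self.mha.forward(x), train, rng)
        h1 = self.ln1.forward(x + a)
        f = self.fc2.forward(self.relu.forward(self.fc1.forward(h1)))
        f = self.drop2.forward(f, train, rng)
        return self.ln2.forward(h1 + f)

    def backward(self, g):
        dr2 = self.ln2.backward(g)
        df = self.drop2.backward(dr2)
        dh1 = dr2 + self.fc1.backward(self.relu.backward(self.fc2.backward(df)))
        dr1 = self.ln1.backward(dh1)
        da = self.drop1.backward(dr1)
        return dr1 + self.mha.backward(da)


class ErpTransformerNet:
    """Positional encoding + encoder stack + flatten + linear classifier.

    Parameters mirror the published operating point: 3 encoders, 5 heads of
    dimension equal to the channel count (35 at full scale), dropout 0.5,
    attention scores scaled by ``num_heads**-0.5``, classifier input
    ``seq_len * n_channels`` (8 960 at full scale) mapped to 2 logits.
    """

    def __init__(self, seq_len, input_dim, num_encoders=3, num_heads=5,
                 head_dim=None, ffn_hidden=64, dropout_p=0.5,
                 attention_scale="num_heads", num_classes=2,
                 use_positional_encoding=True, seed=0):
        if num_heads < 1 or num_encoders < 1:
            raise ValueError("num_heads and num_encoders must be >= 1")
        if not 0.0 <= dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        head_dim = input_dim if head_dim is None else head_dim
        if attention_scale == "num_heads":
            scale = num_heads ** -0.5
        elif attention_scale == "head_dim":
            scale = head_dim ** -0.5
        else:
            raise ValueError("attention_scale must be 'num_heads' or 'head_dim'")
        self.seq_len, self.input_dim = seq_len, input_dim
        self.num_classes = num_classes
        self.config = dict(
            seq_len=seq_len, input_dim=input_dim, num_encoders=num_encoders,
            num_heads=num_heads, head_dim=head_dim, ffn_hidden=ffn_hidden,
            dropout_p=dropout_p, attention_scale=attention_scale,
            num_classes=num_classes,
            use_positional_encoding=use_positional_encoding,
        )
        rng = np.random.default_rng(seed)
        self.pe = (positional_encoding(seq_len, input_dim)
                   if use_positional_encoding else np.zeros((seq_len, input_dim)))
        self.drop0 = Dropout(dropout_p)
        self.encoders = [
            EncoderBlock(rng, input_dim, num_heads, head_dim, ffn_hidden,
                         dropout_p, scale)
            for _ in range(num_encoders)
        ]
        self.classifier = Dense(rng, seq_len * input_dim, num_classes)

    def params(self):
        out = []
        for enc in self.encoders:
            out.extend(enc.params())
        out.extend(self.classifier.params())
        return out

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def _check_input(self, x):
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[np.newaxis]
        if x.ndim != 3 or x.shape[1:] != (self.seq_len, self.input_dim):
            raise ValueError(
                f"expected epochs of shape ({self.seq_len}, {self.input_dim}), "
                f"got {x.shape}"
            )
        return x

    def encode(self, x, train=False, rng=None):
        """Encoder-stack output ``(B, T, C)`` (dropout off unless training)."""
        x = self._check_input(x)
        h = self.drop0.forward(x + self.pe, train, rng)
        for enc in self.encoders:
            h = enc.forward(h, train, rng)
        return h

    def forward(self, x, train=False, rng=None):
        """Class logits ``(B, num_classes)``."""
        h = self.encode(x, train, rng)
        return self.classifier.forward(h.reshape(h.shape[0], -1))

    def predict_proba(self, x):
        return softmax(self.forward(x, train=False))

    def backward(self, dlogits):
        dh = self.classifier.backward(dlogits)
        dh = dh.reshape(-1, self.seq_len, self.input_dim)
        for enc in reversed(self.encoders):
            dh = enc.backward(dh)
        self.drop0.backward(dh)

    def loss_and_grad(self, x, y, rng):
        """Training-mode cross-entropy loss; accumulates parameter grads."""
        self.zero_grad()
        logits = self.forward(x, train=True, rng=rng)
        loss, dlogits = softmax_cross_entropy(logits, np.asarray(y))
        self.backward(dlogits)
        return loss

    # --- checkpointing -----------------------------------------------------
    def state_arrays(self):
        return [p.value for p in self.params()]

    def save(self, path, extra=None):
        import json
        arrays = {f"p{i}": a for i, a in enumerate(self.state_arrays())}
        if extra:
            arrays.update({f"x_{k}": v for k, v in extra.items()})
        np.savez(path, config=np.frombuffer(
            json.dumps(self.config).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path, extra_keys=()):
        import json
        with np.load(path, allow_pickle=False) as f:
            config = json.loads(bytes(f["config"]).decode())
            net = cls(**config)
            for i, p in enumerate(net.params()):
                p.value[...] = f[f"p{i}"]
            extra = {k: f[f"x_{k}"] for k in extra_keys}
        return (net, extra) if extra_keys else net


class Adam:
    """Adam optimiser over a list of :class:`Param` objects."""

    def __init__(self, params, lr=5e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
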