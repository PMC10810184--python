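"""Compact NumPy neural-network engine for the per-residue meta-predictor.

Implements exactly the layers the meta-model architecture needs -- dense
layers, ReLU, layer normalization, masked multi-head self-attention, a
post-norm transformer block -- with explicit forward/backward passes and an
Adam optimizer. Arrays are (batch, length, features) with a boolean
(batch, length) validity mask for padded positions; padded keys are
excluded from attention and padded positions carry no loss.

Everything is deterministic given the initialization seed and the batch
order, which the trainer also derives from the seed.
"""

from __future__ import annotations

import numpy as np

#: computation dtype; single precision is ample for this model size
DTYPE = np.float32


class Layer:
    """Base: layers own ``params`` and accumulate matching ``grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        limit = np.sqrt(6.0 / (d_in + d_out))  # Glorot uniform
        self.params = {
            "W": rng.uniform(-limit, limit, (d_in, d_out)).astype(DTYPE),
            "b": np.zeros(d_out, dtype=DTYPE),
        }

    def forward(self, x, mask=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        d2 = dout.reshape(-1, dout.shape[-1])
        self.grads["W"] = x2.T @ d2
        self.grads["b"] = d2.sum(axis=0)
        return dout @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, mask=None):
        self._pos = x > 0
        return x * self._pos

    def backward(self, dout):
        return dout * self._pos


class LayerNorm(Layer):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.params = {"gamma": np.ones(d, dtype=DTYPE), "beta": np.zeros(d, dtype=DTYPE)}

    def forward(self, x, mask=None):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dout):
        xhat = self._xhat
        self.grads["gamma"] = (dout * xhat).sum(axis=tuple(range(dout.ndim - 1)))
        self.grads["beta"] = dout.sum(axis=tuple(range(dout.ndim - 1)))
        dxhat = dout * self.params["gamma"]
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return (dxhat - m1 - xhat * m2) / self._std


class MultiHeadSelfAttention(Layer):
    """Scaled dot-product self-attention; padded keys are masked out."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        limit = np.sqrt(6.0 / (2 * d_model))
        for name in ("Wq", "Wk", "Wv", "Wo"):
            self.params[name] = rng.uniform(
                -limit, limit, (d_model, d_model)
            ).astype(DTYPE)
            self.params["b" + name[1]] = np.zeros(d_model, dtype=DTYPE)

    def _split(self, x):  # (B,L,D) -> (B,h,L,dh)
        b, l, _ = x.shape
        return x.reshape(b, l, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def _merge(self, x):  # (B,h,L,dh) -> (B,L,D)
        b, h, l, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(b, l, h * dh)

    def forward(self, x, mask=None):
        p = self.params
        self._x = x
        q = self._split(x @ p["Wq"] + p["bq"])
        k = self._split(x @ p["Wk"] + p["bk"])
        v = self._split(x @ p["Wv"] + p["bv"])
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(self.d_head)
        if mask is not None:
            scores = np.where(mask[:, None, None, :], scores, -1e9)
        scores -= scores.max(axis=-1, keepdims=True)
        expd = np.exp(scores)
        attn = expd / expd.sum(axis=-1, keepdims=True)
        self._q, self._k, self._v, self._attn = q, k, v, attn
        merged = self._merge(attn @ v)
        self._merged = merged
        return merged @ p["Wo"] + p["bo"]

    def backward(self, dout):
        p = self.params
        flat = lambda a: a.reshape(-1, a.shape[-1])
        self.grads["Wo"] = flat(self._merged).T @ flat(dout)
        self.grads["bo"] = flat(dout).sum(axis=0)
        d_merged = dout @ p["Wo"].T
        d_av = self._split(d_merged)
        d_attn = d_av @ self._v.transpose(0, 1, 3, 2)
        dv = self._attn.transpose(0, 1, 3, 2) @ d_av
        # softmax backward (masked entries have attn ~ 0, grads vanish)
        a = self._attn
        d_scores = a * (d_attn - (d_attn * a).sum(axis=-1, keepdims=True))
        d_scores /= np.sqrt(self.d_head)
        dq = d_scores @ self._k
        dk = d_scores.transpose(0, 1, 3, 2) @ self._q
        dq, dk, dv = map(self._merge, (dq, dk, dv))
        x2 = flat(self._x)
        dx = np.zeros_like(self._x)
        for name, dz in (("Wq", dq), ("Wk", dk), ("Wv", dv)):
            self.grads[name] = x2.T @ flat(dz)
            self.grads["b" + name[1]] = flat(dz).sum(axis=0)
            dx += dz @ p[name].T
        return dx


class TransformerBlock(Layer):
    """Post-norm block: self-attention -> feed-forward -> normalization,
    with residual connections around the attention and feed-forward units."""

    def __init__(self, d_model: int, n_heads: int, ff_hidden: int,
                 rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.ff1 = Dense(d_model, ff_hidden, rng)
        self.relu = ReLU()
        self.ff2 = Dense(ff_hidden, d_model, rng)
        self.norm = LayerNorm(d_model)
        self.children = [self.attn, self.ff1, self.ff2, self.norm]

    def forward(self, x, mask=None):
        h = x + self.attn.forward(x, mask)
        f = h + self.ff2.forward(self.relu.forward(self.ff1.forward(h)))
        return self.norm.forward(f)

    def backward(self, dout):
        df = self.norm.backward(dout)
        dh = df + self.ff1.backward(self.relu.backward(self.ff2.backward(df)))
        return dh + self.attn.backward(dh)

    def n_parameters(self) -> int:
        return sum(c.n_parameters() for c in self.children)

    def all_layers(self):
        return self.children


class Network:
    """Input projection -> transformer blocks -> reducing feed-forward head."""

    def __init__(self, n_features: int, d_model: int, n_blocks: int,
                 n_heads: int, ff_hidden: int, head_dims: tuple[int, ...],
                 seed: int = 0):
        if head_dims[0] != d_model or head_dims[-1] != 1:
            raise ValueError(
                f"head_dims must run from d_model ({d_model}) to 1, got {head_dims}"
            )
        rng = np.random.default_rng(seed)
        self.proj = Dense(n_features, d_model, rng)
        self.blocks = [
            TransformerBlock(d_model, n_heads, ff_hidden, rng)
            for _ in range(n_blocks)
        ]
        self.head: list[Layer] = []
        for d_in, d_out in zip(head_dims[:-1], head_dims[1:]):
            self.head.append(Dense(d_in, d_out, rng))
            if d_out != 1:
                self.head.append(ReLU())
        self.n_features = n_features

    def all_layers(self) -> list[Layer]:
        out: list[Layer] = [self.proj]
        for b in self.blocks:
            out.extend(b.all_layers())
        out.extend(self.head)
        return out

    def n_parameters(self) -> int:
        return sum(l.n_parameters() for l in self.all_layers())

    def forward(self, x: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        """Logits of shape (batch, length) from (batch, length, n_features)."""
        h = self.proj.forward(np.asarray(x, dtype=DTYPE))
        for block in self.blocks:
            h = block.forward(h, mask)
        for layer in self.head:
            h = layer.forward(h)
        return h[..., 0]

    def backward(self, dlogits: np.ndarray) -> None:
        d = np.asarray(dlogits, dtype=DTYPE)[..., None]
        for layer in reversed(self.head):
            d = layer.backward(d)
        for block in reversed(self.blocks):
            d = block.backward(d)
        self.proj.backward(d)

    # ---- (de)serialization ------------------------------------------------

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for l in self.all_layers() for p in l.params.values()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.all_layers():
            for name in layer.params:
                w = next(it)
                if w.shape != layer.params[name].shape:
                    raise ValueError("weight shape mismatch")
                layer.params[name] = w.astype(DTYPE)


def masked_loss_and_grad(
    logits: np.ndarray, targets: np.ndarray, mask: np.ndarray, loss: str = "bce",
    pos_weight: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Mean loss over valid positions and its gradient w.r.t. the logits.

    ``bce`` is binary cross-entropy on the logistic output (computed in the
    numerically stable logit form); ``l1`` is mean absolute error between
    the logistic output and the 0/1 target.
    """
    logits = np.asarray(logits, dtype=np.float64)
    m = mask.astype(float)
    n = m.sum()
    if n == 0:
        raise ValueError("empty mask")
    w = np.where(targets > 0.5, pos_weight, 1.0) * m
    sig = 1.0 / (1.0 + np.exp(-logits))
    if loss == "bce":
        per = np.maximum(logits, 0) - logits * targets + np.log1p(
            np.exp(-np.abs(logits))
        )
        dlogits = (sig - targets) * w / w.sum()
    elif loss == "l1":
        per = np.abs(sig - targets)
        dlogits = np.sign(sig - targets) * sig * (1 - sig) * w / w.sum()
    else:
        raise ValueError(f"unknown loss {loss!r}")
    value = float((per * w).sum() / w.sum())
    if not np.isfinite(value):
        raise FloatingPointError("non-finite loss")
    return value, dlogits


class Adam:
    def __init__(self, network: Network, lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = network.all_layers()
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]

    def step(self) -> None:
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, g in layer.grads.items():
                m[k] = self.beta1 * m[k] + (1 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1 - self.beta2) * g * g
                layer.params[k] -= (
                    self.lr * (m[k] / b1c) / (np.sqrt(v[k] / b2c) + self.eps)
                )
            layer.grads = {}
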