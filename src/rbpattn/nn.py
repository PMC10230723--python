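"""Minimal NumPy neural-network layers with explicit backward passes.

Every layer caches what its backward pass needs during ``forward`` and
accumulates parameter gradients into ``Parameter.grad`` during ``backward``.
All computation is plain NumPy, so a fixed seed gives bit-identical results
on a single device. Layers are dtype-generic; training defaults to float32,
numerical tests use float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "Conv1d",
    "BatchNorm1d",
    "LayerNorm",
    "ReLU",
    "Dropout",
    "Embedding",
    "MultiHeadAttention",
    "FeedForward",
    "TransformerBlock",
    "softmax",
    "SoftmaxCrossEntropy",
    "Adam",
]


class Parameter:
    """A learnable array plus its accumulated gradient."""

    __slots__ = ("data", "grad", "trainable", "name")

    def __init__(self, data: np.ndarray, trainable: bool = True, name: str = ""):
        self.data = np.asarray(data)
        self.grad = np.zeros_like(self.data)
        self.trainable = trainable
        self.name = name

    @property
    def shape(self):
        return self.data.shape


class Module:
    """Base class: tracks sub-modules/parameters and a training flag."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for value in vars(self).values():
            if isinstance(value, Parameter):
                out.append(value)
            elif isinstance(value, Module):
                out.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for key, value in vars(self).items():
            name = f"{prefix}{key}"
            if isinstance(value, Parameter):
                out.append((name, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(prefix=name + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{name}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{name}.{i}", item))
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def train(self, mode: bool = True):
        self.training = mode
        for value in vars(self).values():
            if isinstance(value, Module):
                value.train(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            d[name] = buf.copy()
        return d

    def named_buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out: list[tuple[str, np.ndarray]] = []
        for key, value in vars(self).items():
            name = f"{prefix}{key}"
            if isinstance(value, Module):
                out.extend(value.named_buffers(prefix=name + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_buffers(prefix=f"{name}.{i}."))
            elif key.startswith("running_") and isinstance(value, np.ndarray):
                out.append((name, value))
        return out

    def load_state_dict(self, d: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for name, arr in d.items():
            if name in params:
                params[name].data[...] = arr
            elif name in buffers:
                buffers[name][...] = arr
            else:
                raise KeyError(f"unknown parameter {name!r} in state dict")


def _he_uniform(rng: np.random.Generator, fan_in: int, shape, dtype):
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, bias: bool = True, *,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.d_in, self.d_out = d_in, d_out
        self.W = Parameter(_he_uniform(rng, d_in, (d_in, d_out), dtype))
        self.b = Parameter(np.zeros(d_out, dtype=dtype)) if bias else None
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.W.data
        if self.b is not None:
            y = y + self.b.data
        return y

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        x2 = x.reshape(-1, self.d_in)
        g2 = g.reshape(-1, self.d_out)
        self.W.grad += x2.T @ g2
        if self.b is not None:
            self.b.grad += g2.sum(axis=0)
        return g @ self.W.data.T

    def zero_(self):
        self.W.data[...] = 0.0
        if self.b is not None:
            self.b.data[...] = 0.0


class Conv1d(Module):
    """1-D convolution over the position axis with 'same' zero padding.

    Input/output layout is (batch, positions, channels); stride is 1 and the
    kernel width must be odd so position count is preserved.
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int = 3, bias: bool = True,
                 *, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for 'same' padding")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel_size
        fan_in = c_in * kernel_size
        self.W = Parameter(_he_uniform(rng, fan_in, (fan_in, c_out), dtype))
        self.b = Parameter(np.zeros(c_out, dtype=dtype)) if bias else None
        self._xcol = None
        self._in_shape = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, L, c = x.shape
        p = self.k // 2
        xp = np.zeros((n, L + 2 * p, c), dtype=x.dtype)
        xp[:, p:p + L] = x
        cols = np.concatenate([xp[:, i:i + L] for i in range(self.k)], axis=2)
        return cols  # (n, L, k*c)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[2] != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {x.shape[2]}")
        self._in_shape = x.shape
        xcol = self._im2col(x)
        self._xcol = xcol
        y = xcol @ self.W.data
        if self.b is not None:
            y = y + self.b.data
        return y

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, L, c = self._in_shape
        p = self.k // 2
        xcol2 = self._xcol.reshape(-1, self.k * self.c_in)
        g2 = g.reshape(-1, self.c_out)
        self.W.grad += xcol2.T @ g2
        if self.b is not None:
            self.b.grad += g2.sum(axis=0)
        dcol = (g @ self.W.data.T).reshape(n, L, self.k, self.c_in)
        dxp = np.zeros((n, L + 2 * p, self.c_in), dtype=g.dtype)
        for i in range(self.k):
            dxp[:, i:i + L] += dcol[:, :, i]
        return dxp[:, p:p + L]

    def zero_(self):
        self.W.data[...] = 0.0
        if self.b is not None:
            self.b.data[...] = 0.0


class BatchNorm1d(Module):
    """Batch normalization per channel over the batch x position axes."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)  # population variance for normalization
            m = x.size // x.shape[-1]
            unbiased = var * m / max(m - 1, 1)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(self.running_mean.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased).astype(self.running_var.dtype)
        else:
            mean = self.running_mean
            var = self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * invstd
        self._cache = (xhat, invstd)
        return xhat * self.gamma.data + self.beta.data

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        axes = tuple(range(g.ndim - 1))
        self.gamma.grad += (g * xhat).sum(axis=axes)
        self.beta.grad += g.sum(axis=axes)
        gx = g * self.gamma.data
        if not self.training:
            return gx * invstd
        m = g.size // g.shape[-1]
        return (invstd / m) * (m * gx
                               - gx.sum(axis=axes)
                               - xhat * (gx * xhat).sum(axis=axes))


class LayerNorm(Module):
    """Per-position standardization over the channel axis with learned
    gain gamma and bias beta: LN(z) = ((z - mu) / sqrt(sigma^2 + eps)) * gamma + beta,
    where mu and sigma^2 are the mean and population variance over the M
    channels of one position."""

    def __init__(self, channels: int, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * invstd
        self._cache = (xhat, invstd)
        return xhat * self.gamma.data + self.beta.data

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        lead = tuple(range(g.ndim - 1))
        self.gamma.grad += (g * xhat).sum(axis=lead)
        self.beta.grad += g.sum(axis=lead)
        gx = g * self.gamma.data
        mean_g = gx.mean(axis=-1, keepdims=True)
        mean_gx = (gx * xhat).mean(axis=-1, keepdims=True)
        return invstd * (gx - mean_g - xhat * mean_gx)


class ReLU(Module):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, 0.0)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return g
        return g * self._mask


class Embedding(Module):
    """Token-index lookup table; index -1 yields an all-zero row (absent/pad)."""

    def __init__(self, vocab_size: int, dim: int, *, rng: np.random.Generator,
                 trainable: bool = True, dtype=np.float32):
        super().__init__()
        self.vocab_size, self.dim = vocab_size, dim
        self.W = Parameter(
            (rng.standard_normal((vocab_size, dim)) / np.sqrt(dim)).astype(dtype),
            trainable=trainable,
        )
        self._idx = None

    def forward(self, idx: np.ndarray) -> np.ndarray:
        self._idx = idx
        out = np.zeros(idx.shape + (self.dim,), dtype=self.W.data.dtype)
        valid = idx >= 0
        out[valid] = self.W.data[idx[valid]]
        return out

    def backward(self, g: np.ndarray) -> None:
        valid = self._idx >= 0
        np.add.at(self.W.grad, self._idx[valid], g[valid])
        return None


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class MultiHeadAttention(Module):
    """Scaled dot-product multi-head self-attention.

    Per head i, softmax(q_i k_i^T / sqrt(scale)) v_i; heads are concatenated
    and output-projected. ``scale_mode`` selects the denominator: per-head
    width d/h (the convention of the original transformer) or the full model
    width d.
    """

    def __init__(self, dim: int, heads: int, *, rng: np.random.Generator,
                 scale_mode: str = "per_head", dtype=np.float32):
        super().__init__()
        if dim % heads != 0:
            raise ValueError("model width must be divisible by head count")
        if scale_mode not in ("per_head", "model"):
            raise ValueError(f"unknown scale_mode {scale_mode!r}")
        self.dim, self.heads = dim, heads
        self.d_head = dim // heads
        self.scale = np.sqrt(self.d_head if scale_mode == "per_head" else dim)
        self.Wq = Linear(dim, dim, rng=rng, dtype=dtype)
        self.Wk = Linear(dim, dim, rng=rng, dtype=dtype)
        self.Wv = Linear(dim, dim, rng=rng, dtype=dtype)
        self.Wo = Linear(dim, dim, rng=rng, dtype=dtype)
        self._cache = None

    def _split(self, x: np.ndarray) -> np.ndarray:
        n, L, _ = x.shape
        return x.reshape(n, L, self.heads, self.d_head).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        n, h, L, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(n, L, h * dh)

    def attention_weights(self, x: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        """Forward pass returning only the (n, heads, L, L) softmax weights."""
        self.forward(x, mask)
        return self._cache[3]

    def forward(self, x: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        n, L, _ = x.shape
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != (n, L):
                raise ValueError("mask must have shape (batch, positions)")
            if not mask.any(axis=1).all():
                raise ValueError("a sequence with all positions masked has no attention keys")
        q = self._split(self.Wq.forward(x))
        k = self._split(self.Wk.forward(x))
        v = self._split(self.Wv.forward(x))
        scores = q @ k.transpose(0, 1, 3, 2) / self.scale
        if mask is not None:
            scores = np.where(mask[:, None, None, :], scores, -1e30)
        A = softmax(scores, axis=-1)
        ctx = A @ v
        merged = self._merge(ctx)
        out = self.Wo.forward(merged)
        self._cache = (q, k, v, A, mask)
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        q, k, v, A, mask = self._cache
        dmerged = self.Wo.backward(g)
        dctx = self._split(dmerged)
        dA = dctx @ v.transpose(0, 1, 3, 2)
        dv = A.transpose(0, 1, 3, 2) @ dctx
        # softmax backward per row
        ds = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        ds /= self.scale
        dq = ds @ k
        dk = ds.transpose(0, 1, 3, 2) @ q
        dx = self.Wq.backward(self._merge(dq))
        dx = dx + self.Wk.backward(self._merge(dk))
        dx = dx + self.Wv.backward(self._merge(dv))
        return dx


class FeedForward(Module):
    """Position-wise two-layer perceptron with ReLU."""

    def __init__(self, dim: int, hidden: int, *, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.lin1 = Linear(dim, hidden, rng=rng, dtype=dtype)
        self.act = ReLU()
        self.lin2 = Linear(hidden, dim, rng=rng, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.lin2.forward(self.act.forward(self.lin1.forward(x)))

    def backward(self, g: np.ndarray) -> np.ndarray:
        return self.lin1.backward(self.act.backward(self.lin2.backward(g)))


class TransformerBlock(Module):
    """One residual attention block, wired pre-norm or post-norm.

    pre:  p = x + Drop(MHA(LN1(x)));  out = p + Drop(FFN(LN2(p)))
    post: y = LN1(x + Drop(MHA(x)));  out = LN2(y + Drop(FFN(y)))
    """

    def __init__(self, dim: int, heads: int, ffn_dim: int, norm_style: str = "pre",
                 dropout: float = 0.0, *, rng: np.random.Generator,
                 scale_mode: str = "per_head", dtype=np.float32):
        super().__init__()
        if norm_style not in ("pre", "post"):
            raise ValueError(f"norm_style must be 'pre' or 'post', got {norm_style!r}")
        self.norm_style = norm_style
        self.ln1 = LayerNorm(dim, dtype=dtype)
        self.attn = MultiHeadAttention(dim, heads, rng=rng, scale_mode=scale_mode,
                                       dtype=dtype)
        self.drop1 = Dropout(dropout, rng)
        self.ln2 = LayerNorm(dim, dtype=dtype)
        self.ffn = FeedForward(dim, ffn_dim, rng=rng, dtype=dtype)
        self.drop2 = Dropout(dropout, rng)

    def zero_init_sublayer_outputs(self):
        """Zero the attention output projection and the second FFN map.

        A pre-norm block so initialized is exactly the identity map; the
        matched post-norm block reduces to two layer norms.
        """
        self.attn.Wo.zero_()
        self.ffn.lin2.zero_()

    def forward(self, x: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        if self.norm_style == "pre":
            p = x + self.drop1.forward(self.attn.forward(self.ln1.forward(x), mask))
            return p + self.drop2.forward(self.ffn.forward(self.ln2.forward(p)))
        y = self.ln1.forward(x + self.drop1.forward(self.attn.forward(x, mask)))
        return self.ln2.forward(y + self.drop2.forward(self.ffn.forward(y)))

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self.norm_style == "pre":
            dp = g + self.ln2.backward(self.ffn.backward(self.drop2.backward(g)))
            return dp + self.ln1.backward(self.attn.backward(self.drop1.backward(dp)))
        dy = self.ln2.backward(g)
        dy = dy + self.ffn.backward(self.drop2.backward(dy))
        dx = self.ln1.backward(dy)
        return dx + self.attn.backward(self.drop1.backward(dx))


class SoftmaxCrossEntropy:
    """Mean cross-entropy over a batch of logits against integer labels."""

    def __init__(self):
        self._probs = None
        self._labels = None

    def forward(self, logits: np.ndarray, labels: np.ndarray) -> float:
        probs = softmax(logits, axis=-1)
        self._probs = probs
        self._labels = labels
        n = logits.shape[0]
        eps = np.finfo(probs.dtype).tiny
        return float(-np.log(probs[np.arange(n), labels] + eps).mean())

    def backward(self) -> np.ndarray:
        probs, labels = self._probs, self._labels
        n = probs.shape[0]
        g = probs.copy()
        g[np.arange(n), labels] -= 1.0
        return g / n


class Adam:
    """Adam with L2-style weight decay added to the gradient."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = [p for p in params if p.trainable]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad.astype(np.float64)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data -= (self.lr * update).astype(p.data.dtype)
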