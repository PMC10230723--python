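"""Self-attention sequence classifier with pre-norm residual wiring.

The stack consumes the fused per-position feature z and applies residual
attention blocks. Pre-norm wiring normalizes sub-layer *inputs*:

    p   = z + MHA(LN(z))
    z_s = p + FFN(LN(p))

so a block whose sub-layer output projections are zero is exactly the
identity map, and the loss gradient reaches every block input through an
additive identity path. The post-norm variant (residual addition followed by
layer normalization) is kept for ablation. Classification is mask-aware mean
pooling, an affine map to two logits, and a softmax.

Functional single-example ops (``layer_norm``, ``multi_head_attention``,
``prenorm_block``, ``postnorm_block``, ``classify``) expose the same
computations for direct inspection and testing; the classes are what
training uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import LayerNorm, MultiHeadAttention, TransformerBlock, softmax


@dataclass
class LayerNormParams:
    """gamma/beta/eps of one layer norm over M channels."""

    gamma: np.ndarray
    beta: np.ndarray
    eps: float = 1e-5

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=np.float64)
        self.beta = np.asarray(self.beta, dtype=np.float64)
        if self.gamma.shape != self.beta.shape or self.eps <= 0:
            raise ValueError("gamma/beta must match and eps must be positive")


def layer_norm(z: np.ndarray, params: LayerNormParams) -> np.ndarray:
    """((z - mu) / sqrt(sigma^2 + eps)) * gamma + beta, with mu and the
    population variance taken over the channel (last) axis independently per
    position."""
    z = np.asarray(z, dtype=np.float64)
    mu = z.mean(axis=-1, keepdims=True)
    var = z.var(axis=-1, keepdims=True)
    return (z - mu) / np.sqrt(var + params.eps) * params.gamma + params.beta


def multi_head_attention(z: np.ndarray, params: MultiHeadAttention,
                         mask: np.ndarray | None = None) -> np.ndarray:
    """Functional wrapper: run one (L, d) matrix through an attention module
    (padded keys excluded from every softmax)."""
    z = np.asarray(z)
    single = z.ndim == 2
    if single:
        z = z[None]
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)[None]
    out = params.forward(z, mask)
    return out[0] if single else out


def prenorm_block(z: np.ndarray, block: TransformerBlock,
                  mask: np.ndarray | None = None) -> np.ndarray:
    """p = z + MHA(LN(z)); z_s = p + FFN(LN(p))."""
    if block.norm_style != "pre":
        raise ValueError("block is not wired pre-norm")
    return _run_block(z, block, mask)


def postnorm_block(x: np.ndarray, block: TransformerBlock,
                   mask: np.ndarray | None = None) -> np.ndarray:
    """y = LN(x + MHA(x)); out = LN(y + FFN(y)) — residual addition followed
    by layer normalization, per sub-layer."""
    if block.norm_style != "post":
        raise ValueError("block is not wired post-norm")
    return _run_block(x, block, mask)


def _run_block(z, block, mask):
    z = np.asarray(z)
    single = z.ndim == 2
    if single:
        z = z[None]
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)[None]
    out = block.forward(z, mask)
    return out[0] if single else out


class ClassifierHead(nn.Module):
    """Mask-aware pooling over positions, affine map to 2 logits, softmax."""

    def __init__(self, dim: int, pooling: str = "mean", *,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        if pooling not in ("mean", "max"):
            raise ValueError("pooling must be 'mean' or 'max'")
        self.pooling = pooling
        self.out = nn.Linear(dim, 2, rng=rng, dtype=dtype)
        self._cache = None

    def forward(self, z: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        n, L, d = z.shape
        if mask is None:
            mask = np.ones((n, L), dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        counts = mask.sum(axis=1)
        if (counts == 0).any():
            raise ValueError("cannot pool a sequence whose positions are all masked")
        w = mask.astype(z.dtype)
        if self.pooling == "mean":
            pooled = (z * w[..., None]).sum(axis=1) / counts[:, None]
            self._cache = (w, counts, z.shape)
        else:
            zm = np.where(w[..., None] > 0, z, -np.inf)
            arg = zm.argmax(axis=1)
            pooled = np.take_along_axis(z, arg[:, None, :], axis=1)[:, 0, :]
            self._cache = (arg, None, z.shape)
        return self.out.forward(pooled)

    def backward(self, g_logits: np.ndarray) -> np.ndarray:
        gp = self.out.backward(g_logits)
        if self.pooling == "mean":
            w, counts, shape = self._cache
            return (w[..., None] * gp[:, None, :]) / counts[:, None, None]
        arg, _, shape = self._cache
        gz = np.zeros(shape, dtype=gp.dtype)
        np.put_along_axis(gz, arg[:, None, :], gp[:, None, :], axis=1)
        return gz


def classify(z_s: np.ndarray, head: ClassifierHead,
             mask: np.ndarray | None = None) -> np.ndarray:
    """Probability pair(s) for fused features (L, d) or a batch (N, L, d)."""
    z_s = np.asarray(z_s)
    single = z_s.ndim == 2
    if single:
        z_s = z_s[None]
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)[None]
    probs = softmax(head.forward(z_s, mask), axis=-1)
    return probs[0] if single else probs


class TransformerEncoder(nn.Module):
    """A stack of residual attention blocks (plus a final layer norm when
    wired pre-norm, the standard closing step for pre-norm stacks).

    ``forward(..., collect=True)`` records each block's input so a later
    ``backward`` can report the loss gradient at every depth.
    """

    def __init__(self, dim: int, heads: int, ffn_dim: int, blocks: int,
                 norm_style: str = "pre", dropout: float = 0.0, *,
                 rng: np.random.Generator, scale_mode: str = "per_head",
                 dtype=np.float32, final_norm: bool | None = None):
        super().__init__()
        self.norm_style = norm_style
        self.blocks = [
            TransformerBlock(dim, heads, ffn_dim, norm_style, dropout,
                             rng=rng, scale_mode=scale_mode, dtype=dtype)
            for _ in range(blocks)
        ]
        use_final = (norm_style == "pre") if final_norm is None else final_norm
        self.final_ln = LayerNorm(dim, dtype=dtype) if use_final else None
        self.block_input_grads: list[np.ndarray] | None = None
        self.output_grad: np.ndarray | None = None

    def zero_init_sublayer_outputs(self):
        for b in self.blocks:
            b.zero_init_sublayer_outputs()

    def forward(self, z: np.ndarray, mask: np.ndarray | None = None,
                collect: bool = False) -> np.ndarray:
        self._collect = collect
        for b in self.blocks:
            z = b.forward(z, mask)
        self._pre_final = z
        if self.final_ln is not None:
            z = self.final_ln.forward(z)
        return z

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self.final_ln is not None:
            g = self.final_ln.backward(g)
        self.output_grad = g
        grads = []
        for b in reversed(self.blocks):
            g = b.backward(g)
            grads.append(g)
        self.block_input_grads = grads[::-1]  # index l = gradient at block l input
        return g
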