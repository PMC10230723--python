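"""Feature-encoding module: unify the three descriptor matrices into one
fused per-position representation.

Each descriptor branch applies a same-length 1-D convolution, batch
normalization over the batch x position axes, and ReLU, mapping its own
channel count to a shared width C_u. The branch outputs are concatenated in
fixed order (knfp, seq2vec, kmer_context) and projected to the model width d
by a 1x1 convolution (a per-position affine map). Disabled branches
contribute zero matrices so every ablation configuration keeps identical
downstream shapes.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .descriptors import DESCRIPTOR_NAMES, DescriptorMatrix


class EncoderBranch(nn.Module):
    """Conv1d -> BatchNorm1d -> ReLU for one descriptor."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int = 3, *,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.conv = nn.Conv1d(c_in, c_out, kernel_size, rng=rng, dtype=dtype)
        self.bn = nn.BatchNorm1d(c_out, dtype=dtype)
        self.act = nn.ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[-1] != self.c_in:
            raise ValueError(
                f"branch expects {self.c_in} channels, got {x.shape[-1]}")
        return self.act.forward(self.bn.forward(self.conv.forward(x)))

    def backward(self, g: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.bn.backward(self.act.backward(g)))


def encode_descriptor(m: DescriptorMatrix | np.ndarray,
                      branch: EncoderBranch) -> np.ndarray:
    """Run one descriptor matrix (or a (N, L, C) batch) through a branch."""
    x = m.data if isinstance(m, DescriptorMatrix) else np.asarray(m)
    single = x.ndim == 2
    if single:
        x = x[None]
    y = branch.forward(x.astype(branch.conv.W.data.dtype))
    return y[0] if single else y


class FusionEncoder(nn.Module):
    """All three branches plus the 1x1 fusion convolution.

    ``channels`` maps descriptor name -> input channel count; ``enabled``
    selects the active subset (ablations) — disabled branches are replaced by
    zero matrices of the right shape.
    """

    def __init__(self, channels: dict[str, int], c_u: int = 128, dim: int = 128,
                 kernel_size: int = 3, enabled: tuple[str, ...] = DESCRIPTOR_NAMES,
                 *, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        unknown = set(enabled) - set(DESCRIPTOR_NAMES)
        if unknown:
            raise ValueError(f"unknown descriptors: {sorted(unknown)}")
        self.enabled = tuple(d for d in DESCRIPTOR_NAMES if d in enabled)
        if not self.enabled:
            raise ValueError("at least one descriptor must be enabled")
        self.c_u = c_u
        self.branches = {
            name: EncoderBranch(channels[name], c_u, kernel_size, rng=rng, dtype=dtype)
            for name in DESCRIPTOR_NAMES
        }
        # keep branches discoverable by Module.parameters()
        self.branch_knfp = self.branches["knfp"]
        self.branch_seq2vec = self.branches["seq2vec"]
        self.branch_kmer_context = self.branches["kmer_context"]
        self.fusion = nn.Linear(3 * c_u, dim, rng=rng, dtype=dtype)
        self._shapes = None

    def parameters(self):
        params = []
        for name in self.enabled:
            params.extend(self.branches[name].parameters())
        params.extend(self.fusion.parameters())
        return params

    def forward(self, inputs: dict[str, np.ndarray]) -> np.ndarray:
        """``inputs`` maps descriptor name -> (N, L, C) array for each
        enabled descriptor; returns the fused (N, L, d) feature."""
        ref = inputs[self.enabled[0]]
        n, L = ref.shape[0], ref.shape[1]
        parts = []
        for name in DESCRIPTOR_NAMES:
            if name in self.enabled:
                x = inputs[name]
                if x.shape[:2] != (n, L):
                    raise ValueError(
                        f"descriptor {name!r} has positions {x.shape[:2]}, "
                        f"expected {(n, L)}")
                parts.append(self.branches[name].forward(
                    x.astype(self.fusion.W.data.dtype)))
            else:
                parts.append(np.zeros((n, L, self.c_u),
                                      dtype=self.fusion.W.data.dtype))
        cat = np.concatenate(parts, axis=2)
        self._shapes = (n, L)
        return self.fusion.forward(cat)

    def backward(self, g: np.ndarray) -> dict[str, np.ndarray]:
        """Backpropagate; returns the gradient at each enabled branch input
        (needed by the trainable k-mer embedding table upstream)."""
        dcat = self.fusion.backward(g)
        input_grads: dict[str, np.ndarray] = {}
        for j, name in enumerate(DESCRIPTOR_NAMES):
            if name in self.enabled:
                sl = dcat[:, :, j * self.c_u:(j + 1) * self.c_u]
                input_grads[name] = self.branches[name].backward(sl)
        return input_grads


def fuse(branches: list[np.ndarray], fusion: nn.Linear) -> np.ndarray:
    """Channel-wise concatenation (knfp, seq2vec, kmer_context order) followed
    by the 1x1 fusion convolution."""
    Ls = {b.shape[-2] for b in branches}
    if len(Ls) != 1:
        raise ValueError(f"branches disagree on position count: {sorted(Ls)}")
    return fusion.forward(np.concatenate(branches, axis=-1))
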