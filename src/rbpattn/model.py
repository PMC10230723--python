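"""End-to-end classifier: descriptor branches -> fusion -> attention stack ->
softmax head, with a single configuration object and checkpointing."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from . import nn
from .descriptors import DESCRIPTOR_NAMES
from .fusion_encoder import FusionEncoder
from .seq_transformer import ClassifierHead, TransformerEncoder


@dataclass
class ModelConfig:
    """Structural hyperparameters.

    Attention blocks follow the pre-norm wiring by default; ``norm_style``
    switches to post-norm for ablation. ``positional`` adds a learned
    per-position embedding to the fused feature (scaled dot-product attention
    alone is position-agnostic). ``attn_scale`` picks the softmax scaling
    denominator: per-head width d/h (default) or the full model width d.
    """

    length: int = 101
    descriptors: tuple[str, ...] = DESCRIPTOR_NAMES
    seq2vec_dim: int = 64
    context_dim: int = 64
    context_k: int = 3
    window_width: int = 10
    window_stride: int = 1
    encoder_channels: int = 64
    kernel_size: int = 7
    dim: int = 64
    heads: int = 8
    blocks: int = 2
    ffn_dim: int = 256
    norm_style: str = "pre"
    positional: bool = True
    dropout: float = 0.1
    attn_scale: str = "per_head"
    pooling: str = "mean"
    context_learnable: bool = True
    residual_zero_init: bool = True
    seed: int = 0

    def __post_init__(self):
        self.descriptors = tuple(self.descriptors)
        unknown = set(self.descriptors) - set(DESCRIPTOR_NAMES)
        if unknown:
            raise ValueError(f"unknown descriptors: {sorted(unknown)}")
        if not self.descriptors:
            raise ValueError("at least one descriptor must be enabled")
        if self.dim % self.heads:
            raise ValueError("dim must be divisible by heads")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        return cls(**json.loads(text))


class SequenceClassifier(nn.Module):
    """The full network. ``forward`` takes a featurized batch dict with keys

    * ``knfp``:    (N, L, 3) float
    * ``seq2vec``: (N, L, D_s) float
    * ``tokens``:  (N, L) int k-mer indices, -1 at absent positions
    * ``mask``:    (N, L) bool, True at real (attendable, poolable) positions
    """

    def __init__(self, cfg: ModelConfig, dtype=np.float32):
        super().__init__()
        self.cfg = cfg
        self.dtype = dtype
        rng = np.random.default_rng(cfg.seed)
        self.context_table = nn.Embedding(4 ** cfg.context_k + 1, cfg.context_dim,
                                          rng=rng, trainable=cfg.context_learnable,
                                          dtype=dtype)
        channels = {"knfp": 3, "seq2vec": cfg.seq2vec_dim,
                    "kmer_context": cfg.context_dim}
        self.encoder = FusionEncoder(channels, cfg.encoder_channels, cfg.dim,
                                     cfg.kernel_size, enabled=cfg.descriptors,
                                     rng=rng, dtype=dtype)
        if cfg.positional:
            self.pos_embed = nn.Parameter(
                (rng.standard_normal((cfg.length, cfg.dim)) * 0.02).astype(dtype))
        else:
            self.pos_embed = None
        self.transformer = TransformerEncoder(
            cfg.dim, cfg.heads, cfg.ffn_dim, cfg.blocks, cfg.norm_style,
            cfg.dropout, rng=rng, scale_mode=cfg.attn_scale, dtype=dtype)
        if cfg.residual_zero_init:
            # start every block as the identity: residual branches fade in
            self.transformer.zero_init_sublayer_outputs()
        self.head = ClassifierHead(cfg.dim, cfg.pooling, rng=rng, dtype=dtype)
        self._dropout_rng = rng  # dropout layers share the model generator

    def parameters(self):
        params = []
        if "kmer_context" in self.cfg.descriptors:
            params.extend(self.context_table.parameters())
        params.extend(self.encoder.parameters())
        if self.pos_embed is not None:
            params.append(self.pos_embed)
        params.extend(self.transformer.parameters())
        params.extend(self.head.parameters())
        return params

    def import_context_table(self, matrix: np.ndarray, freeze: bool = True):
        """Install a precomputed per-token embedding table (4^k + 1 rows:
        all k-mers in lexicographic order, then UNK)."""
        if matrix.shape != self.context_table.W.data.shape:
            raise ValueError(
                f"context table must be {self.context_table.W.data.shape}, "
                f"got {matrix.shape}")
        self.context_table.W.data[...] = matrix.astype(self.dtype)
        self.context_table.W.trainable = not freeze

    def forward(self, batch: dict[str, np.ndarray]) -> np.ndarray:
        """Return (N, 2) logits."""
        mask = np.asarray(batch["mask"], dtype=bool)
        inputs: dict[str, np.ndarray] = {}
        if "knfp" in self.cfg.descriptors:
            inputs["knfp"] = batch["knfp"]
        if "seq2vec" in self.cfg.descriptors:
            inputs["seq2vec"] = batch["seq2vec"]
        if "kmer_context" in self.cfg.descriptors:
            inputs["kmer_context"] = self.context_table.forward(batch["tokens"])
        z = self.encoder.forward(inputs)
        if self.pos_embed is not None:
            z = z + self.pos_embed.data
        z = self.transformer.forward(z, mask)
        self._mask = mask
        return self.head.forward(z, mask)

    def backward(self, g_logits: np.ndarray) -> None:
        g = self.head.backward(g_logits)
        g = self.transformer.backward(g)
        if self.pos_embed is not None:
            self.pos_embed.grad += g.sum(axis=0)
        input_grads = self.encoder.backward(g)
        if "kmer_context" in self.cfg.descriptors:
            self.context_table.backward(input_grads["kmer_context"])
        return None

    def predict_proba(self, batch: dict[str, np.ndarray],
                      chunk: int = 256) -> np.ndarray:
        """Positive/negative class probabilities in eval mode, chunked."""
        self.eval()
        n = batch["mask"].shape[0]
        outs = []
        for s in range(0, n, chunk):
            sub = {k: v[s:s + chunk] for k, v in batch.items()}
            outs.append(nn.softmax(self.forward(sub), axis=-1))
        return np.concatenate(outs, axis=0)

    # -- checkpointing ----------------------------------------------------
    def save(self, path, config_sidecar: str | None = None):
        np.savez(path, **self.state_dict())
        if config_sidecar:
            with open(config_sidecar, "w") as fh:
                fh.write(self.cfg.to_json())

    @classmethod
    def load(cls, path, config_path) -> "SequenceClassifier":
        with open(config_path) as fh:
            cfg = ModelConfig.from_json(fh.read())
        model = cls(cfg)
        z = np.load(path, allow_pickle=False)
        model.load_state_dict({k: z[k] for k in z.files})
        return model
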