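"""Training protocol, metrics, stability studies, gradient-depth profiling
and ablations.

The optimizer protocol: Adam with weight decay 3e-4, batch size 64, initial
learning rate 3e-3 decaying to one-tenth every two epochs, cross-entropy over
the two-class softmax, stratified 80/20 split. Metrics are ACC, AUC (the
Mann-Whitney probability that a random positive outscores a random negative,
mid-rank ties), precision and recall at threshold 0.5.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (accuracy_score, precision_score, recall_score,
                             roc_auc_score)

from .descriptors import knfp_encode, token_index_matrix, tokenize_window
from .model import ModelConfig, SequenceClassifier
from .nn import Adam, SoftmaxCrossEntropy
from .seq2vec import Seq2VecModel, train_seq2vec
from .sequence_io import (LabeledDataset, RNASequence, split_dataset,
                          split_hash, standardize_length)


@dataclass
class TrainingConfig:
    """The published optimizer protocol plus the run seed."""

    weight_decay: float = 3e-4
    batch_size: int = 64
    initial_rate: float = 3e-3
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 2
    epochs: int = 10
    seed: int = 42
    train_frac: float = 0.8
    clip_norm: float | None = 1.0
    seq2vec_epochs: int = 20
    seq2vec_window: int = 5

    def __post_init__(self):
        if self.batch_size < 1 or self.initial_rate <= 0 or self.weight_decay < 0:
            raise ValueError("rates must be positive and batch_size >= 1")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TrainingConfig":
        return cls(**json.loads(text))


@dataclass
class MetricsReport:
    """ACC, AUC, precision and recall for one evaluation."""

    acc: float
    auc: float
    precision: float
    recall: float
    n_pos: int
    n_neg: int
    threshold: float = 0.5
    precision_defined: bool = True
    auc_defined: bool = True

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GradientDepthProfile:
    """Loss gradient at every block input, plus at the stack output."""

    norm_style: str
    block_input_grad_norms: list[float]
    output_grad_norm: float
    block_input_grads: list[np.ndarray] = field(repr=False, default_factory=list)
    output_grad: np.ndarray | None = field(repr=False, default=None)
    finite: bool = True


def lr_at_epoch(e: int, cfg: TrainingConfig) -> float:
    """initial_rate * decay_factor^floor(e / decay_every): tenfold decay every
    two epochs under the defaults."""
    if e < 0:
        raise ValueError("epoch index must be >= 0")
    return cfg.initial_rate * cfg.lr_decay_factor ** (e // cfg.lr_decay_every)


class Featurizer:
    """Turns sequences into the model's input tensors.

    ``fit`` standardizes lengths, builds the sliding-window corpus from the
    *training* sequences and trains the PV-DM embedding model on it (no
    external corpus is used); ``transform`` computes KNFP, embedding-lookup
    and token-index tensors for any sequence set. Windows unseen in training
    map to zero rows.
    """

    def __init__(self, cfg: ModelConfig, train_cfg: TrainingConfig):
        self.cfg = cfg
        self.train_cfg = train_cfg
        self.seq2vec: Seq2VecModel | None = None

    def _standardize(self, seqs) -> list[RNASequence]:
        return [standardize_length(s, self.cfg.length) for s in seqs]

    def fit(self, train_seqs) -> "Featurizer":
        seqs = self._standardize(train_seqs)
        corpus = [tokenize_window(s, self.cfg.window_width, self.cfg.window_stride)
                  for s in seqs]
        corpus = [ws for ws in corpus if ws.words]
        if "seq2vec" in self.cfg.descriptors:
            self.seq2vec = train_seq2vec(
                corpus, dim=self.cfg.seq2vec_dim,
                window=self.train_cfg.seq2vec_window,
                epochs=self.train_cfg.seq2vec_epochs,
                seed=self.train_cfg.seed,
                width=self.cfg.window_width, stride=self.cfg.window_stride)
        return self

    def transform(self, seqs) -> dict[str, np.ndarray]:
        from .descriptors import embed_sequence

        seqs = self._standardize(seqs)
        n, L = len(seqs), self.cfg.length
        out: dict[str, np.ndarray] = {
            "mask": np.stack([s.valid_mask() for s in seqs]) if n else
                    np.zeros((0, L), dtype=bool),
        }
        if "knfp" in self.cfg.descriptors:
            out["knfp"] = (np.stack([knfp_encode(s).data for s in seqs])
                           if n else np.zeros((0, L, 3)))
        if "seq2vec" in self.cfg.descriptors:
            if self.seq2vec is None:
                raise RuntimeError("featurizer not fitted (seq2vec missing)")
            out["seq2vec"] = (np.stack(
                [embed_sequence(self.seq2vec, s, self.cfg.window_width,
                                self.cfg.window_stride).data for s in seqs])
                if n else np.zeros((0, L, self.cfg.seq2vec_dim)))
        if "kmer_context" in self.cfg.descriptors:
            out["tokens"] = (np.stack(
                [token_index_matrix(s, self.cfg.context_k) for s in seqs])
                if n else np.zeros((0, L), dtype=np.int64))
        return out


class TrainingDivergedError(RuntimeError):
    pass


def train(model: SequenceClassifier, features: dict[str, np.ndarray],
          labels: np.ndarray, cfg: TrainingConfig) -> list[dict]:
    """Minimize cross-entropy with Adam under the step-decay schedule.

    Returns the per-epoch history (mean loss plus training ACC/AUC computed
    from the scores accumulated over that epoch). A fixed seed reproduces the
    history bit-for-bit on a single device.
    """
    labels = np.asarray(labels, dtype=np.int64)
    n = labels.size
    if n == 0:
        raise ValueError("empty training set")
    opt = Adam(model.parameters(), lr=cfg.initial_rate,
               weight_decay=cfg.weight_decay)
    loss_fn = SoftmaxCrossEntropy()
    rng = np.random.default_rng(cfg.seed)
    history: list[dict] = []
    model.train()
    for epoch in range(cfg.epochs):
        opt.lr = lr_at_epoch(epoch, cfg)
        order = rng.permutation(n)
        losses, all_scores, all_labels = [], [], []
        for s in range(0, n, cfg.batch_size):
            sel = order[s:s + cfg.batch_size]
            batch = {k: v[sel] for k, v in features.items()}
            logits = model.forward(batch)
            loss = loss_fn.forward(logits, labels[sel])
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss {loss!r} at epoch {epoch}, step {s // cfg.batch_size}")
            opt.zero_grad()
            model.backward(loss_fn.backward())
            if cfg.clip_norm is not None:
                _clip_global_norm(opt.params, cfg.clip_norm)
            opt.step()
            losses.append(loss)
            probs = _stable_probs(logits)
            all_scores.append(probs)
            all_labels.append(labels[sel])
        scores = np.concatenate(all_scores)
        ep_labels = np.concatenate(all_labels)
        report = compute_metrics(ep_labels, scores)
        history.append({"epoch": epoch, "lr": opt.lr,
                        "loss": float(np.mean(losses)),
                        "train_acc": report.acc, "train_auc": report.auc})
        model.train()
    return history


def _clip_global_norm(params, max_norm: float) -> None:
    total = np.sqrt(sum(float((p.grad.astype(np.float64) ** 2).sum())
                        for p in params))
    if total > max_norm:
        scale = max_norm / total
        for p in params:
            p.grad[...] = (p.grad * scale).astype(p.grad.dtype)


def _stable_probs(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return (e[:, 1] / e.sum(axis=1)).astype(np.float64)


def compute_metrics(labels: np.ndarray, scores: np.ndarray,
                    threshold: float = 0.5) -> MetricsReport:
    """ACC/precision/recall at the threshold; AUC as the Mann-Whitney rank
    statistic with mid-rank tie handling. With single-class labels the AUC is
    undefined (reported as nan with ``auc_defined=False``); precision with no
    positive predictions is reported as 0 with ``precision_defined=False``."""
    labels = np.asarray(labels, dtype=np.int64)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    preds = (scores >= threshold).astype(np.int64)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    acc = float(accuracy_score(labels, preds))
    recall = float(recall_score(labels, preds, zero_division=0))
    precision_defined = bool(preds.sum() > 0)
    precision = float(precision_score(labels, preds, zero_division=0))
    auc_defined = n_pos > 0 and n_neg > 0
    auc = float(roc_auc_score(labels, scores)) if auc_defined else float("nan")
    return MetricsReport(acc=acc, auc=auc, precision=precision, recall=recall,
                         n_pos=n_pos, n_neg=n_neg, threshold=threshold,
                         precision_defined=precision_defined,
                         auc_defined=auc_defined)


def run_experiment(ds: LabeledDataset, model_cfg: ModelConfig,
                   train_cfg: TrainingConfig) -> dict:
    """Full protocol on one dataset: stratified 80/20 split, featurize (the
    embedding model is trained on the train split only), train, evaluate on
    the held-out part."""
    train_ds, test_ds = split_dataset(ds, train_cfg.train_frac, train_cfg.seed)
    feat = Featurizer(model_cfg, train_cfg).fit(train_ds.records)
    X_train = feat.transform(train_ds.records)
    X_test = feat.transform(test_ds.records)
    model_cfg = dataclasses.replace(model_cfg, seed=train_cfg.seed)
    model = SequenceClassifier(model_cfg)
    history = train(model, X_train, train_ds.labels(), train_cfg)
    scores = model.predict_proba(X_test)[:, 1]
    report = compute_metrics(test_ds.labels(), scores)
    return {"model": model, "featurizer": feat, "history": history,
            "report": report, "scores": scores,
            "train_hash": split_hash(train_ds), "test_hash": split_hash(test_ds),
            "test_labels": test_ds.labels()}


def stability_run(ds: LabeledDataset, model_cfg: ModelConfig,
                  train_cfg: TrainingConfig, n_runs: int = 10) -> dict:
    """Retrain with seeds seed+0 .. seed+n_runs-1 on fresh splits; report
    per-run metrics and the AUC dispersion."""
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    reports: list[MetricsReport] = []
    for i in range(n_runs):
        cfg_i = dataclasses.replace(train_cfg, seed=train_cfg.seed + i)
        reports.append(run_experiment(ds, model_cfg, cfg_i)["report"])
    aucs = np.array([r.auc for r in reports])
    return {"reports": reports, "aucs": aucs,
            "auc_mean": float(aucs.mean()), "auc_std": float(aucs.std(ddof=1))}


def gradient_depth_profile(model: SequenceClassifier,
                           batch: dict[str, np.ndarray],
                           labels: np.ndarray) -> GradientDepthProfile:
    """Backpropagate the cross-entropy loss of one batch and record the
    gradient of the loss with respect to every attention-block input.

    Under pre-norm wiring with zero-initialized sub-layer output projections
    the recorded gradients are all exactly equal to the gradient at the stack
    output — the additive identity term of the pre-norm gradient expansion;
    under post-norm each layer-norm Jacobian reshapes them.
    """
    model.eval()  # deterministic forward (dropout off, running BN stats)
    loss_fn = SoftmaxCrossEntropy()
    logits = model.forward(batch)
    loss_fn.forward(logits, np.asarray(labels, dtype=np.int64))
    model.zero_grad()
    model.backward(loss_fn.backward())
    grads = model.transformer.block_input_grads
    out_grad = model.transformer.output_grad
    norms = [float(np.linalg.norm(g)) for g in grads]
    finite = bool(np.isfinite(norms).all() and np.isfinite(out_grad).all())
    return GradientDepthProfile(
        norm_style=model.cfg.norm_style,
        block_input_grad_norms=norms,
        output_grad_norm=float(np.linalg.norm(out_grad)),
        block_input_grads=grads, output_grad=out_grad, finite=finite)


ABLATION_AXES = ("norm_style", "descriptor")


def ablate(ds: LabeledDataset, model_cfg: ModelConfig, train_cfg: TrainingConfig,
           axis: str) -> pd.DataFrame:
    """Matched-configuration comparison differing only on one axis.

    ``norm_style`` trains pre vs post (2 rows); ``descriptor`` trains each
    single descriptor and the fused set (4 rows). All rows share the seed and
    the split (identical split hashes) so differences are attributable to the
    axis alone. The comparison is reported, never asserted: these are
    stochastic claims.
    """
    if axis not in ABLATION_AXES:
        raise ValueError(f"axis must be one of {ABLATION_AXES}")
    if axis == "norm_style":
        variants = [("pre", {"norm_style": "pre"}),
                    ("post", {"norm_style": "post"})]
    else:
        variants = [("knfp", {"descriptors": ("knfp",)}),
                    ("seq2vec", {"descriptors": ("seq2vec",)}),
                    ("kmer_context", {"descriptors": ("kmer_context",)}),
                    ("fused", {"descriptors": ("knfp", "seq2vec", "kmer_context")})]
    rows = []
    for name, overrides in variants:
        cfg_v = dataclasses.replace(model_cfg, **overrides)
        res = run_experiment(ds, cfg_v, train_cfg)
        r = res["report"]
        rows.append({"config": name, "axis": axis, "acc": r.acc, "auc": r.auc,
                     "precision": r.precision, "recall": r.recall,
                     "seed": train_cfg.seed, "train_hash": res["train_hash"],
                     "test_hash": res["test_hash"]})
    return pd.DataFrame(rows)
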