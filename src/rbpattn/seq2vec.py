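"""Distributed-memory paragraph-vector (PV-DM) embeddings of sliding-window
sequence words, trained with negative sampling.

For a central word w_t with context w_{t-c} .. w_{t+c} inside document d, the
model maximizes the average log-probability of the central word given the
mean of the context word vectors *and* the document vector — the document
term is what distinguishes this from plain word2vec. The softmax is
approximated by negative sampling from the unigram^0.75 noise distribution.

The trainer is pure NumPy, single-threaded and driven by one seeded
generator, so a fixed seed reproduces word vectors bit-for-bit. Updates are
applied in deterministic mini-batches (a design choice documented in the
methods note; classic implementations update one example at a time).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .descriptors import WordSequence


@dataclass
class Seq2VecModel:
    """Trained PV-DM model: word/document vectors and the training recipe."""

    vocabulary: dict[str, int]
    word_vectors: np.ndarray          # |V| x D input vectors (the embeddings)
    context_vectors: np.ndarray       # |V| x D output (prediction) vectors
    doc_vectors: np.ndarray           # n_docs x D
    dim: int
    window: int
    epochs: int
    seed: int
    width: int = 10                   # tokenizer window the corpus was built with
    stride: int = 1
    oov_warnings: int = field(default=0, compare=False)

    def word_vector(self, word: str) -> np.ndarray | None:
        idx = self.vocabulary.get(word)
        if idx is None:
            self.oov_warnings += 1
            return None
        return self.word_vectors[idx]

    def to_tsv(self, path) -> None:
        """Portable word-vector dump: token \\t v1..vD."""
        inv = sorted(self.vocabulary.items(), key=lambda kv: kv[1])
        with open(path, "w") as fh:
            for tok, i in inv:
                vals = "\t".join(repr(float(x)) for x in self.word_vectors[i])
                fh.write(f"{tok}\t{vals}\n")

    def save_npz(self, path) -> None:
        tokens = np.array(sorted(self.vocabulary, key=self.vocabulary.get))
        np.savez(path, tokens=tokens, word_vectors=self.word_vectors,
                 context_vectors=self.context_vectors, doc_vectors=self.doc_vectors,
                 meta=np.array([self.dim, self.window, self.epochs, self.seed,
                                self.width, self.stride], dtype=np.int64))

    @classmethod
    def load_npz(cls, path) -> "Seq2VecModel":
        z = np.load(path, allow_pickle=False)
        dim, window, epochs, seed, width, stride = (int(x) for x in z["meta"])
        vocab = {str(t): i for i, t in enumerate(z["tokens"])}
        return cls(vocabulary=vocab, word_vectors=z["word_vectors"],
                   context_vectors=z["context_vectors"], doc_vectors=z["doc_vectors"],
                   dim=dim, window=window, epochs=epochs, seed=seed,
                   width=width, stride=stride)


def _build_examples(corpus: list[WordSequence], vocab: dict[str, int],
                    window: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Flatten the corpus into (doc_id, center, padded-context, context-count)
    arrays; context slots beyond a word's true context hold -1."""
    doc_ids, centers, ctx_rows, ctx_counts = [], [], [], []
    width = 2 * window
    for d, ws in enumerate(corpus):
        idxs = [vocab[w] for w in ws.words]
        for t, center in enumerate(idxs):
            lo = max(0, t - window)
            hi = min(len(idxs), t + window + 1)
            ctx = idxs[lo:t] + idxs[t + 1:hi]
            row = ctx + [-1] * (width - len(ctx))
            doc_ids.append(d)
            centers.append(center)
            ctx_rows.append(row)
            ctx_counts.append(len(ctx))
    return (np.array(doc_ids, dtype=np.int64),
            np.array(centers, dtype=np.int64),
            np.array(ctx_rows, dtype=np.int64).reshape(len(centers), width),
            np.array(ctx_counts, dtype=np.int64))


def train_seq2vec(corpus: list[WordSequence], dim: int = 64, window: int = 5,
                  epochs: int = 20, seed: int = 0, negative: int = 5,
                  alpha: float = 0.025, min_alpha: float = 1e-4,
                  batch: int = 512, width: int = 10, stride: int = 1) -> Seq2VecModel:
    """Train a PV-DM model over sliding-window word sequences.

    ``window`` is the context half-width in *words*; ``width``/``stride``
    record the letter-window tokenizer settings the corpus was built with so
    embedding lookups stay aligned.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    if not corpus or all(not ws.words for ws in corpus):
        raise ValueError("empty corpus: no words to train on")
    vocab: dict[str, int] = {}
    counts: list[int] = []
    for ws in corpus:
        for w in ws.words:
            i = vocab.setdefault(w, len(vocab))
            if i == len(counts):
                counts.append(0)
            counts[i] += 1
    rng = np.random.default_rng(seed)
    V, D = len(vocab), dim
    W_in = ((rng.random((V, D)) - 0.5) / D).astype(np.float64)
    W_out = np.zeros((V, D), dtype=np.float64)
    docs = ((rng.random((len(corpus), D)) - 0.5) / D).astype(np.float64)

    noise = np.array(counts, dtype=np.float64) ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    doc_ids, centers, ctx_rows, ctx_counts = _build_examples(corpus, vocab, window)
    n_ex = centers.size
    total_steps = max(1, epochs * n_ex)
    seen = 0
    for _ in range(epochs):
        order = rng.permutation(n_ex)
        for s in range(0, n_ex, batch):
            sel = order[s:s + batch]
            B = sel.size
            lr = max(min_alpha, alpha * (1.0 - seen / total_steps))
            seen += B
            ctx = ctx_rows[sel]                      # (B, 2w)
            ctxv = np.where(ctx[..., None] >= 0, W_in[np.maximum(ctx, 0)], 0.0)
            denom = (ctx_counts[sel] + 1.0)[:, None]
            h = (ctxv.sum(axis=1) + docs[doc_ids[sel]]) / denom  # (B, D)

            neg = np.searchsorted(noise_cdf, rng.random((B, negative)))
            targets = np.concatenate([centers[sel][:, None], neg], axis=1)  # (B, 1+k)
            labels = np.zeros((B, 1 + negative))
            labels[:, 0] = 1.0
            outv = W_out[targets]                    # (B, 1+k, D)
            scores = np.einsum("bkd,bd->bk", outv, h)
            sig = 1.0 / (1.0 + np.exp(-scores))
            gloss = (sig - labels) * lr              # (B, 1+k)

            np.add.at(W_out, targets, -gloss[..., None] * h[:, None, :])
            gh = np.einsum("bk,bkd->bd", gloss, outv) / denom
            valid = ctx >= 0
            np.add.at(W_in, ctx[valid], -np.broadcast_to(
                gh[:, None, :], ctxv.shape)[valid])
            np.add.at(docs, doc_ids[sel], -gh)

    return Seq2VecModel(vocabulary=vocab, word_vectors=W_in, context_vectors=W_out,
                        doc_vectors=docs, dim=dim, window=window, epochs=epochs,
                        seed=seed, width=width, stride=stride)
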