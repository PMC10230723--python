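"""Per-position sequence feature descriptors.

Three descriptors feed the downstream encoder:

* **KNFP** — k-tuple nucleotide frequency pattern. For k = 1, 2, 3 the
  relative frequency of every overlapping k-mer is computed over the
  sequence (count / (n - k + 1)); position i then carries, per k, the global
  frequency of the k-mer starting at i (3 channels). A pooled per-sequence
  4 + 16 + 64 = 84-dimensional variant is also exposed.
* **seq2vec** — distributed embeddings of width-10 sliding-window words from
  a PV-DM (Doc2Vec-style) model (see :mod:`rbpattn.seq2vec`); row i is the
  vector of the window starting at i.
* **kmer_context** — overlapping 3-mer tokens mapped through a (trainable or
  imported/frozen) embedding table.

K-mers are indexed lexicographically with A < C < G < U. Rows at padded,
masked-unknown or incomplete-window positions are all-zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .sequence_io import ALPHABET, RNASequence

BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}  # A<C<G<U

DESCRIPTOR_NAMES = ("knfp", "seq2vec", "kmer_context")


def kmer_vocabulary(k: int) -> list[str]:
    """All 4^k k-mers in lexicographic A<C<G<U order."""
    return ["".join(p) for p in product(ALPHABET, repeat=k)]


@dataclass
class KmerFrequencyVector:
    """Relative frequencies of the 4^k overlapping k-mers of one sequence."""

    k: int
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (4 ** self.k,):
            raise ValueError(f"expected length {4 ** self.k}, got {self.values.shape}")


@dataclass
class DescriptorMatrix:
    """Positions x channels feature matrix from one descriptor."""

    descriptor_name: str
    data: np.ndarray  # (L, C)
    pad_mask: np.ndarray  # (L,) True at pad positions

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.pad_mask = np.asarray(self.pad_mask, dtype=bool)
        if self.data.ndim != 2 or self.pad_mask.shape != (self.data.shape[0],):
            raise ValueError("data must be (L, C) with a length-L pad mask")

    @property
    def positions(self) -> int:
        return self.data.shape[0]

    @property
    def channels(self) -> int:
        return self.data.shape[1]


@dataclass
class WordSequence:
    """Sliding-window words of one sequence (the tokens of the PV-DM corpus)."""

    words: list[str]
    source_id: str = ""


def _kmer_indices(seq: RNASequence, k: int) -> np.ndarray:
    """Index of the k-mer starting at each position; -1 where the window is
    incomplete or touches a pad/unknown residue."""
    n = seq.n
    valid = seq.valid_mask()
    codes = np.full(n, -1, dtype=np.int64)
    for i, ch in enumerate(seq.residues):
        if valid[i]:
            codes[i] = BASE_INDEX[ch]
    idx = np.full(n, -1, dtype=np.int64)
    for i in range(n - k + 1):
        window = codes[i:i + k]
        if (window >= 0).all():
            v = 0
            for c in window:
                v = v * 4 + int(c)
            idx[i] = v
    return idx


def kmer_frequency_vector(seq: RNASequence, k: int) -> KmerFrequencyVector:
    """Eq.-style k-tuple composition: count of each k-mer among the
    overlapping windows divided by the number of complete windows.

    Windows touching pads or masked residues count in neither numerator nor
    denominator. A sequence shorter than k yields the all-zero vector.
    """
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    values = np.zeros(4 ** k, dtype=np.float64)
    idx = _kmer_indices(seq, k) if seq.n >= k else np.empty(0, dtype=np.int64)
    good = idx[idx >= 0]
    if good.size:
        counts = np.bincount(good, minlength=4 ** k)
        values = counts / good.size
    return KmerFrequencyVector(k=k, values=values)


def global_knfp(seq: RNASequence) -> np.ndarray:
    """Pooled per-sequence KNFP: the concatenated k = 1, 2, 3 frequency
    vectors (4 + 16 + 64 = 84 entries)."""
    return np.concatenate([kmer_frequency_vector(seq, k).values for k in (1, 2, 3)])


def knfp_encode(seq: RNASequence) -> DescriptorMatrix:
    """Per-position KNFP: row i carries, for k = 1, 2, 3, the global relative
    frequency of the k-mer that starts at position i (3 channels); windows
    running past the end or touching a pad carry 0."""
    L = seq.n
    data = np.zeros((L, 3), dtype=np.float64)
    for col, k in enumerate((1, 2, 3)):
        freqs = kmer_frequency_vector(seq, k).values
        idx = _kmer_indices(seq, k)
        ok = idx >= 0
        data[ok, col] = freqs[idx[ok]]
    pad = seq.pad_mask if seq.pad_mask is not None else np.zeros(L, dtype=bool)
    return DescriptorMatrix("knfp", data, pad)


def tokenize_window(seq: RNASequence, width: int = 10, stride: int = 1) -> WordSequence:
    """Sliding-window words seq[i:i+width] for i = 0, stride, 2*stride, ...
    while the window fits; windows touching pads/unknowns are skipped."""
    if width < 1 or stride < 1:
        raise ValueError("width and stride must be >= 1")
    valid = seq.valid_mask()
    words = []
    for i in range(0, seq.n - width + 1, stride):
        if valid[i:i + width].all():
            words.append(seq.residues[i:i + width])
    return WordSequence(words=words, source_id=seq.id)


def kmer_tokenize(seq: RNASequence, k: int = 3) -> list[str]:
    """Overlapping k-mer tokens, stride 1 (n - k + 1 tokens for a clean
    sequence; windows touching pads/unknowns are skipped)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    valid = seq.valid_mask()
    return [seq.residues[i:i + k] for i in range(seq.n - k + 1)
            if valid[i:i + k].all()]


def token_index(token: str, k: int = 3) -> int:
    """Lexicographic index of a k-mer; the UNK index (4^k) if it contains a
    non-{A,C,G,U} character."""
    v = 0
    for ch in token:
        c = BASE_INDEX.get(ch)
        if c is None:
            return 4 ** k
        v = v * 4 + c
    return v


def token_index_matrix(seq: RNASequence, k: int = 3) -> np.ndarray:
    """Aligned token indices: entry i is the index of the k-mer starting at
    position i, 4^k (UNK) if it contains a masked residue, and -1 where the
    window is incomplete or starts on a pad."""
    n = seq.n
    valid = seq.valid_mask()
    out = np.full(n, -1, dtype=np.int64)
    pad = seq.pad_mask if seq.pad_mask is not None else np.zeros(n, dtype=bool)
    for i in range(n - k + 1):
        if pad[i:i + k].any():
            continue
        if valid[i:i + k].all():
            out[i] = token_index(seq.residues[i:i + k], k)
        else:
            out[i] = 4 ** k  # masked-unknown inside an otherwise real window
    return out


@dataclass
class ContextEmbeddingTable:
    """Embedding table over all 4^k k-mer tokens plus UNK (and an implicit
    all-zero row for absent positions).

    When ``learnable`` the table is registered as a model parameter and
    trained end-to-end; a precomputed per-token table (TSV: token, v1..vD)
    can be imported and frozen instead.
    """

    k: int = 3
    dim: int = 64
    learnable: bool = True
    matrix: np.ndarray | None = None
    vocab: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.vocab = {tok: i for i, tok in enumerate(kmer_vocabulary(self.k))}
        self.vocab["UNK"] = 4 ** self.k
        if self.matrix is None:
            rng = np.random.default_rng(0)
            self.matrix = (rng.standard_normal((4 ** self.k + 1, self.dim))
                           / np.sqrt(self.dim))
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (4 ** self.k + 1, self.dim):
            raise ValueError(
                f"embedding table must be {(4 ** self.k + 1, self.dim)}, "
                f"got {self.matrix.shape}")

    @classmethod
    def from_tsv(cls, path, k: int = 3) -> "ContextEmbeddingTable":
        rows: dict[str, np.ndarray] = {}
        dim = None
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2:
                    continue
                vec = np.array([float(x) for x in parts[1:]])
                if dim is None:
                    dim = vec.size
                elif vec.size != dim:
                    raise ValueError(f"token {parts[0]!r}: dimension mismatch "
                                     f"({vec.size} != {dim})")
                rows[parts[0]] = vec
        if dim is None:
            raise ValueError("empty embedding TSV")
        table = cls(k=k, dim=dim, learnable=False,
                    matrix=np.zeros((4 ** k + 1, dim)))
        for tok, vec in rows.items():
            idx = table.vocab.get(tok)
            if idx is not None:
                table.matrix[idx] = vec
        return table

    def to_tsv(self, path) -> None:
        inv = {i: tok for tok, i in self.vocab.items()}
        with open(path, "w") as fh:
            for i in range(self.matrix.shape[0]):
                vals = "\t".join(repr(float(x)) for x in self.matrix[i])
                fh.write(f"{inv[i]}\t{vals}\n")


def context_embed(tokens: list[str], table: ContextEmbeddingTable,
                  L: int | None = None) -> DescriptorMatrix:
    """Embed a token list: row i is the embedding of token i; rows beyond the
    token count (up to L) are zero."""
    n_tok = len(tokens)
    L = n_tok if L is None else L
    data = np.zeros((L, table.dim), dtype=np.float64)
    for i, tok in enumerate(tokens[:L]):
        data[i] = table.matrix[table.vocab.get(tok, table.vocab["UNK"])]
    pad = np.zeros(L, dtype=bool)
    pad[n_tok:] = True
    return DescriptorMatrix("kmer_context", data, pad)


def embed_sequence(model, seq: RNASequence, width: int = 10,
                   stride: int = 1) -> DescriptorMatrix:
    """Per-position distributed-embedding descriptor: row i is the trained
    word vector of the window starting at i (pure lookup); trailing rows,
    pads and out-of-vocabulary windows are zero.

    Returns a matrix whose ``oov_count`` attribute counts unseen windows
    (non-zero only when the model corpus differs from the dataset).
    """
    L = seq.n
    data = np.zeros((L, model.dim), dtype=np.float64)
    valid = seq.valid_mask()
    oov = 0
    for i in range(0, L - width + 1, stride):
        if not valid[i:i + width].all():
            continue
        vec = model.word_vector(seq.residues[i:i + width])
        if vec is None:
            oov += 1
        else:
            data[i] = vec
    pad = seq.pad_mask if seq.pad_mask is not None else np.zeros(L, dtype=bool)
    mat = DescriptorMatrix("seq2vec", data, pad)
    mat.oov_count = oov
    return mat
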