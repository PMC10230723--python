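"""Sequence ingestion, alphabet normalization, length standardization and
stratified train/test splitting.

Sequences are RNA fragments over {A,C,G,U}; DNA input is accepted and T is
mapped to U. Positions that cannot be resolved to one of the four bases are
carried as the sentinel ``N`` and flagged so downstream descriptors emit
zero feature rows there.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGU"
PAD_CHAR = "N"

ALPHABET_POLICIES = ("strict", "map_dna", "mask_unknown")
PAD_POLICIES = ("pad_N_as_zero", "pad_repeat", "error")


class FastaParseError(ValueError):
    pass


class AlphabetError(ValueError):
    pass


class LengthError(ValueError):
    pass


class StratificationError(ValueError):
    pass


@dataclass
class RNASequence:
    """One fixed-alphabet RNA fragment with an optional binary label.

    ``pad_mask`` flags positions appended by length standardization; those
    positions (and any masked-unknown ``N`` residues) yield all-zero
    descriptor rows.
    """

    id: str
    residues: str
    label: int | None = None
    pad_mask: np.ndarray | None = None  # True at padded positions

    def __post_init__(self):
        if self.pad_mask is not None:
            self.pad_mask = np.asarray(self.pad_mask, dtype=bool)
            if self.pad_mask.shape != (len(self.residues),):
                raise ValueError("pad_mask length must equal sequence length")

    @property
    def n(self) -> int:
        return len(self.residues)

    @property
    def n_valid(self) -> int:
        """Length of the un-padded prefix."""
        if self.pad_mask is None:
            return self.n
        return int((~self.pad_mask).sum())

    def valid_mask(self) -> np.ndarray:
        """True where the residue is a real {A,C,G,U} base (not pad, not N)."""
        mask = np.frombuffer(self.residues.encode(), dtype=np.uint8) != ord(PAD_CHAR)
        if self.pad_mask is not None:
            mask &= ~self.pad_mask
        return mask


@dataclass
class LabeledDataset:
    """Ordered collection of labeled sequences (1 = bound, 0 = unbound)."""

    records: list[RNASequence] = field(default_factory=list)

    def __post_init__(self):
        for rec in self.records:
            if rec.label not in (0, 1):
                raise ValueError(f"record {rec.id!r} lacks a binary label")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def positive_count(self) -> int:
        return sum(1 for r in self.records if r.label == 1)

    @property
    def negative_count(self) -> int:
        return sum(1 for r in self.records if r.label == 0)

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=np.int64)


def normalize_residues(raw: str, alphabet_policy: str = "mask_unknown",
                       record_id: str = "?") -> str:
    if alphabet_policy not in ALPHABET_POLICIES:
        raise ValueError(f"unknown alphabet policy {alphabet_policy!r}")
    s = raw.upper()
    if alphabet_policy in ("map_dna", "mask_unknown"):
        s = s.replace("T", "U")
    out = []
    for i, ch in enumerate(s):
        if ch in ALPHABET:
            out.append(ch)
        elif alphabet_policy == "mask_unknown":
            out.append(PAD_CHAR)
        else:
            raise AlphabetError(
                f"record {record_id!r}: unknown character {ch!r} at position {i}")
    return "".join(out)


def read_fasta(path, alphabet_policy: str = "mask_unknown") -> list[RNASequence]:
    """Read a FASTA file into RNASequence records, in file order.

    Multi-line bodies are concatenated, case is upper-normalized and T is
    mapped to U (unless the policy is ``strict``).
    """
    records: list[RNASequence] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        body = str(rec.seq)
        if not rec.id:
            raise FastaParseError(f"record {i}: empty header")
        if not body:
            raise FastaParseError(f"record {i} ({rec.id!r}): empty sequence body")
        records.append(RNASequence(id=rec.id,
                                   residues=normalize_residues(
                                       body, alphabet_policy, rec.id)))
    return records


def write_fasta(seqs, path, width: int = 70) -> None:
    recs = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")
    # Biopython wraps at 60; width kept for signature stability.


def read_label_tsv(path, header: bool = False) -> dict[str, int]:
    """Two-column id -> label (0/1) TSV."""
    labels: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            if header and i == 0:
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FastaParseError(f"label TSV line {i}: expected 2 columns")
            labels[parts[0]] = int(parts[1])
    return labels


def load_labeled_fasta(positives_path, negatives_path,
                       alphabet_policy: str = "mask_unknown") -> LabeledDataset:
    """Build a dataset from separate positive/negative FASTA files."""
    pos = [replace(r, label=1) for r in read_fasta(positives_path, alphabet_policy)]
    neg = [replace(r, label=0) for r in read_fasta(negatives_path, alphabet_policy)]
    return LabeledDataset(records=pos + neg)


def attach_labels(seqs: list[RNASequence], labels: dict[str, int]) -> LabeledDataset:
    recs = []
    for s in seqs:
        if s.id not in labels:
            raise KeyError(f"no label for sequence {s.id!r}")
        recs.append(replace(s, label=labels[s.id]))
    return LabeledDataset(records=recs)


def standardize_length(seq: RNASequence, L: int,
                       pad_policy: str = "pad_N_as_zero") -> RNASequence:
    """Return a copy with residues of length exactly ``L``.

    Over-length sequences are center-truncated (binding sites in these
    benchmarks are centered by construction). Short sequences are
    right-padded: ``pad_N_as_zero`` appends flagged ``N`` positions that
    descriptors zero out; ``pad_repeat`` cyclically repeats the sequence
    (unflagged — apt for covalently closed circular fragments); ``error``
    refuses any length change.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if pad_policy not in PAD_POLICIES:
        raise ValueError(f"unknown pad policy {pad_policy!r}")
    n = seq.n
    if n == L:
        return seq
    if pad_policy == "error":
        raise LengthError(f"sequence {seq.id!r} has length {n}, expected {L}")
    if n > L:
        off = (n - L) // 2
        residues = seq.residues[off:off + L]
        pad = None if seq.pad_mask is None else seq.pad_mask[off:off + L]
        return replace(seq, residues=residues, pad_mask=pad)
    m = L - n
    old_pad = seq.pad_mask if seq.pad_mask is not None else np.zeros(n, dtype=bool)
    if pad_policy == "pad_N_as_zero":
        residues = seq.residues + PAD_CHAR * m
        pad = np.concatenate([old_pad, np.ones(m, dtype=bool)])
    else:  # pad_repeat
        reps = seq.residues * (m // n + 2)
        residues = seq.residues + reps[:m]
        pad = np.concatenate([old_pad, np.zeros(m, dtype=bool)])
    return replace(seq, residues=residues, pad_mask=pad)


def split_dataset(ds: LabeledDataset, train_frac: float = 0.8,
                  seed: int = 0) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified train/test split: per-label train counts are
    round(train_frac * per-label total); the same seed reproduces the
    identical split."""
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in (0, 1):
        idx = [i for i, r in enumerate(ds.records) if r.label == label]
        if len(idx) < 2:
            raise StratificationError(
                f"label {label} has {len(idx)} record(s); need >= 2 to stratify")
        perm = rng.permutation(len(idx))
        n_tr = int(round(train_frac * len(idx)))
        train_idx.extend(idx[j] for j in perm[:n_tr])
        test_idx.extend(idx[j] for j in perm[n_tr:])
    train_idx.sort()
    test_idx.sort()
    return (LabeledDataset([ds.records[i] for i in train_idx]),
            LabeledDataset([ds.records[i] for i in test_idx]))


def split_hash(ds: LabeledDataset) -> str:
    """Stable fingerprint of a dataset's membership (order-insensitive)."""
    import hashlib
    h = hashlib.sha256()
    for rid in sorted(r.id for r in ds.records):
        h.update(rid.encode())
        h.update(b"\x00")
    return h.hexdigest()[:16]
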