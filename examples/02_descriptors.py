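"""Compute the three per-position descriptors for one sequence.

Every descriptor yields a positions x channels matrix aligned to the same
101 positions, so the downstream encoder can fuse them per position.
"""

import numpy as np

import rbpattn as rb

seq = rb.RNASequence("demo", "ACGUACGUAC" * 10 + "A")  # 101 nt

# 1. KNFP: per-position k-mer frequencies, k = 1,2,3 -> 3 channels
knfp = rb.knfp_encode(seq)
print("KNFP matrix:", knfp.data.shape)
print("  row 0 (freq of A, AC, ACG in this sequence):",
      np.round(knfp.data[0], 3))
print("  pooled 84-dim variant:", rb.global_knfp(seq).shape)

# 2. Distributed embeddings of width-10 windows from a PV-DM model
corpus = [rb.tokenize_window(seq, width=10)]
s2v = rb.train_seq2vec(corpus, dim=16, epochs=5, seed=0)
emb = rb.embed_sequence(s2v, seq, width=10)
print("seq2vec matrix:", emb.data.shape,
      f"(vocabulary {len(s2v.vocabulary)} windows; "
      f"rows beyond position {seq.n - 10} are zero)")

# 3. Overlapping 3-mer tokens through an embedding table
tokens = rb.kmer_tokenize(seq, 3)
table = rb.ContextEmbeddingTable(dim=16)
ctx = rb.context_embed(tokens, table, L=seq.n)
print("kmer_context matrix:", ctx.data.shape,
      f"({len(tokens)} tokens; last {seq.n - len(tokens)} rows zero)")
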