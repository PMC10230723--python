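# rbpattn

Sequence classification of RNA–protein binding sites: multi-descriptor
encoding of fixed-length RNA fragments, a convolutional feature-unification
encoder, and a **pre-normalized residual self-attention** classifier — plus
a synthetic motif-planting benchmark generator so the entire pipeline is
trainable and testable without downloading CLIP-Seq archives.

## Who this is for

Computational biologists working on RNA-binding-protein (RBP) site
prediction from CLIP-derived fragment benchmarks (circular or linear RNA),
and anyone who wants a small, fully inspectable NumPy implementation of a
pre-norm attention classifier whose every layer is verified against
independent oracles.

## The model

A fragment S = [S₁…Sₙ], Sᵢ ∈ {A,C,G,U} (typically n = 101; DNA input is
accepted with T→U) is encoded three ways, all per position:

* **KNFP** — k-tuple nucleotide frequency pattern: for k = 1,2,3, the
  relative frequency of each overlapping k-mer, count/(n−k+1); position i
  carries the frequency of the k-mer starting at i (3 channels). A pooled
  4+16+64 = 84-dim per-sequence variant is exposed as `global_knfp`.
* **seq2vec** — PV-DM (Doc2Vec-style) distributed embeddings of width-10
  sliding-window words, trained with negative sampling on the training
  split; row i is the vector of the window starting at i.
* **kmer_context** — overlapping 3-mer tokens through a trainable embedding
  table (end-to-end), with an import hook for precomputed frozen per-token
  embeddings.

Each descriptor passes through Conv1d → BatchNorm → ReLU to a common width,
is concatenated and projected 1×1 to the model width d, giving the fused
per-position feature z. The attention stack is wired **pre-norm**:

    p  = z + MHA(LN(z))         LN(z) = (z − μ)/√(σ² + ε) ⊙ γ + β
    zₛ = p + FFN(LN(p))         MHA(Q,K,V) = softmax(QKᵀ/√d_h) V

so the loss gradient reaches every block input through an additive identity
path (∂ε/∂x_l = ∂ε/∂x_L · (1 + Σ_k ∂F/∂x_l)); the post-norm variant
(x_{l+1} = LN(x_l + F(x_l))) is kept for ablation. Classification is
mask-aware mean pooling → affine → softmax. Training follows the published
protocol: Adam, weight decay 3e-4, batch 64, initial learning rate 3e-3
decaying tenfold every two epochs, stratified 80/20 split. Metrics are ACC,
AUC (Mann–Whitney, mid-rank ties), precision and recall.

## Worked example

```bash
python examples/04_train_and_evaluate.py
```

trains on 500 synthetic fragments (101 nt, planted 8-mer UGCAUGCA mutated at
10% per base, uniform background) and prints:

```
epoch  lr        loss    train_auc
    0  3.0e-03  1.0871  0.503
    1  3.0e-03  0.6818  0.614
    2  3.0e-04  0.7065  0.743
    3  3.0e-04  0.6762  0.661
    4  3.0e-05  0.6526  0.790
    5  3.0e-05  0.6533  0.789

held-out (50+50 sequences): AUC 0.786  ACC 0.640  precision 0.719  recall 0.460
```

The learning-rate column shows the tenfold-every-two-epochs decay; AUC is
the probability that a random bound fragment outscores a random unbound one
(0.5 = chance). At this reduced n the model is data-limited; the
default-scale run (n = 2000, below) reaches held-out AUC ≈ 0.92–0.94.

The other examples cover the generator (`01`), the three descriptors
(`02`), pre- vs post-norm gradient flow (`03`) and matched-seed ablations
(`05`). A thin CLI wraps the same functions:

```bash
rbpattn simulate --n 2000 --out data/
rbpattn train --positives data/positives.fa --negatives data/negatives.fa --out run/
rbpattn predict --checkpoint run/checkpoint.npz --model-config run/model_config.json \
                --seq2vec-model run/seq2vec.npz --fasta data/positives.fa
rbpattn ablate --positives data/positives.fa --negatives data/negatives.fa --axis norm_style
```

Every command writes its fully resolved configuration next to its outputs;
rerunning with `--config run/run_config.json` reproduces the metrics
bit-identically.

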