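# Methods

## Problem and model

`rbpattn` classifies fixed-length RNA fragments (typically 101 nt over
{A,C,G,U}; DNA input is accepted with T→U mapping) as bound / unbound by an
RNA-binding protein. The classifier has three stages.

**Multi-descriptor encoding.** Each sequence is encoded three ways, all
aligned per position:

1. *KNFP* (k-tuple nucleotide frequency pattern). For k = 1, 2, 3 the
   relative frequency of every overlapping k-mer is `count / (n − k + 1)`;
   position i carries the global frequency of the k-mer that starts at i,
   giving a 3-channel matrix. K-mers are ordered lexicographically with
   A < C < G < U. A pooled 84-dimensional per-sequence variant
   (4 + 16 + 64) is exposed as `global_knfp` for users who want the classic
   composition vector; the per-position layout is the default because the
   attention stack consumes position-indexed sequences.
2. *seq2vec*: a PV-DM (paragraph-vector distributed-memory) model over
   width-10 sliding-window words. For a central word w_t with context
   w_{t−c}…w_{t+c} in document d, training maximizes the average
   log-probability of w_t given the mean of the context word vectors and the
   document vector, with negative sampling (5 noise words from the
   unigram^0.75 distribution). Row i of the descriptor is the trained input
   vector of the window starting at i; out-of-vocabulary windows and pads are
   zero rows.
3. *kmer_context*: overlapping 3-mer tokens through a trainable embedding
   table (65 rows: 64 3-mers + UNK) learned end-to-end with the classifier.
   A precomputed per-token table (TSV) can be imported and frozen instead —
   the import hook exists so externally learned token representations (for
   example from a pretrained genomic language model) can be dropped in.

**Feature-unification encoder.** Each descriptor passes through its own
same-length 1-D convolution (kernel 3), batch normalization over the
batch × position axes, and ReLU, mapping to a shared channel width C_u; the
three branches are concatenated in fixed order and projected to the model
width d by a 1×1 convolution. Disabled branches (descriptor ablations)
contribute zero matrices, so every configuration keeps identical downstream
shapes.

**Pre-norm self-attention classifier.** The fused feature z passes through
residual attention blocks wired pre-norm:

    p   = z + MHA(LN(z))
    z_s = p + FFN(LN(p))

followed by a final layer norm, mask-aware mean pooling over positions, an
affine map to two logits and a softmax. The post-norm variant
(y = LN(x + MHA(x)); out = LN(y + FFN(y))) is retained solely for ablation.
Layer normalization uses the population variance over the channel axis.
Scaled dot-product multi-head attention excludes padded keys from every
softmax; the softmax scaling denominator is the per-head width d/h by
default (`attn_scale="model"` switches to the full width d for users who
want the literal single-denominator form — with h heads of width d/h, the
per-head convention is what the original transformer uses).

Because dot-product attention is position-agnostic, a learned per-position
embedding is added to z before the first block (`positional`, default on).

### Why pre-norm

For a stack of L residual blocks, the post-norm gradient of the loss ε at a
block input x_l contains a product of layer-norm Jacobians accumulated
across depth, while the pre-norm gradient is

    ∂ε/∂x_l = ∂ε/∂x_L × (1 + Σ_k ∂F(LN(x_k))/∂x_l),

whose additive identity term propagates ∂ε/∂x_L to every depth unchanged.
Both facts are exercised empirically: a pre-norm block whose attention
output projection and second FFN map are zero is *exactly* the identity, and
`gradient_depth_profile` verifies bit-exact gradient equality across a
12-block zero-initialized pre-norm stack (and its absence post-norm).

## Training protocol

Adam (β = 0.9/0.999, ε = 1e-8) with L2-style weight decay 3e-4 added to the
gradient, batch size 64, cross-entropy loss, initial learning rate 3e-3
decaying to one-tenth every two epochs, 10 epochs, stratified 80/20
train/test split. The embedding (seq2vec) model is trained on the training
split only — no external corpus — so held-out windows are usually
out-of-vocabulary on synthetic data (see limitations).

## Defaults and their rationale

| parameter | default | why |
|---|---|---|
| fragment length L | 101 | typical CLIP-derived fragment length; config value |
| encoder kernel | 7 | over 3-mer embeddings a kernel-7 filter spans 9 nt, wider than the 6–8-nt motifs typical of RBPs, so one filter can act as a whole-motif detector |
| encoder channels C_u | 64 | desk-scale speed on one CPU core |
| model width d | 64 | idem; must divide the head count |
| heads h | 8 | d_h = 8 per head |
| blocks | 2 | shallow stacks suffice at this input length |
| FFN width | 256 | 4×d, the usual transformer ratio |
| dropout | 0.1 | mild regularization |
| residual zero-init | on | blocks start as the identity; the network fades residual branches in, which keeps the 3e-3 initial learning rate stable |
| gradient clipping | global norm 1.0 | tames the earliest high-lr steps; standard transformer practice |
| seq2vec dim / window / epochs | 64 / 5 words / 20 | PV-DM defaults; single worker for determinism |
| batch norm momentum / eps | 0.1 / 1e-5 | standard semantics |
| classification threshold | 0.5 | ACC/precision/recall operating point |

The width/kernel combination was sized for the published schedule: with a
tenfold decay every two epochs nearly all learning happens in the first
four epochs, so the architecture must train stably at the 3e-3 initial rate
and have a receptive field that makes motif evidence directly visible to
the first convolution. Wider models (d = 128, C_u = 128) are supported via
config but train less stably under that schedule on one CPU at desk scale.

Problem sizes were chosen so the default end-to-end run (n = 2000, L = 101)
trains in a few minutes on one CPU core; ablation and stability studies use
n = 500 for the same reason. These are the package's own desk-scale study
conditions, not statements about production-scale training.

## Synthetic benchmark

The generator emulates CLIP-style benchmarks: n fixed-length fragments,
balanced classes, uniform (configurable) background; each positive carries
one motif instance — consensus with per-base mutation rate 0.1, or a PWM
sample — at a uniformly random offset. Negatives are *not* screened for
chance motif occurrences by default; `clean_negatives` enables rejection
sampling, in which case an exact-substring scan separates the classes
perfectly (the generator's self-check). Defaults: n = 2000, L = 101,
pos_frac = 0.5, consensus UGCAUGCA, mutation 0.1, seed 42.

What the generator does **not** emulate: positional biases of real
crosslink sites, transcript-level base composition, clustered/overlapping
binding sites, read-coverage artifacts, and back-splice junctions of
circular RNAs. Passing tests on synthetic data therefore demonstrate that
the pipeline can recover a planted degenerate motif under the published
protocol — not that it reproduces benchmark AUCs on real CLIP data.

## Numerical choices

* All layers are hand-written NumPy with explicit backward passes; every
  backward is checked against central finite differences in float64.
* Training uses float32 parameters; functional ops run in the caller's
  dtype.
* Masked attention scores are set to −1e30 before the softmax; an all-masked
  sequence is a contract violation (raised), not a silent NaN.
* AUC uses mid-rank tie handling (the Mann–Whitney convention).
* Sequences longer than L are center-truncated (binding sites in these
  benchmarks are centered by construction); shorter ones are right-padded
  with flagged positions that all descriptors map to zero rows and the
  attention/pooling mask excludes. `pad_repeat` cyclically extends instead
  (unflagged), which suits covalently closed circular fragments.
* Ambiguity codes are masked to a sentinel that behaves like padding
  (`mask_unknown`, default) or rejected (`strict`).
* The PV-DM trainer applies updates in deterministic mini-batches of 512
  examples (classic implementations update per example); with a fixed seed
  and a single worker, word vectors are bit-for-bit reproducible.
* round() (banker's rounding) sets per-label train counts in the split.

## Design choices where the design was open

* **Fusion operator**: concatenate-then-project rather than sum — preserves
  descriptor identity and lets the 1×1 convolution learn the weighting.
* **KNFP layout**: per-position (default) with the pooled 84-dim vector as
  an auxiliary op.
* **Positional information**: learned positional embedding on by default,
  since the attention stack is otherwise permutation-equivariant and the
  3-mer embedding stand-in has no positional parameters of its own.
* **Softmax head over 2 classes** rather than a single sigmoid.
* **Stability and ablation comparisons are reported, never hard-asserted**:
  they are stochastic claims about training runs.

## Known limitations

* The seq2vec vocabulary is built from the training split; on
  high-entropy synthetic backgrounds most held-out windows are
  out-of-vocabulary and receive zero vectors, so this descriptor carries
  little test-time signal there. On real data (lower-entropy, repeated
  motifs, larger corpora) coverage is far higher. The import hook for a
  precomputed corpus-level embedding table is the intended remedy.
* Single CPU, desk scale: no GPU kernels, no data-parallel training.
* The aggressive tenfold-per-two-epochs decay concentrates almost all
  learning in the first four epochs; architectures were sized so training is
  stable at the 3e-3 initial rate (see the sizing note above).
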