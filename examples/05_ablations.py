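"""Matched-seed ablations: pre- vs post-norm wiring, and descriptors.

Every row shares the same seed and the same train/test split (identical
split hashes), so differences are attributable to the varied axis alone.
These comparisons are stochastic claims about training runs — they are
reported, not asserted.
"""

import rbpattn as rb

ds = rb.generate_dataset(rb.GeneratorConfig(n=500, seed=21))
model_cfg = rb.ModelConfig(dim=16, heads=4, blocks=1, ffn_dim=32,
                           seq2vec_dim=8, context_dim=8, encoder_channels=8,
                           dropout=0.0)
train_cfg = rb.TrainingConfig(epochs=4, seed=21, seq2vec_epochs=3)

for axis in ("norm_style", "descriptor"):
    table = rb.ablate(ds, model_cfg, train_cfg, axis)
    print(f"\n=== axis: {axis} ===")
    print(table[["config", "auc", "acc", "precision", "recall"]]
          .to_string(index=False, float_format="%.3f"))

print("\nRows within one table share seed and split; the norm_style table "
      "contrasts residual wiring, the descriptor table contrasts single "
      "descriptors against the fused set.")
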