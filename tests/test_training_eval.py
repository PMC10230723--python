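"""Training protocol, metrics oracle, gradient-depth profiling, ablation
machinery."""

import dataclasses

import numpy as np
import pytest

import rbpattn as rb
from rbpattn.nn import SoftmaxCrossEntropy
from rbpattn.training_eval import (Featurizer, TrainingDivergedError,
                                   compute_metrics, lr_at_epoch)


def brute_force_auc(labels, scores):
    """All-pairs Mann-Whitney with half credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestLrSchedule:
    @pytest.mark.parametrize("epoch,rate", [(0, 3e-3), (1, 3e-3), (2, 3e-4),
                                            (3, 3e-4), (4, 3e-5), (5, 3e-5)])
    def test_tenfold_decay_every_two_epochs(self, epoch, rate):
        cfg = rb.TrainingConfig()
        assert lr_at_epoch(epoch, cfg) == pytest.approx(rate)

    def test_schedule_non_increasing(self):
        cfg = rb.TrainingConfig()
        rates = [lr_at_epoch(e, cfg) for e in range(20)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))


class TestComputeMetrics:
    def test_perfect_separation(self):
        r = compute_metrics(np.array([0, 0, 1, 1]), np.array([0.1, 0.2, 0.8, 0.9]))
        assert r.auc == 1.0 and r.acc == 1.0 and r.precision == 1.0 and r.recall == 1.0

    def test_all_ties_give_half(self):
        r = compute_metrics(np.array([0, 1, 0, 1]), np.full(4, 0.5))
        assert r.auc == 0.5

    def test_worked_four_point_example(self):
        r = compute_metrics(np.array([1, 0, 1, 0]), np.array([0.9, 0.8, 0.4, 0.1]))
        assert r.auc == pytest.approx(0.75)

    def test_matches_all_pairs_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 40))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            # quantized scores force ties to exercise mid-rank handling
            scores = np.round(rng.random(n), 1)
            r = compute_metrics(labels, scores)
            assert abs(r.auc - brute_force_auc(labels, scores)) < 1e-12

    def test_auc_invariant_to_monotone_transform(self, rng):
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        scores = rng.random(50)
        a = compute_metrics(labels, scores).auc
        b = compute_metrics(labels, np.exp(3 * scores)).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_flags_auc_undefined(self):
        r = compute_metrics(np.ones(4, dtype=int), np.array([0.1, 0.6, 0.7, 0.9]))
        assert not r.auc_defined and np.isnan(r.auc)
        assert r.acc == 0.75  # three of four above threshold

    def test_no_positive_predictions_flags_precision(self):
        r = compute_metrics(np.array([0, 1]), np.array([0.1, 0.2]))
        assert r.precision == 0.0 and not r.precision_defined


@pytest.fixture
def featurized(tiny_model_cfg, tiny_train_cfg, tiny_dataset):
    feat = Featurizer(tiny_model_cfg, tiny_train_cfg).fit(tiny_dataset.records)
    X = feat.transform(tiny_dataset.records)
    return X, tiny_dataset.labels()


class TestTrain:
    def test_zero_epochs_returns_empty_history(self, tiny_model_cfg, featurized):
        X, y = featurized
        model = rb.SequenceClassifier(tiny_model_cfg)
        cfg = rb.TrainingConfig(epochs=0, seed=0)
        assert rb.train(model, X, y, cfg) == []

    def test_same_seed_reproduces_history_bitwise(self, tiny_model_cfg, featurized):
        X, y = featurized
        cfgs = [rb.SequenceClassifier(tiny_model_cfg) for _ in range(2)]
        hists = [rb.train(m, X, y, rb.TrainingConfig(epochs=2, batch_size=16,
                                                     seed=7))
                 for m in cfgs]
        assert hists[0] == hists[1]
        a, b = (m.state_dict() for m in cfgs)
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_divergence_aborts_with_diagnostic(self, tiny_model_cfg, featurized):
        X, y = featurized
        model = rb.SequenceClassifier(tiny_model_cfg)
        model.head.out.b.data[:] = np.inf
        with pytest.raises(TrainingDivergedError):
            rb.train(model, X, y, rb.TrainingConfig(epochs=1, seed=0))

    def test_loss_decreases_on_learnable_task(self, tiny_model_cfg, featurized):
        X, y = featurized
        model = rb.SequenceClassifier(tiny_model_cfg)
        hist = rb.train(model, X, y, rb.TrainingConfig(epochs=4, batch_size=16,
                                                       seed=1))
        assert hist[-1]["loss"] < hist[0]["loss"]


class TestGradientDepthProfile:
    def _model_and_batch(self, norm_style, blocks=8):
        cfg = rb.ModelConfig(length=16, dim=8, heads=2, blocks=blocks,
                             ffn_dim=16, seq2vec_dim=4, context_dim=4,
                             encoder_channels=4, dropout=0.0,
                             norm_style=norm_style, seed=0)
        model = rb.SequenceClassifier(cfg, dtype=np.float64)
        rng = np.random.default_rng(3)
        batch = {"knfp": rng.random((8, 16, 3)),
                 "seq2vec": rng.random((8, 16, 4)),
                 "tokens": rng.integers(0, 64, (8, 16)),
                 "mask": np.ones((8, 16), bool)}
        labels = rng.integers(0, 2, 8)
        return model, batch, labels

    def test_prenorm_zero_init_gradients_identical_across_blocks(self):
        model, batch, labels = self._model_and_batch("pre", blocks=12)
        model.transformer.zero_init_sublayer_outputs()
        prof = rb.gradient_depth_profile(model, batch, labels)
        assert prof.finite and prof.norm_style == "pre"
        for g in prof.block_input_grads:
            np.testing.assert_array_equal(g, prof.output_grad)
        assert len(set(prof.block_input_grad_norms)) == 1
        assert prof.block_input_grad_norms[0] == prof.output_grad_norm

    def test_postnorm_zero_init_gradients_transformed_by_ln_jacobians(self):
        model, batch, labels = self._model_and_batch("post", blocks=12)
        model.transformer.zero_init_sublayer_outputs()
        prof = rb.gradient_depth_profile(model, batch, labels)
        assert prof.finite
        norms = prof.block_input_grad_norms
        assert len(set(np.round(norms, 12))) > 1  # LN Jacobians reshape them

    def test_random_init_prenorm_first_block_gradient_positive(self):
        model, batch, labels = self._model_and_batch("pre", blocks=8)
        prof = rb.gradient_depth_profile(model, batch, labels)
        assert prof.block_input_grad_norms[0] > 0.0


class TestAblateAndStability:
    def test_norm_style_axis_two_matched_rows(self, tiny_model_cfg,
                                              tiny_train_cfg, tiny_dataset):
        table = rb.ablate(tiny_dataset, tiny_model_cfg, tiny_train_cfg,
                          "norm_style")
        assert list(table["config"]) == ["pre", "post"]
        assert table["train_hash"].nunique() == 1
        assert table["test_hash"].nunique() == 1
        assert table["seed"].nunique() == 1

    def test_descriptor_axis_four_matched_rows(self, tiny_model_cfg,
                                               tiny_train_cfg, tiny_dataset):
        table = rb.ablate(tiny_dataset, tiny_model_cfg, tiny_train_cfg,
                          "descriptor")
        assert list(table["config"]) == ["knfp", "seq2vec", "kmer_context",
                                         "fused"]
        assert table["train_hash"].nunique() == 1

    def test_invalid_axis_rejected(self, tiny_model_cfg, tiny_train_cfg,
                                   tiny_dataset):
        with pytest.raises(ValueError, match="axis"):
            rb.ablate(tiny_dataset, tiny_model_cfg, tiny_train_cfg, "dropout")

    def test_stability_reports_dispersion(self, tiny_model_cfg, tiny_train_cfg,
                                          tiny_dataset):
        res = rb.stability_run(tiny_dataset, tiny_model_cfg, tiny_train_cfg,
                               n_runs=2)
        assert len(res["reports"]) == 2
        assert np.isfinite(res["auc_std"])

    def test_stability_requires_two_runs(self, tiny_model_cfg, tiny_train_cfg,
                                         tiny_dataset):
        with pytest.raises(ValueError):
            rb.stability_run(tiny_dataset, tiny_model_cfg, tiny_train_cfg,
                             n_runs=1)
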