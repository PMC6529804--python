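"""Losses, pair sampling and the two training stages."""

import numpy as np
import pandas as pd
import pytest

from histoadapt.errors import SamplingError
from histoadapt.models import Discriminator, NetConfig, SourceNet, state_hash
from histoadapt.nn import sigmoid
from histoadapt.synthdata import generate_dataset
from histoadapt.train import (AdaptConfig, SourceTrainConfig, adapt_target,
                              adversarial_losses, classification_loss, one_hot,
                              sample_pairs, siamese_loss, softmax_cross_entropy,
                              train_source)

LN2 = np.log(2.0)


class TestClassificationLoss:
    def test_uniform_scores_give_ln2(self):
        scores = np.zeros((4, 2))
        y = one_hot(["low", "high", "low", "high"])
        assert classification_loss(scores, y) == pytest.approx(LN2, abs=1e-9)

    def test_confident_correct_scores_drive_loss_to_zero(self):
        scores = np.array([[50.0, 0.0], [0.0, 50.0]])
        y = one_hot(["low", "high"])
        assert classification_loss(scores, y) < 1e-12

    def test_matches_independent_log_sum_exp_oracle(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(0, 3, (32, 2))
        labels = rng.integers(0, 2, 32)
        y = np.eye(2)[labels]
        # independent direct evaluation
        expected = np.mean([
            -scores[i, labels[i]] + np.log(np.exp(scores[i]).sum())
            for i in range(32)
        ])
        assert classification_loss(scores, y) == pytest.approx(expected, abs=1e-6)

    def test_non_one_hot_labels_rejected(self):
        with pytest.raises(ValueError):
            classification_loss(np.zeros((2, 2)), np.array([[1, 1], [0, 1]]))

    def test_gradient_is_softmax_minus_labels(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(0, 1, (8, 2))
        y = np.eye(2)[rng.integers(0, 2, 8)]
        _, grad = softmax_cross_entropy(scores, y)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        sm = e / e.sum(axis=1, keepdims=True)
        assert np.allclose(grad, (sm - y) / 8, atol=1e-6)


class TestAdversarialLosses:
    @pytest.fixture()
    def half_discriminator(self):
        d = Discriminator(4, (5, 5), seed=0)
        d.net.layers[-1].params["W"][...] = 0
        d.net.layers[-1].params["b"][...] = 0
        return d

    def test_closed_form_at_one_half(self, half_discriminator):
        rng = np.random.default_rng(0)
        ladv_d, ladv_m = adversarial_losses(half_discriminator,
                                            rng.normal(size=(6, 4)),
                                            rng.normal(size=(6, 4)))
        assert ladv_d == pytest.approx(2 * LN2, abs=1e-6)
        assert ladv_m == pytest.approx(LN2, abs=1e-6)

    def test_perfect_discriminator_limits(self):
        from histoadapt.nn.layers import BatchNorm

        d = Discriminator(1, (2, 2), seed=0)
        # saturate the layers toward the sign of the input feature
        for layer in d.net.param_layers():
            for k in layer.params:
                layer.params[k][...] = 0
            if isinstance(layer, BatchNorm):
                layer.params["gamma"][...] = 1.0
        d.net.layers[0].params["W"][...] = 100.0
        d.net.layers[3].params["W"][...] = 100.0
        d.net.layers[-1].params["W"][...] = 100.0
        d.net.layers[-1].params["b"][...] = -50.0  # zero hidden -> logit -50
        fs = np.full((4, 1), 1.0)
        ft = np.full((4, 1), -1.0)
        ladv_d, ladv_m = adversarial_losses(d, fs, ft)
        assert ladv_d < 1e-4
        assert ladv_m > 10.0  # clamped large value

    def test_matches_formula_oracle_on_random_features(self):
        d = Discriminator(4, (5, 5), seed=2)
        rng = np.random.default_rng(3)
        fs, ft = rng.normal(size=(10, 4)), rng.normal(size=(12, 4))
        ladv_d, ladv_m = adversarial_losses(d, fs, ft)
        ps = np.clip(sigmoid(d.forward(fs)), 1e-7, 1 - 1e-7)
        pt = np.clip(sigmoid(d.forward(ft)), 1e-7, 1 - 1e-7)
        assert ladv_d == pytest.approx(float(-np.log(ps).mean()
                                             - np.log(1 - pt).mean()), abs=1e-6)
        assert ladv_m == pytest.approx(float(-np.log(pt).mean()), abs=1e-6)

    def test_empty_batch_rejected(self, half_discriminator):
        with pytest.raises(ValueError):
            adversarial_losses(half_discriminator, np.empty((0, 4)),
                               np.ones((2, 4)))


class TestSiameseLoss:
    def test_half_probabilities_give_ln2(self):
        assert siamese_loss(np.full(10, 0.5), np.random.default_rng(0)
                            .integers(0, 2, 10)) == pytest.approx(LN2, abs=1e-12)

    def test_perfect_predictions_give_zero(self):
        y = np.array([0, 1, 1, 0])
        assert siamese_loss(y.astype(float), y) == pytest.approx(0.0, abs=1e-5)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.01, 0.99, 64)
        y = rng.integers(0, 2, 64)
        expected = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert siamese_loss(p, y) == pytest.approx(float(expected), abs=1e-6)

    def test_out_of_range_probabilities_rejected(self):
        with pytest.raises(ValueError):
            siamese_loss(np.array([1.2]), np.array([1]))


@pytest.fixture(scope="module")
def target_train_rows(small_pair):
    _, tgt = small_pair
    return tgt.manifest.rows(domain="target", split="train").reset_index(drop=True)


class TestSamplePairs:
    def test_balanced_composition(self, target_train_rows):
        batch = sample_pairs(target_train_rows, 128, 0.5,
                             np.random.default_rng(0))
        assert int(batch.y.sum()) == 64
        assert len(batch.y) == 128

    def test_labels_consistent_with_manifest(self, target_train_rows):
        batch = sample_pairs(target_train_rows, 64, 0.5,
                             np.random.default_rng(1))
        w1 = target_train_rows["wsi_id"].to_numpy()[batch.idx1]
        w2 = target_train_rows["wsi_id"].to_numpy()[batch.idx2]
        assert np.array_equal(batch.y, (w1 == w2).astype(int))

    def test_same_wsi_anchors_uniform(self, target_train_rows):
        """Each eligible WSI anchors same-WSI pairs uniformly (multinomial
        check at 3 sd over 1e4 draws)."""
        rng = np.random.default_rng(2)
        counts = {}
        n_draws, per_batch = 200, 50
        for _ in range(n_draws):
            b = sample_pairs(target_train_rows, per_batch, 0.999, rng)
            w = target_train_rows["wsi_id"].to_numpy()
            for i, y in zip(b.idx1, b.y):
                if y == 1:
                    counts[w[i]] = counts.get(w[i], 0) + 1
        total = sum(counts.values())
        k = len(set(target_train_rows["wsi_id"]))
        expected = total / k
        sd = np.sqrt(total * (1 / k) * (1 - 1 / k))
        for wsi, c in counts.items():
            assert abs(c - expected) <= 3.5 * sd

    def test_impossible_composition_raises(self):
        rows = pd.DataFrame({
            "patch_id": ["a", "b", "c"],
            "wsi_id": ["w1", "w1", "w1"],
        })
        with pytest.raises(SamplingError):
            sample_pairs(rows, 8, 0.5, np.random.default_rng(0))


@pytest.fixture(scope="module")
def tiny_source():
    from histoadapt.synthdata import SyntheticDomainSpec

    return generate_dataset(SyntheticDomainSpec(), 4, 6, seed=5,
                            domain="source", patch_size=32)


class TestTrainSource:
    def test_zero_learning_rate_leaves_weights_unchanged(self, tiny_source):
        net = SourceNet(NetConfig.tiny(32), seed=0)
        h0 = state_hash(net)
        cfg = SourceTrainConfig.tiny(input_size=32, epochs=1, batch_size=8,
                                     seed=0, lr0=0.0, weight_decay=0.0)
        net, _ = train_source(net, tiny_source, cfg)
        assert state_hash(net) == h0  # learnable weights untouched

    def test_identical_seeds_identical_history(self, tiny_source):
        cfg = SourceTrainConfig.tiny(input_size=32, epochs=2, batch_size=8, seed=3)
        _, h1 = train_source(SourceNet(NetConfig.tiny(32), seed=3),
                             tiny_source, cfg)
        _, h2 = train_source(SourceNet(NetConfig.tiny(32), seed=3),
                             tiny_source, cfg)
        assert h1.equals(h2)

    def test_crop_exceeding_resize_rejected(self):
        with pytest.raises(ValueError):
            SourceTrainConfig(resize=32, crop=64)


class TestAdaptTarget:
    def test_zero_iterations_returns_exact_copy(self, study):
        run = study[0]
        cfg = AdaptConfig(batch_size=8, n_iterations=0, seed=0)
        tnet, _, history = adapt_target(run.net, run.source, run.target, cfg)
        x = (run.target.patch_array(run.target.manifest.rows(split="test"))
             .astype(np.float32) / 255.0 - 0.5).transpose(0, 3, 1, 2)[:4]
        fs, ss = run.net.forward(x, train=False)
        ft, st = tnet.forward(x, train=False)
        assert np.array_equal(ss, st) and np.array_equal(fs, ft)
        assert len(history) == 0

    def test_source_hash_invariant_under_adaptation(self, study):
        run = study[0]
        h0 = state_hash(run.net)
        adapt_target(run.net, run.source, run.target,
                     AdaptConfig(batch_size=8, n_iterations=5, seed=1))
        assert state_hash(run.net) == h0

    def test_history_records_all_loss_components(self, study):
        run = study[0]
        _, _, history = adapt_target(run.net, run.source, run.target,
                                     AdaptConfig(batch_size=8, n_iterations=3,
                                                 seed=2))
        assert list(history.columns) == ["iteration", "LadvD", "LadvM", "Ls",
                                         "D_acc"]
        assert np.isfinite(history[["LadvD", "LadvM", "Ls"]].to_numpy()).all()


class TestAdaptationProperties:
    def test_feature_separability_drifts_toward_chance(self, study, adapted):
        """A held-out logistic probe separates source from target features
        less well after adaptation than before (domain confusion)."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import cross_val_score

        from histoadapt.train import predict_scores

        run = study[0]
        ste = run.source.manifest.rows(domain="source", split="test")
        tte = run.target.manifest.rows(domain="target", split="test")
        fs, _ = predict_scores(run.net, run.source.patch_array(ste))
        ft_before, _ = predict_scores(run.net, run.target.patch_array(tte))
        ft_after, _ = predict_scores(adapted[0].lt, run.target.patch_array(tte))

        def separability(fa, fb):
            x = np.vstack([fa, fb])
            y = np.r_[np.zeros(len(fa)), np.ones(len(fb))]
            return cross_val_score(LogisticRegression(max_iter=2000), x, y,
                                   cv=5).mean()

        assert separability(fs, ft_after) <= separability(fs, ft_before)

    def test_no_harm_when_source_equals_target(self):
        """With no domain shift, adaptation costs at most 2 accuracy points
        (median over 3 seeds)."""
        from histoadapt.models import NetConfig, SourceNet
        from histoadapt.synthdata import (SyntheticDomainSpec,
                                          generate_domain_pair)
        from histoadapt.train import predict_scores, train_source

        spec = SyntheticDomainSpec()
        drops = []
        for seed in (0, 1, 2):
            src, tgt = generate_domain_pair(spec, spec, 8, 13, seed=300 + seed,
                                            patch_size=64)
            net = SourceNet(NetConfig.tiny(64), seed=seed)
            net, _ = train_source(net, src, SourceTrainConfig.tiny(
                input_size=64, epochs=8, batch_size=16, seed=seed))
            rows = tgt.manifest.rows(domain="target", split="test")
            x = tgt.patch_array(rows)
            y = np.array([0 if tgt.truth.labels[p] == "low" else 1
                          for p in rows["patch_id"]])
            tnet, _, _ = adapt_target(net, src, tgt, AdaptConfig(
                batch_size=16, n_iterations=250, seed=seed))
            _, s0 = predict_scores(net, x)
            _, s1 = predict_scores(tnet, x)
            drops.append(float((s0.argmax(1) == y).mean()
                               - (s1.argmax(1) == y).mean()))
        assert np.median(drops) <= 0.02 + 1e-9
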