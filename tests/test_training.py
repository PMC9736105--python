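"""Pseudo-label loss, SGD training, and the alternating loop."""

import numpy as np
import pytest
from scipy.special import logsumexp

import camgrade as cg
from camgrade.backbone import BackboneConfig, build_backbone
from camgrade.cluster import kmeans_fit
from camgrade.reduce import apply_reduction, fit_reduction, l2_normalize
from camgrade.training import (
    ClassifierHead, TrainConfig, TrainingError, _SGD, derive_run_seeds,
    pseudo_label_loss, train_epoch,
)
from conftest import hungarian_accuracy


@pytest.fixture(scope="module")
def tiny_images():
    return cg.generate_dataset(3, rng_seed=1)


class TestPseudoLabelLoss:
    def test_uniform_logits_give_log_k(self):
        logits = np.zeros((4, 3))
        labels = np.array([0, 1, 2, 0])
        assert pseudo_label_loss(logits, labels) == pytest.approx(np.log(3))

    def test_confident_correct_logit_approaches_zero(self):
        logits = np.array([[50.0, 0.0, 0.0]])
        assert pseudo_label_loss(logits, np.array([0])) < 1e-15

    def test_matches_logsumexp_oracle(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(0, 3, (20, 4))
        labels = rng.integers(0, 4, 20)
        expected = np.mean([logsumexp(l) - l[y]
                            for l, y in zip(logits, labels)])
        assert pseudo_label_loss(logits, labels) == pytest.approx(expected)

    def test_non_finite_logits_raise(self):
        with pytest.raises(TrainingError):
            pseudo_label_loss(np.array([[np.inf, 0.0]]), np.array([0]))


class TestTrainEpoch:
    def test_zero_learning_rate_leaves_parameters_unchanged(self, tiny_images):
        backbone = build_backbone(BackboneConfig(init_seed=0))
        head = ClassifierHead(backbone.feature_dim, 3, rng_seed=1)
        before = backbone.weight_checksum()
        w_before = head.linear.params["W"].copy()
        cfg = TrainConfig(learning_rate=0.0, epochs=1, rng_seed=2)
        train_epoch(backbone, head, tiny_images,
                    np.zeros(len(tiny_images), dtype=int), cfg)
        assert backbone.weight_checksum() == before
        assert np.array_equal(head.linear.params["W"], w_before)

    def test_single_step_matches_analytic_softmax_gradient(self, tiny_images):
        # Frozen backbone, one sample, no clipping: the head update must be
        # W ← W − η f (p − y)ᵀ with p = softmax(Wᵀf + b).
        backbone = build_backbone(BackboneConfig(init_seed=0))
        head = ClassifierHead(backbone.feature_dim, 3, rng_seed=1)
        img = [tiny_images[0]]
        label = np.array([2])
        f = backbone.forward(backbone.preprocess(img))[0].astype(np.float64)
        w = head.linear.params["W"].astype(np.float64)
        b = head.linear.params["b"].astype(np.float64)
        logits = f @ w + b
        p = np.exp(logits - logsumexp(logits))
        grad = np.outer(f, p - np.eye(3)[2])
        lr = 1e-4
        expected_w = w - lr * grad
        cfg = TrainConfig(learning_rate=lr, momentum=0.9, epochs=1,
                          batch_size=1, freeze_backbone=True, grad_clip=None,
                          rng_seed=3)
        train_epoch(backbone, head, img, label, cfg)
        assert np.abs(head.linear.params["W"] - expected_w).max() < 1e-6

    def test_head_only_training_is_monotone_on_fixed_toy(self, tiny_images):
        # With the backbone frozen the problem is convex; full-batch descent
        # at a small rate must not increase the loss.
        backbone = build_backbone(BackboneConfig(init_seed=4))
        head = ClassifierHead(backbone.feature_dim, 3, rng_seed=5)
        labels = np.array([0, 1, 2] * 3)
        images = tiny_images
        cfg = TrainConfig(learning_rate=1e-3, momentum=0.0, epochs=1,
                          batch_size=len(images), freeze_backbone=True,
                          uniform_label_sampling=False, rng_seed=6)
        params = [(head.linear, n) for n in head.linear.params]
        opt = _SGD(params, cfg.learning_rate, cfg.momentum, cfg.grad_clip)
        rng = np.random.default_rng(7)
        losses = [train_epoch(backbone, head, images, labels[:len(images)],
                              cfg, optimizer=opt, rng=rng) for _ in range(5)]
        assert all(a >= b - 1e-9 for a, b in zip(losses, losses[1:]))

    def test_divergence_raises_training_error(self, tiny_images):
        backbone = build_backbone(BackboneConfig(init_seed=0))
        head = ClassifierHead(backbone.feature_dim, 3, rng_seed=1)
        cfg = TrainConfig(learning_rate=1e12, grad_clip=None, epochs=1,
                          rng_seed=2)
        with pytest.raises(TrainingError), np.errstate(all="ignore"):
            for _ in range(10):
                train_epoch(backbone, head, tiny_images,
                            np.array([0, 1, 2] * 3), cfg)

    def test_label_validation(self, tiny_images):
        backbone = build_backbone(BackboneConfig(init_seed=0))
        head = ClassifierHead(backbone.feature_dim, 3)
        with pytest.raises(ValueError):
            train_epoch(backbone, head, tiny_images, np.array([0, 1]),
                        TrainConfig())
        with pytest.raises(ValueError):
            train_epoch(backbone, head, tiny_images,
                        np.array([0, 1, 5] * 3), TrainConfig())


class TestRunDeepCluster:
    def test_single_epoch_equals_manual_composition(self, tiny_images):
        cfg = TrainConfig(epochs=1, rng_seed=9)
        results = cg.run_deepcluster(tiny_images, k=3, train_config=cfg)

        plan = derive_run_seeds(cfg.rng_seed, cfg.epochs)
        backbone = build_backbone(BackboneConfig(init_seed=plan["backbone"]))
        feats = cg.extract_features(backbone, tiny_images)
        reduction = fit_reduction(feats)
        reduced = l2_normalize(apply_reduction(reduction, feats))
        clustering = kmeans_fit(reduced, 3,
                                rng_seed=plan["epochs"][0]["kmeans"])
        head = ClassifierHead(backbone.feature_dim, 3,
                              rng_seed=plan["epochs"][0]["head"])
        params = [(head.linear, n) for n in head.linear.params] + backbone.parameters()
        opt = _SGD(params, cfg.learning_rate, cfg.momentum, cfg.grad_clip)
        rng = np.random.default_rng(plan["epochs"][0]["batches"])
        loss = train_epoch(backbone, head, tiny_images,
                           clustering.assignments, cfg, optimizer=opt, rng=rng)

        assert np.array_equal(results.assignments, clustering.assignments)
        assert results.history.loss[0] == pytest.approx(loss)
        assert results.clustering.objective == pytest.approx(clustering.objective)

    def test_identical_seeds_give_identical_histories(self, tiny_images):
        cfg = TrainConfig(epochs=2, rng_seed=11)
        a = cg.run_deepcluster(tiny_images, k=3, train_config=cfg)
        b = cg.run_deepcluster(tiny_images, k=3, train_config=cfg)
        assert np.array_equal(a.history.loss, b.history.loss)
        assert np.array_equal(a.history.clustering_objective,
                              b.history.clustering_objective)
        assert np.array_equal(a.assignments, b.assignments)

    def test_recovers_planted_stages(self, recovery_run):
        _, truth, results = recovery_run
        assert hungarian_accuracy(truth, results.assignments) >= 0.9
        assert cg.clustering_agreement(truth, results.assignments) >= 0.8

    def test_assignments_stabilize_over_rounds(self, recovery_run):
        _, _, results = recovery_run
        nmi = results.history.nmi_vs_previous
        assert np.nanmean(nmi[-5:]) > np.nanmean(nmi[:5])

    def test_cluster_sizes_never_zero(self, recovery_run):
        _, _, results = recovery_run
        assert (results.history.cluster_sizes > 0).all()

    def test_identify_agrees_with_final_pseudo_labels(self, recovery_run):
        images, _, results = recovery_run
        predicted = results.identify(images)
        assert (predicted == results.assignments).mean() >= 0.9

    def test_identify_is_deterministic_and_probabilistic_output_normalised(
            self, recovery_run):
        images, _, results = recovery_run
        twice = [results.identify([images[0]] * 2)]
        assert twice[0][0] == twice[0][1]
        proba = results.predict_proba(images[:4])
        assert proba.sum(axis=1) == pytest.approx(np.ones(4))

    def test_projection_and_summary(self, recovery_run):
        images, _, results = recovery_run
        df = results.projection_2d()
        assert set(df.columns) == {"id", "pc1", "pc2", "cluster"}
        assert len(df) == len(images)
        text = results.summary()
        assert "cluster sizes" in text and "final objective" in text

    def test_needs_at_least_k_images(self, tiny_images):
        with pytest.raises(ValueError):
            cg.DeepClusterModel(tiny_images[:2], k=3)
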