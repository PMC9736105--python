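"""Shared fixtures: the two expensive trained-model experiments.

Both are session-scoped so the recovery run and the crack-localization
model are trained exactly once and shared between the unit tests and the
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

import camgrade as cg
from camgrade.backbone import BackboneConfig, build_backbone
from camgrade.training import ClassifierHead, TrainConfig, _SGD, train_epoch

STAGE_INDEX = {"unripe": 0, "ripe": 1, "overripe": 2}


def hungarian_accuracy(truth: np.ndarray, assignments: np.ndarray) -> float:
    """Best label-permutation agreement between truth and cluster ids."""
    k = max(truth.max(), assignments.max()) + 1
    m = np.zeros((k, k))
    for t, a in zip(truth, assignments):
        m[t, a] += 1
    rows, cols = linear_sum_assignment(-m)
    return float(m[rows, cols].sum() / len(truth))


@pytest.fixture(scope="session")
def recovery_run():
    """Deep-clustering run on 150 well-separated synthetic images.

    Returns (images, truth indices, fitted results).  High stage
    separation, tiny backbone, 64×64, 20 reassignment rounds.
    """
    images = cg.generate_dataset(50, size=64, rng_seed=7, separation=1.5)
    truth = np.array([STAGE_INDEX[img.truth_stage] for img in images])
    results = cg.run_deepcluster(
        images, k=3, train_config=TrainConfig(epochs=20, rng_seed=3))
    return images, truth, results


def crack_informative_phenotypes() -> dict[str, cg.StagePhenotype]:
    """Stages that differ only in crack/seed rendering (identical peel)."""
    return {
        "unripe": cg.StagePhenotype("unripe", hue_mean=50, hue_jitter=6,
                                    peel_roughness=0.06),
        "ripe": cg.StagePhenotype("ripe", hue_mean=50, hue_jitter=6,
                                  peel_roughness=0.06, crack_fraction=0.08,
                                  seed_exposure=0.03),
        "overripe": cg.StagePhenotype("overripe", hue_mean=50, hue_jitter=6,
                                      peel_roughness=0.06, crack_fraction=0.22,
                                      seed_exposure=0.15),
    }


def train_crack_classifier(rng_seed: int = 11, n_per_stage: int = 40,
                           epochs: int = 15):
    """Supervised training on crack-informative images; returns (backbone, head)."""
    phenos = crack_informative_phenotypes()
    images = cg.generate_dataset(n_per_stage, rng_seed=rng_seed,
                                 phenotypes=phenos)
    labels = np.array([STAGE_INDEX[img.truth_stage] for img in images])
    backbone = build_backbone(BackboneConfig(init_seed=2))
    head = ClassifierHead(backbone.feature_dim, 3, rng_seed=3)
    cfg = TrainConfig(learning_rate=0.05, epochs=1, rng_seed=4)
    params = [(head.linear, n) for n in head.linear.params] + backbone.parameters()
    opt = _SGD(params, cfg.learning_rate, cfg.momentum, cfg.grad_clip)
    rng = np.random.default_rng(42)
    for _ in range(epochs):
        train_epoch(backbone, head, images, labels, cfg, optimizer=opt, rng=rng)
    return backbone, head


@pytest.fixture(scope="session")
def crack_model():
    """Classifier trained on images where only the crack is informative."""
    return train_crack_classifier()
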