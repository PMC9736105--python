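"""The alternating deep-clustering loop and its Model/Results interface.

One training round: extract features on the current backbone weights,
reduce them (PCA + L2), cluster with K-Means, then treat the cluster
assignments as pseudo-labels and update the network — a freshly
reinitialised linear classifier head on top of the shared backbone — by
mini-batch SGD with momentum on the softmax cross-entropy (negative
log-softmax) loss.  Iterating rounds lets the feature extractor and the
grouping co-adapt: assignments stabilise as the features sharpen around
the cluster structure.

The loop is exposed statsmodels-style: :class:`DeepClusterModel` holds
the data and configuration, ``fit()`` returns a
:class:`DeepClusterResults` carrying the trained network, the final
grading, the per-epoch history, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from camgrade.backbone import (
    Backbone, BackboneConfig, FeatureMatrix, Linear, build_backbone,
)
from camgrade.cluster import ClusteringResult, clustering_agreement, kmeans_fit
from camgrade.reduce import apply_reduction, fit_reduction, l2_normalize
from camgrade.synthetic import FruitImage


class TrainingError(RuntimeError):
    """Raised when optimisation diverges (non-finite loss)."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings for pseudo-label training.

    ``epochs`` counts passes over the data; clustering reassignment
    happens every ``reassign_every`` epochs.  ``uniform_label_sampling``
    draws training batches uniformly over pseudo-labels (with
    replacement), which guards against trivial single-cluster collapse.
    ``freeze_backbone`` restricts updates to the classifier head, making
    the problem convex (useful for diagnostics).
    """

    learning_rate: float = 0.1
    momentum: float = 0.9
    epochs: int = 20
    batch_size: int = 32
    reassign_every: int = 1
    uniform_label_sampling: bool = True
    freeze_backbone: bool = False
    grad_clip: float | None = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1 or self.reassign_every < 1:
            raise ValueError("batch_size and reassign_every must be >= 1")


@dataclass(frozen=True)
class ReductionConfig:
    """PCA settings for the per-round feature reduction."""

    n_components: int | None = None
    whiten: bool = False


class ClassifierHead:
    """The final linear layer mapping backbone features to k stage logits."""

    def __init__(self, feature_dim: int, k: int, rng_seed: int = 0):
        if feature_dim < 1 or k < 2:
            raise ValueError("feature_dim must be >= 1 and k >= 2")
        self.feature_dim = feature_dim
        self.k = k
        self.linear = Linear(feature_dim, k, np.random.default_rng(rng_seed))

    def logits(self, features: np.ndarray) -> np.ndarray:
        out = self.linear.forward(np.asarray(features, dtype=np.float32))
        if not np.isfinite(out).all():
            raise TrainingError("classifier head produced non-finite logits")
        return out

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.linear.backward(dlogits)


class _SGD:
    """SGD with classical momentum: v ← μv − η∇;  w ← w + v.

    When ``grad_clip`` is set, the global gradient norm (over all
    parameters) is rescaled to at most that value before the update —
    the usual stabiliser for momentum SGD at large learning rates.
    """

    def __init__(self, params: list[tuple[object, str]], lr: float,
                 momentum: float, grad_clip: float | None = None):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.grad_clip = grad_clip
        self.velocity = [np.zeros_like(layer.params[name])
                         for layer, name in params]

    def step(self) -> None:
        scale = 1.0
        if self.grad_clip is not None:
            total = np.sqrt(sum(float((layer.grads[name] ** 2).sum())
                                for layer, name in self.params))
            if total > self.grad_clip:
                scale = self.grad_clip / total
        for i, (layer, name) in enumerate(self.params):
            grad = layer.grads[name] * scale
            self.velocity[i] = (self.momentum * self.velocity[i]
                                - self.lr * grad).astype(np.float32)
            layer.params[name] = layer.params[name] + self.velocity[i]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def pseudo_label_loss(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-softmax of the assigned label."""
    logits = np.asarray(logits, dtype=np.float64)
    if not np.isfinite(logits).all():
        raise TrainingError("non-finite logits")
    labels = np.asarray(labels)
    n, k = logits.shape
    if labels.shape != (n,):
        raise ValueError("labels must be 1-D with one entry per row of logits")
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError("labels out of range")
    z = logits - logits.max(axis=1, keepdims=True)
    log_probs = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return float(-log_probs[np.arange(n), labels].mean())


def _sample_batches(labels: np.ndarray, batch_size: int, uniform: bool,
                    rng: np.random.Generator) -> list[np.ndarray]:
    n = len(labels)
    if uniform:
        present = np.unique(labels)
        by_label = {int(c): np.flatnonzero(labels == c) for c in present}
        chosen_labels = rng.choice(present, size=n, replace=True)
        idx = np.array([by_label[int(c)][rng.integers(len(by_label[int(c)]))]
                        for c in chosen_labels])
    else:
        idx = rng.permutation(n)
    return [idx[s:s + batch_size] for s in range(0, n, batch_size)]


def _train_one_epoch(backbone: Backbone, head: ClassifierHead, x: np.ndarray,
                     labels: np.ndarray, config: TrainConfig,
                     optimizer: _SGD, rng: np.random.Generator) -> float:
    batches = _sample_batches(labels, config.batch_size,
                              config.uniform_label_sampling, rng)
    total_loss = 0.0
    total_n = 0
    for idx in batches:
        xb = x[idx]
        yb = labels[idx]
        feats = backbone.forward(xb)
        logits = head.logits(feats)
        loss = pseudo_label_loss(logits, yb)
        if not np.isfinite(loss):
            raise TrainingError(f"training diverged (loss={loss})")
        probs = softmax(logits.astype(np.float64))
        dlogits = probs.copy()
        dlogits[np.arange(len(yb)), yb] -= 1.0
        dlogits = (dlogits / len(yb)).astype(np.float32)
        dfeat = head.backward(dlogits)
        if not config.freeze_backbone:
            backbone.backward(dfeat)
        optimizer.step()
        total_loss += loss * len(yb)
        total_n += len(yb)
    return total_loss / total_n


def train_epoch(backbone: Backbone, head: ClassifierHead,
                images: list[FruitImage], pseudo_labels,
                config: TrainConfig, optimizer: _SGD | None = None,
                rng: np.random.Generator | None = None) -> float:
    """One SGD epoch on pseudo-labels; returns the mean batch loss.

    Parameters are updated in place.  Deterministic for a fixed
    ``config.rng_seed`` (or a supplied generator).
    """
    labels = np.asarray(pseudo_labels)
    if len(labels) != len(images):
        raise ValueError("pseudo_labels length must match images")
    if labels.min() < 0 or labels.max() >= head.k:
        raise ValueError("pseudo-labels out of range for the classifier head")
    x = backbone.preprocess(images)
    if optimizer is None:
        params = [(head.linear, n) for n in head.linear.params]
        if not config.freeze_backbone:
            params = params + backbone.parameters()
        optimizer = _SGD(params, config.learning_rate, config.momentum,
                         config.grad_clip)
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    return _train_one_epoch(backbone, head, x, labels, config, optimizer, rng)


def derive_run_seeds(rng_seed: int, epochs: int) -> dict:
    """Deterministic seed plan for a full run.

    Draws, in order: the backbone init seed, then per epoch a
    (kmeans, head, batch-sampling) seed triple.  Exposed so a run can be
    reproduced by manually composing the stage operations.
    """
    master = np.random.default_rng(rng_seed)
    plan = {"backbone": int(master.integers(2**31 - 1)), "epochs": []}
    for _ in range(epochs):
        plan["epochs"].append({
            "kmeans": int(master.integers(2**31 - 1)),
            "head": int(master.integers(2**31 - 1)),
            "batches": int(master.integers(2**31 - 1)),
        })
    return plan


@dataclass
class TrainHistory:
    """Per-epoch trace of the alternating loop."""

    loss: np.ndarray                   # mean pseudo-label loss
    clustering_objective: np.ndarray   # K-Means objective (nan if no reassign)
    nmi_vs_previous: np.ndarray        # NMI vs previous assignments (nan first)
    cluster_sizes: np.ndarray          # epochs × k
    empty_cluster_repairs: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "epoch": np.arange(1, len(self.loss) + 1),
            "loss": self.loss,
            "clustering_objective": self.clustering_objective,
            "nmi_vs_previous": self.nmi_vs_previous,
            "empty_cluster_repairs": self.empty_cluster_repairs,
        })
        for j in range(self.cluster_sizes.shape[1]):
            df[f"cluster_{j}_size"] = self.cluster_sizes[:, j]
        return df


class DeepClusterModel:
    """Unsupervised maturity grading model over a set of fruit images.

    Parameters
    ----------
    images : list of FruitImage
        The unlabelled training images (any truth labels they carry are
        ignored by the fit).
    k : int
        Number of maturity groups (3 for unripe/ripe/overripe).
    backbone_config, reduction_config, train_config :
        Stage configurations; sensible desk-scale defaults are used when
        omitted.  All randomness derives from ``train_config.rng_seed``.
    """

    def __init__(self, images: list[FruitImage], k: int = 3,
                 backbone_config: BackboneConfig | None = None,
                 reduction_config: ReductionConfig | None = None,
                 train_config: TrainConfig | None = None):
        if len(images) < k:
            raise ValueError(f"need at least k={k} images")
        self.images = list(images)
        self.k = k
        self.backbone_config = backbone_config or BackboneConfig()
        self.reduction_config = reduction_config or ReductionConfig()
        self.train_config = train_config or TrainConfig()

    def fit(self, progress: bool = False) -> "DeepClusterResults":
        cfg = self.train_config
        plan = derive_run_seeds(cfg.rng_seed, cfg.epochs)
        backbone = build_backbone(replace(self.backbone_config,
                                          init_seed=plan["backbone"]))
        x = backbone.preprocess(self.images)
        ids = [img.sample_id or f"img_{i:05d}" for i, img in enumerate(self.images)]

        head: ClassifierHead | None = None
        optimizer: _SGD | None = None
        clustering: ClusteringResult | None = None
        reduction = None
        prev_assignments: np.ndarray | None = None

        loss_hist, obj_hist, nmi_hist, repair_hist = [], [], [], []
        size_hist = []
        for epoch in range(cfg.epochs):
            seeds = plan["epochs"][epoch]
            reassign = epoch % cfg.reassign_every == 0
            if reassign or clustering is None:
                feats = FeatureMatrix(values=_forward_batched(backbone, x), ids=ids)
                reduction = fit_reduction(
                    feats, n_components=self.reduction_config.n_components,
                    whiten=self.reduction_config.whiten)
                reduced = l2_normalize(apply_reduction(reduction, feats))
                clustering = kmeans_fit(reduced, self.k, rng_seed=seeds["kmeans"])
                nmi = (np.nan if prev_assignments is None else
                       clustering_agreement(prev_assignments, clustering.assignments))
                prev_assignments = clustering.assignments
                # Fresh head (and optimiser state) after every reassignment:
                # cluster ids are arbitrary per round, so stale logit bindings
                # would fight the new labels.
                head = ClassifierHead(backbone.feature_dim, self.k,
                                      rng_seed=seeds["head"])
                params = [(head.linear, n) for n in head.linear.params]
                if not cfg.freeze_backbone:
                    params = params + backbone.parameters()
                optimizer = _SGD(params, cfg.learning_rate, cfg.momentum,
                                 cfg.grad_clip)
                obj = clustering.objective
                repairs = clustering.empty_cluster_repairs
            else:
                nmi, obj, repairs = np.nan, np.nan, 0
            rng = np.random.default_rng(seeds["batches"])
            loss = _train_one_epoch(backbone, head, x,
                                    clustering.assignments, cfg, optimizer, rng)
            loss_hist.append(loss)
            obj_hist.append(obj)
            nmi_hist.append(nmi)
            repair_hist.append(repairs)
            size_hist.append(clustering.cluster_sizes)
            if progress:
                print(f"epoch {epoch + 1:3d}  loss {loss:.4f}  "
                      f"objective {obj:.5f}  nmi {nmi:.3f}")

        history = TrainHistory(
            loss=np.asarray(loss_hist),
            clustering_objective=np.asarray(obj_hist),
            nmi_vs_previous=np.asarray(nmi_hist),
            cluster_sizes=np.asarray(size_hist),
            empty_cluster_repairs=np.asarray(repair_hist),
        )
        return DeepClusterResults(model=self, backbone=backbone, head=head,
                                  reduction=reduction, clustering=clustering,
                                  history=history, ids=ids)


def _forward_batched(backbone: Backbone, x: np.ndarray,
                     batch_size: int = 32) -> np.ndarray:
    return np.concatenate([backbone.forward(x[s:s + batch_size])
                           for s in range(0, len(x), batch_size)])


@dataclass
class DeepClusterResults:
    """Fitted grading model: network, final grading, and training history."""

    model: DeepClusterModel
    backbone: Backbone
    head: ClassifierHead
    reduction: object
    clustering: ClusteringResult
    history: TrainHistory
    ids: list[str]

    @property
    def assignments(self) -> np.ndarray:
        """Final pseudo-label assignment of each training image."""
        return self.clustering.assignments

    def predict_logits(self, images: list[FruitImage]) -> np.ndarray:
        x = self.backbone.preprocess(images)
        return self.head.logits(_forward_batched(self.backbone, x))

    def predict_proba(self, images: list[FruitImage]) -> np.ndarray:
        return softmax(self.predict_logits(images).astype(np.float64))

    def identify(self, images: list[FruitImage]) -> np.ndarray:
        """Predicted cluster label (argmax head logit) per image."""
        return np.argmax(self.predict_logits(images), axis=1)

    def projection_2d(self, images: list[FruitImage] | None = None) -> pd.DataFrame:
        """First two PCA coordinates of the (final) reduced features.

        Useful for scatter plots of the grading structure; rows carry the
        image id and, where known, the assignment.
        """
        if images is None:
            images = self.model.images
            labels = self.assignments
            ids = self.ids
        else:
            labels = self.identify(images)
            ids = [img.sample_id or f"img_{i:05d}" for i, img in enumerate(images)]
        x = self.backbone.preprocess(images)
        feats = FeatureMatrix(values=_forward_batched(self.backbone, x), ids=ids)
        reduced = l2_normalize(apply_reduction(self.reduction, feats))
        return pd.DataFrame({"id": ids, "pc1": reduced.values[:, 0],
                             "pc2": reduced.values[:, 1], "cluster": labels})

    def summary(self) -> str:
        cfg = self.model.train_config
        sizes = ", ".join(str(int(s)) for s in self.clustering.cluster_sizes)
        nmi = self.history.nmi_vs_previous
        nmi_last = nmi[~np.isnan(nmi)]
        lines = [
            "Deep clustering maturity grading",
            "=" * 40,
            f"images:               {len(self.model.images)}",
            f"clusters (k):         {self.model.k}",
            f"backbone:             {self.model.backbone_config.scale} "
            f"({self.backbone.feature_dim}-d features)",
            f"epochs:               {cfg.epochs} "
            f"(reassign every {cfg.reassign_every})",
            f"learning rate:        {cfg.learning_rate}",
            f"momentum:             {cfg.momentum}",
            f"final loss:           {self.history.loss[-1]:.4f}",
            f"final objective:      {self.clustering.objective:.6f}",
            f"cluster sizes:        {sizes}",
            f"empty-cluster repairs:{int(self.history.empty_cluster_repairs.sum()):2d}",
        ]
        if len(nmi_last):
            lines.append(f"last assignment NMI:  {nmi_last[-1]:.4f}")
        return "\n".join(lines)


def run_deepcluster(images: list[FruitImage],
                    backbone_config: BackboneConfig | None = None,
                    reduction_config: ReductionConfig | None = None,
                    k: int = 3,
                    train_config: TrainConfig | None = None,
                    progress: bool = False) -> DeepClusterResults:
    """Functional wrapper: build a :class:`DeepClusterModel` and fit it."""
    return DeepClusterModel(images, k=k, backbone_config=backbone_config,
                            reduction_config=reduction_config,
                            train_config=train_config).fit(progress=progress)


def identify(results: DeepClusterResults, images: list[FruitImage]) -> np.ndarray:
    """Predict the cluster label of each image with the trained head."""
    return results.identify(images)
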