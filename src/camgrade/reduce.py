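"""PCA feature selection and L2 normalisation ahead of clustering.

Random-backbone features are high dimensional (4096 for the full
backbone) and mostly redundant; PCA keeps the directions that carry the
variance, and L2 normalisation puts every image on the unit sphere so
that no single image with unusually large activations dominates the
K-Means geometry.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from camgrade.backbone import FeatureMatrix

#: Default cap on retained components, following common deep-clustering practice.
DEFAULT_COMPONENTS = 256


@dataclass
class ReductionModel:
    """A fitted PCA projection: center, orthonormal basis, variances."""

    n_components: int
    component_basis: np.ndarray        # D×d, orthonormal columns
    center: np.ndarray                 # length D
    explained_variance: np.ndarray     # length d
    explained_variance_ratio: np.ndarray
    whiten: bool = False

    def save(self, path: str, sidecar_path: str) -> None:
        np.savez(path, basis=self.component_basis, center=self.center,
                 var=self.explained_variance, ratio=self.explained_variance_ratio)
        with open(sidecar_path, "w") as fh:
            json.dump({"n_components": self.n_components, "whiten": self.whiten},
                      fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: str, sidecar_path: str) -> "ReductionModel":
        data = np.load(path if path.endswith(".npz") else path + ".npz")
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        return cls(n_components=meta["n_components"], whiten=meta["whiten"],
                   component_basis=data["basis"], center=data["center"],
                   explained_variance=data["var"],
                   explained_variance_ratio=data["ratio"])


def default_n_components(n_samples: int, n_features: int) -> int:
    return min(DEFAULT_COMPONENTS, n_samples - 1, n_features)


def fit_reduction(features: FeatureMatrix, n_components: int | None = None,
                  whiten: bool = False) -> ReductionModel:
    """Fit PCA on the feature rows.

    Components are ordered by decreasing explained variance.  The sign of
    each component is fixed so its largest-magnitude loading is positive,
    making the fit deterministic.
    """
    x = features.values
    n, d = x.shape
    if n < 2:
        raise ValueError("need at least 2 rows to fit a reduction")
    if n_components is None:
        n_components = default_n_components(n, d)
    if not 1 <= n_components <= min(n - 1, d):
        raise ValueError(
            f"n_components must be in [1, {min(n - 1, d)}], got {n_components}")
    pca = PCA(n_components=n_components, whiten=False, svd_solver="full")
    pca.fit(x)
    basis = pca.components_.T.copy()   # D×d
    for j in range(basis.shape[1]):
        col = basis[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            basis[:, j] = -col
    return ReductionModel(
        n_components=n_components,
        component_basis=basis,
        center=pca.mean_.copy(),
        explained_variance=pca.explained_variance_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        whiten=whiten,
    )


def apply_reduction(model: ReductionModel, features: FeatureMatrix) -> FeatureMatrix:
    """Project features onto the fitted basis (whitening if configured)."""
    x = features.values
    if x.shape[1] != model.component_basis.shape[0]:
        raise ValueError(
            f"feature dimension {x.shape[1]} does not match model "
            f"dimension {model.component_basis.shape[0]}")
    z = (x - model.center) @ model.component_basis
    if model.whiten:
        z = z / np.sqrt(np.maximum(model.explained_variance, 1e-30))
    return FeatureMatrix(values=z, ids=list(features.ids))


def l2_normalize(features: FeatureMatrix) -> FeatureMatrix:
    """Scale every row to unit Euclidean norm.

    Zero rows (possible when a random backbone leaves features dead) are
    kept as zero vectors; their count is reported through a warning.
    Idempotent.
    """
    x = features.values
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    zero_rows = int((norms[:, 0] == 0).sum())
    if zero_rows:
        warnings.warn(f"l2_normalize: {zero_rows} zero row(s) left unscaled",
                      RuntimeWarning, stacklevel=2)
    safe = np.where(norms == 0, 1.0, norms)
    return FeatureMatrix(values=x / safe, ids=list(features.ids))
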