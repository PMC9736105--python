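"""Grad-CAM heatmaps for the maturity identification branch.

Gradient-weighted class activation mapping localises the image regions
driving a stage prediction: the gradient of the target stage's logit with
respect to the last convolutional activation maps is spatially averaged
into per-channel weights, the weighted channel sum is rectified,
upsampled bilinearly to the input size, and min-max normalised.  On fruit
images the interesting question is whether the model looks at the peel,
the crack, or the exposed seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from PIL import Image
from skimage.transform import resize as _sk_resize

from camgrade.backbone import Backbone, Conv2d
from camgrade.synthetic import FruitImage
from camgrade.training import ClassifierHead, DeepClusterResults


@dataclass
class HeatMap:
    """A [0,1] saliency map aligned with the input image."""

    values: np.ndarray
    target_stage: int
    raw_score: float
    all_zero: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("heatmap must be 2-D")
        if not self.all_zero and (v.min() < 0 or v.max() > 1):
            raise ValueError("heatmap values must lie in [0, 1]")
        self.values = v

    def top_decile_mask(self) -> np.ndarray:
        """Boolean mask of the hottest 10% of pixels."""
        cut = np.quantile(self.values, 0.9)
        return self.values >= cut

    def bbox_mass_fraction(self, bbox: tuple[int, int, int, int]) -> float:
        """Fraction of top-decile heat mass inside a (r0,c0,r1,c1) box."""
        mask = self.top_decile_mask()
        total = self.values[mask].sum()
        if total == 0:
            return 0.0
        r0, c0, r1, c1 = bbox
        inside = np.zeros_like(mask)
        inside[r0:r1, c0:c1] = True
        return float(self.values[mask & inside].sum() / total)


def _resolve_model(model) -> tuple[Backbone, ClassifierHead]:
    if isinstance(model, DeepClusterResults):
        return model.backbone, model.head
    backbone, head = model
    return backbone, head


def gradcam_heatmap(model, image: FruitImage, target_stage: int) -> HeatMap:
    """Grad-CAM map of one image for one target stage.

    ``model`` is either a fitted :class:`DeepClusterResults` or a
    ``(backbone, head)`` pair.  The map is computed at the last conv
    layer's rectified activation, upsampled to the input size, and
    min-max normalised; an identically-zero map (no positive evidence)
    is returned unnormalised with ``all_zero=True``.
    """
    backbone, head = _resolve_model(model)
    if not any(isinstance(l, Conv2d) for l in backbone.layers):
        raise ValueError("model has no convolutional layer to explain")
    if not 0 <= target_stage < head.k:
        raise ValueError(f"target_stage must be in [0, {head.k})")
    x = backbone.preprocess([image])

    # Forward, caching the last conv block's rectified activation.
    split = backbone.last_conv_index + 1   # layer index after the conv's ReLU
    h = x
    for layer in backbone.layers[:split]:
        h = layer.forward(h)
    activation = h                          # (1, C, Hc, Wc)
    for layer in backbone.layers[split:]:
        h = layer.forward(h)
    logits = head.logits(h)
    score = float(logits[0, target_stage])

    # Backward from the target logit to the cached activation.
    dlogits = np.zeros_like(logits)
    dlogits[0, target_stage] = 1.0
    dfeat = head.backward(dlogits)
    grad = backbone.backward(dfeat, until=split)

    weights = grad.mean(axis=(2, 3))        # (1, C) spatially averaged
    cam = np.maximum((weights[:, :, None, None] * activation).sum(axis=1), 0.0)[0]
    size = image.size
    cam = _sk_resize(cam, size, order=1, mode="edge", anti_aliasing=False)
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak <= 0:
        return HeatMap(values=np.zeros(size), target_stage=target_stage,
                       raw_score=score, all_zero=True)
    cam = (cam - cam.min()) / (peak - cam.min())
    return HeatMap(values=cam, target_stage=target_stage, raw_score=score)


def heatmap_overlay(image: FruitImage, heatmap: HeatMap,
                    colormap: str = "jet", alpha: float = 0.45) -> np.ndarray:
    """Alpha-blend a colormapped heatmap onto the image (uint8 RGB).

    Blending weight scales with the local heat, so a zero map returns the
    original image and warm colours mark strongly contributing regions.
    """
    if heatmap.values.shape != image.size:
        raise ValueError("heatmap and image dimensions differ")
    cmap = colormaps[colormap]
    colour = (cmap(heatmap.values)[..., :3] * 255.0)
    base = image.pixels.astype(np.float64)
    w = alpha * heatmap.values[..., None]
    out = (1.0 - w) * base + w * colour
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def save_overlay(path: str, image: FruitImage, heatmap: HeatMap,
                 colormap: str = "jet") -> None:
    Image.fromarray(heatmap_overlay(image, heatmap, colormap)).save(path)
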