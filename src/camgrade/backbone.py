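"""Convnet backbone and feature extraction, implemented in NumPy.

The grading pipeline uses a randomly initialised VGG-style network purely
as a feature extractor: the activations of the penultimate fully connected
layer are the image representation that gets clustered.  Random convnet
features carry far more structure than random projections of raw pixels —
the convolution/pooling prior alone groups images by colour and local
texture — which is what makes unsupervised clustering of them work at all.

Two scales are provided:

* ``full`` — the VGG16-D layout (13 conv layers in 5 blocks, 2×2 max
  pools, then FC-4096, FC-4096) with the final classification layer
  removed, emitting 4096-dimensional features at 224×224 input.
* ``tiny`` — a 3-block analogue (8/16/32 channels, then FC-128) with the
  same conv-stack → penultimate-FC structure, sized for 64×64 inputs and
  fast CPU experiments.

All layers implement explicit ``forward``/``backward`` passes, so the same
code supports feature extraction, pseudo-label training by SGD with
momentum, and Grad-CAM (which needs gradients at the last conv layer).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize as _sk_resize

from camgrade.synthetic import FruitImage

# Fixed preprocessing constants (dataset-independent for reproducibility).
_PREPROC_MEAN = 0.5
_PREPROC_STD = 0.25


# ---------------------------------------------------------------------------
# Layers

class Layer:
    """A differentiable layer with explicit parameter/gradient storage."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """3×3 (or k×k) convolution, stride 1, 'same' zero padding."""

    def __init__(self, c_in: int, c_out: int, ksize: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.ksize = c_in, c_out, ksize
        fan_in = c_in * ksize * ksize
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, ksize, ksize))
        self.params = {"W": w.astype(np.float32),
                       "b": np.zeros(c_out, dtype=np.float32)}
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.ksize
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        n, _, h, w = x.shape
        # windows: (N, C, H, W, k, k) view over the padded input
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, -1)
        wmat = self.params["W"].reshape(self.c_out, -1)
        out = cols @ wmat.T + self.params["b"]
        self._cache = (x.shape, cols)
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (xshape, cols) = self._cache
        n, c, h, w = xshape
        k = self.ksize
        pad = k // 2
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.grads["W"] = (dflat.T @ cols).reshape(self.params["W"].shape)
        self.grads["b"] = dflat.sum(axis=0)
        dcols = (dflat @ self.params["W"].reshape(self.c_out, -1))
        dcols = dcols.reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, pad:pad + h, pad:pad + w]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2d(Layer):
    """2×2 max pooling, stride 2; ties resolve to the first window index."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2d requires even spatial dims")
        win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(n, c, h // 2, w // 2, 4)
        self._argmax = win.argmax(axis=-1)
        self._xshape = x.shape
        return np.take_along_axis(win, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        dwin = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dwin, self._argmax[..., None], dout[..., None], axis=-1)
        dwin = dwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dwin.reshape(n, c, h, w)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.params = {"W": w.astype(np.float32),
                       "b": np.zeros(d_out, dtype=np.float32)}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


# ---------------------------------------------------------------------------
# Backbone

@dataclass(frozen=True)
class BackboneConfig:
    """Configuration of the feature-extracting network.

    ``full`` reproduces the VGG16-D topology with the last fully connected
    layer removed (4096-d features); ``tiny`` is a 3-conv-block analogue
    with 128-d features for desk-scale runs.  ``sobel_preprocess`` applies
    a fixed Sobel edge filter (2 channels: gray + gradient magnitude)
    before the conv stack, as some deep-clustering setups do; it is off by
    default.
    """

    scale: str = "tiny"
    input_size: int = 64
    feature_dim: int | None = None
    init_seed: int = 0
    sobel_preprocess: bool = False

    def __post_init__(self) -> None:
        if self.scale not in ("tiny", "full"):
            raise ValueError("scale must be 'tiny' or 'full'")
        dim = self.resolved_feature_dim
        if dim <= 0:
            raise ValueError("feature_dim must be positive")
        if self.scale == "tiny" and dim > 512:
            raise ValueError("tiny scale supports feature_dim <= 512")
        n_pools = 5 if self.scale == "full" else 3
        if self.input_size % (2 ** n_pools) or self.input_size < 2 ** n_pools:
            raise ValueError(
                f"input_size must be a positive multiple of {2 ** n_pools} "
                f"for scale={self.scale!r}")

    @property
    def resolved_feature_dim(self) -> int:
        if self.feature_dim is not None:
            return self.feature_dim
        return 4096 if self.scale == "full" else 512


_VGG16_BLOCKS = ((64, 64), (128, 128), (256, 256, 256),
                 (512, 512, 512), (512, 512, 512))
_TINY_BLOCKS = ((32,), (64,), (128,))


class Backbone:
    """Conv stack plus penultimate fully connected feature head."""

    def __init__(self, config: BackboneConfig):
        self.config = config
        rng = np.random.default_rng(config.init_seed)
        c_in = 2 if config.sobel_preprocess else 3
        blocks = _VGG16_BLOCKS if config.scale == "full" else _TINY_BLOCKS
        self.layers: list[Layer] = []
        self.last_conv_index = -1
        size = config.input_size
        for block in blocks:
            for c_out in block:
                self.layers.append(Conv2d(c_in, c_out, 3, rng))
                self.last_conv_index = len(self.layers)  # index after its ReLU
                self.layers.append(ReLU())
                c_in = c_out
            self.layers.append(MaxPool2d())
            size //= 2
        self.layers.append(Flatten())
        flat_dim = c_in * size * size
        feat = config.resolved_feature_dim
        if config.scale == "full":
            self.layers.append(Linear(flat_dim, 4096, rng))
            self.layers.append(ReLU())
            self.layers.append(Linear(4096, feat, rng))
            self.layers.append(ReLU())
        else:
            self.layers.append(Linear(flat_dim, feat, rng))
            self.layers.append(ReLU())
        self.feature_dim = feat

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Map a preprocessed batch (N,C,H,W) to features (N, feature_dim)."""
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dfeat: np.ndarray, until: int = 0) -> np.ndarray:
        """Backpropagate a feature-gradient; stop before layer ``until``.

        Returns the gradient at the output of layer ``until - 1`` (i.e. the
        input gradient of layer ``until``).  ``until=0`` goes all the way to
        the input; Grad-CAM passes ``until=last_conv_index`` to read the
        gradient at the last conv activation.
        """
        grad = dfeat
        for layer in reversed(self.layers[until:]):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, name) for layer in self.layers for name in layer.params]

    def weight_checksum(self) -> float:
        """Deterministic scalar summary of all weights (for identity tests)."""
        return float(sum(np.abs(layer.params[n]).sum()
                         for layer, n in self.parameters()))

    # -- preprocessing ------------------------------------------------------
    def preprocess(self, images: list[FruitImage]) -> np.ndarray:
        """Resize, scale to [0,1], standardize; returns (N,C,H,W) float32."""
        if not images:
            raise ValueError("no images given")
        sizes = {img.size for img in images}
        if len(sizes) > 1:
            raise ValueError(f"images have mixed sizes: {sorted(sizes)}")
        target = self.config.input_size
        batch = []
        for img in images:
            arr = img.pixels.astype(np.float32) / 255.0
            if img.size != (target, target):
                arr = _sk_resize(arr, (target, target), order=1,
                                 anti_aliasing=True, preserve_range=True)
            arr = (arr - _PREPROC_MEAN) / _PREPROC_STD
            arr = arr.transpose(2, 0, 1)
            if self.config.sobel_preprocess:
                arr = _sobel_channels(arr)
            batch.append(arr.astype(np.float32))
        return np.stack(batch)


def _sobel_channels(chw: np.ndarray) -> np.ndarray:
    """Replace RGB with (grayscale, Sobel gradient magnitude)."""
    gray = chw.mean(axis=0)
    kx = np.array([[1, 0, -1], [2, 0, -2], [1, 0, -1]], dtype=np.float32) / 4
    gp = np.pad(gray, 1, mode="edge")
    win = sliding_window_view(gp, (3, 3))
    gx = (win * kx).sum(axis=(-2, -1))
    gy = (win * kx.T).sum(axis=(-2, -1))
    return np.stack([gray, np.sqrt(gx ** 2 + gy ** 2)])


@dataclass
class FeatureMatrix:
    """N×D feature matrix with row-aligned image identifiers."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if len(self.ids) != self.values.shape[0]:
            raise ValueError("ids length must match row count")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def save(self, matrix_path: str, ids_path: str) -> None:
        np.save(matrix_path, self.values)
        with open(ids_path, "w") as fh:
            fh.write("id\n")
            fh.writelines(f"{i}\n" for i in self.ids)

    @classmethod
    def load(cls, matrix_path: str, ids_path: str) -> "FeatureMatrix":
        values = np.load(matrix_path)
        with open(ids_path) as fh:
            ids = [line.strip() for line in fh][1:]
        return cls(values=values, ids=ids)


def build_backbone(config: BackboneConfig) -> Backbone:
    """Construct a backbone with deterministic random initialisation."""
    return Backbone(config)


def extract_features(backbone: Backbone, images: list[FruitImage],
                     batch_size: int = 32) -> FeatureMatrix:
    """Run images through the backbone; returns penultimate-FC activations.

    Purely functional (no stochastic layers), so the output is independent
    of the batch partitioning.
    """
    if not images:
        raise ValueError("images must be non-empty")
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    x = backbone.preprocess(images)
    rows = []
    for start in range(0, len(images), batch_size):
        rows.append(backbone.forward(x[start:start + batch_size]))
    ids = [img.sample_id if img.sample_id is not None else f"img_{i:05d}"
           for i, img in enumerate(images)]
    return FeatureMatrix(values=np.concatenate(rows, axis=0), ids=ids)
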