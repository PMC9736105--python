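"""Synthetic oil-tea fruit images and per-sample property tables.

Real studies of *Camellia oleifera* maturity work from orchard photographs
and destructive laboratory assays, neither of which is distributable.  This
module emulates both sides of such a dataset:

* **Images** — a single fruit (an ellipse) on a foliage-like background.
  Maturity is expressed the way field workers describe it: unripe fruit
  have a sleek green, indehiscent peel; ripe fruit a slightly cracked peel
  with seeds just visible; overripe fruit a rough, obviously cracked peel
  with clearly exposed seeds.  The renderer parameterises exactly those
  cues: peel hue, peel texture roughness, crack area and exposed-seed area.

* **Property tables** — per-fruit physical measurements (diameters, fresh
  and dry seed weight, moisture) and seed quality assays (oil, soluble
  protein, soluble sugar, starch), drawn per stage from configurable
  normal distributions whose defaults are the published stage means and
  standard deviations for the Huaxin cultivar.

Everything is driven by explicit integer seeds and is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skimage.color import hsv2rgb
from skimage.draw import ellipse as _draw_ellipse
from skimage.transform import resize as _sk_resize

#: Canonical stage order, from least to most mature.
STAGES: tuple[str, str, str] = ("unripe", "ripe", "overripe")

#: Exposed seed area may not exceed this fraction of the crack area.
SEED_EXPOSURE_CAP = 0.8

#: Hue (degrees) that the ``separation`` knob contracts stage hues toward.
_GRAND_HUE = 60.0

# Stage phenotype base parameters at separation 1.0:
# (hue_mean deg, hue_jitter deg, peel_roughness, crack_fraction, seed_exposure)
_BASE_PHENOTYPES = {
    "unripe": (108.0, 7.0, 0.03, 0.0, 0.0),
    "ripe": (52.0, 7.0, 0.08, 0.055, 0.015),
    "overripe": (27.0, 7.0, 0.16, 0.16, 0.06),
}

#: Per-stage (mean, sd) of each measured property.  Physical properties are
#: per-fruit measurements; quality properties are assayed on pooled seed
#: material and reported as means of three independent determinations.
REFERENCE_PROPERTIES: dict[str, dict[str, tuple[float, float]]] = {
    "transverse_diameter_mm": {
        "unripe": (46.05, 1.54), "ripe": (47.31, 1.65), "overripe": (49.32, 1.57)},
    "vertical_diameter_mm": {
        "unripe": (38.78, 1.33), "ripe": (40.10, 1.95), "overripe": (40.64, 1.71)},
    "dry_seed_weight_g": {
        "unripe": (8.06, 0.41), "ripe": (12.44, 1.02), "overripe": (11.05, 0.38)},
    "moisture_pct": {
        "unripe": (69.55, 3.74), "ripe": (58.79, 2.13), "overripe": (48.15, 0.62)},
    "oil_pct": {
        "unripe": (39.12, 0.99), "ripe": (46.05, 0.49), "overripe": (44.42, 0.53)},
    "soluble_protein_pct": {
        "unripe": (5.21, 0.22), "ripe": (5.61, 0.16), "overripe": (6.11, 0.07)},
    "soluble_sugar_pct": {
        "unripe": (25.69, 1.16), "ripe": (19.28, 3.85), "overripe": (13.75, 0.93)},
    "starch_pct": {
        "unripe": (3.31, 0.55), "ripe": (2.30, 0.24), "overripe": (1.54, 0.82)},
}

_PERCENT_PROPERTIES = frozenset(
    p for p in REFERENCE_PROPERTIES if p.endswith("_pct"))


@dataclass(frozen=True)
class StagePhenotype:
    """Rendering parameters of one maturity stage.

    ``crack_fraction`` is the target crack-mask area as a fraction of the
    fruit area (the renderer is calibrated so the rendered crack area
    matches it in expectation); ``seed_exposure`` is the exposed-seed area
    as a fraction of fruit area and is capped relative to the crack.
    Unripe fruit are indehiscent by definition, so their crack fraction
    must be zero.
    """

    stage: str
    hue_mean: float
    hue_jitter: float = 7.0
    peel_roughness: float = 0.05
    crack_fraction: float = 0.0
    seed_exposure: float = 0.0

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        for name in ("peel_roughness", "crack_fraction", "seed_exposure"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.hue_jitter < 0:
            raise ValueError("hue_jitter must be nonnegative")
        if self.stage == "unripe" and self.crack_fraction != 0.0:
            raise ValueError("unripe fruit are indehiscent: crack_fraction must be 0")
        if self.seed_exposure > SEED_EXPOSURE_CAP * self.crack_fraction + 1e-12:
            raise ValueError(
                "seed_exposure exceeds the crack-dependent cap "
                f"({SEED_EXPOSURE_CAP} * crack_fraction)")


@dataclass
class FruitImage:
    """An RGB fruit image with optional ground truth.

    ``truth_stage`` is present only for generated images — photographs of
    real fruit carry no stage label.  ``crack_bbox`` is the (r0, c0, r1, c1)
    bounding box (half-open) of the rendered crack region, kept for
    localization tests of saliency maps.
    """

    pixels: np.ndarray
    truth_stage: str | None = None
    sample_id: str | None = None
    crack_bbox: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be an H×W×3 array")
        if px.shape[0] < 32 or px.shape[1] < 32:
            raise ValueError("image must be at least 32×32")
        if self.truth_stage is not None and self.truth_stage not in STAGES:
            raise ValueError(f"unknown stage {self.truth_stage!r}")
        self.pixels = px.astype(np.uint8)

    @property
    def size(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class SamplePropertyRecord:
    """Physical and quality measurements of one fruit sample.

    Weights are in grams, diameters in millimetres, everything else in
    percent.  Moisture content is definitionally tied to the two seed
    weights: M_c = 100·(W_f − W_d)/W_f.
    """

    sample_id: str
    stage: str
    transverse_diameter_mm: float
    vertical_diameter_mm: float
    fresh_seed_weight_g: float
    dry_seed_weight_g: float
    moisture_pct: float
    oil_pct: float
    soluble_protein_pct: float
    soluble_sugar_pct: float
    starch_pct: float

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if not (0 < self.dry_seed_weight_g <= self.fresh_seed_weight_g):
            raise ValueError("weights must satisfy 0 < W_d <= W_f")
        for name in ("moisture_pct", "oil_pct", "soluble_protein_pct",
                     "soluble_sugar_pct", "starch_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100], got {v}")

    @classmethod
    def fieldnames(cls) -> list[str]:
        return [f.name for f in dataclasses.fields(cls)]


def default_phenotypes(separation: float = 1.0) -> dict[str, StagePhenotype]:
    """Stage phenotypes with hue bands scaled by a single separation knob.

    ``separation`` = 1 gives the default bands, whose tails overlap
    slightly between adjacent stages (the ambiguity real orchards show);
    larger values pull the stage hues apart, smaller values blend them.
    """
    if separation < 0:
        raise ValueError("separation must be nonnegative")
    out = {}
    for stage, (hue, jit, rough, crack, seed) in _BASE_PHENOTYPES.items():
        out[stage] = StagePhenotype(
            stage=stage,
            hue_mean=_GRAND_HUE + separation * (hue - _GRAND_HUE),
            hue_jitter=jit,
            peel_roughness=rough,
            crack_fraction=crack,
            seed_exposure=seed,
        )
    return out


def _coarse_noise(rng: np.random.Generator, size: int, cells: int, sd: float) -> np.ndarray:
    """Band-limited noise: a coarse normal grid upsampled bilinearly."""
    coarse = rng.normal(0.0, sd, size=(cells, cells))
    return _sk_resize(coarse, (size, size), order=1, mode="reflect",
                      anti_aliasing=False)


def generate_image(phenotype: StagePhenotype, size: int = 64,
                   rng_seed: int = 0, noise_sd: float = 0.02) -> FruitImage:
    """Render one fruit image for a stage phenotype.

    The fruit is an ellipse with jittered centre and radii on a mottled
    foliage background.  Peel hue is drawn from the stage band; if the
    phenotype cracks, a dark wedge through the fruit centre is rendered
    with total area ``crack_fraction`` of the fruit area, and a brighter
    seed strip inside it covering ``seed_exposure`` of the fruit area.
    Additive Gaussian pixel noise (sd in [0,1] units) is applied last.
    Deterministic for a fixed seed.
    """
    if size < 32:
        raise ValueError("size must be >= 32")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(rng_seed)

    # Background: desaturated foliage green with coarse value mottling.
    hsv = np.empty((size, size, 3), dtype=np.float64)
    hsv[..., 0] = ((95.0 + rng.normal(0, 6)) % 360.0) / 360.0
    hsv[..., 1] = 0.28
    hsv[..., 2] = np.clip(0.45 + _coarse_noise(rng, size, 8, 0.10), 0.05, 0.9)

    # Fruit geometry: jittered centre and radii.
    cy = size / 2 + rng.uniform(-0.08, 0.08) * size
    cx = size / 2 + rng.uniform(-0.08, 0.08) * size
    ry = size * rng.uniform(0.30, 0.36)
    rx = ry * rng.uniform(0.85, 1.0)
    rr, cc = _draw_ellipse(cy, cx, ry, rx, shape=(size, size))
    fruit = np.zeros((size, size), dtype=bool)
    fruit[rr, cc] = True
    fruit_area = int(fruit.sum())

    # Peel colouring: stage hue band + texture roughness on the value channel.
    hue = (rng.normal(phenotype.hue_mean, phenotype.hue_jitter)) % 360.0
    tex = _coarse_noise(rng, size, 16, phenotype.peel_roughness)
    yy, xx = np.mgrid[0:size, 0:size]
    radial = np.sqrt(((yy - cy) / max(ry, 1e-9)) ** 2
                     + ((xx - cx) / max(rx, 1e-9)) ** 2)
    shade = 1.0 - 0.25 * np.clip(radial, 0, 1) ** 2
    hsv[fruit, 0] = hue / 360.0
    hsv[fruit, 1] = 0.62
    hsv[fruit, 2] = np.clip((0.58 + tex[fruit]) * shade[fruit], 0.05, 1.0)

    crack_bbox = None
    if phenotype.crack_fraction > 0 and fruit_area > 0:
        # A straight wedge through the fruit centre; its width is solved so
        # the in-fruit crack area matches crack_fraction * fruit_area.
        theta = rng.uniform(0, np.pi)
        u = np.array([np.cos(theta), np.sin(theta)])
        d_along = (yy - cy) * u[0] + (xx - cx) * u[1]
        d_perp = -(yy - cy) * u[1] + (xx - cx) * u[0]
        length = 1.7 * ry
        width = phenotype.crack_fraction * fruit_area / length
        crack = fruit & (np.abs(d_along) <= length / 2) & (np.abs(d_perp) <= width / 2)
        if crack.any():
            hsv[crack, 0] = 25.0 / 360.0
            hsv[crack, 1] = 0.55
            hsv[crack, 2] = 0.12
            if phenotype.seed_exposure > 0:
                # Exposed seeds: a bright tan strip along the crack axis.
                ratio = phenotype.seed_exposure / phenotype.crack_fraction
                seeds = crack & (np.abs(d_perp) <= ratio * width / 2)
                hsv[seeds, 0] = 35.0 / 360.0
                hsv[seeds, 1] = 0.40
                hsv[seeds, 2] = 0.78
            rows = np.flatnonzero(crack.any(axis=1))
            cols = np.flatnonzero(crack.any(axis=0))
            crack_bbox = (int(rows[0]), int(cols[0]),
                          int(rows[-1]) + 1, int(cols[-1]) + 1)

    rgb = hsv2rgb(hsv)
    if noise_sd > 0:
        rgb = rgb + rng.normal(0.0, noise_sd, rgb.shape)
    pixels = np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)
    return FruitImage(pixels=pixels, truth_stage=phenotype.stage,
                      crack_bbox=crack_bbox)


def _as_stage_counts(counts: int | Mapping[str, int]) -> dict[str, int]:
    if isinstance(counts, int):
        return {s: counts for s in STAGES}
    unknown = set(counts) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages in counts: {sorted(unknown)}")
    return {s: int(counts.get(s, 0)) for s in STAGES}


def generate_dataset(n_per_stage: int | Mapping[str, int], size: int = 64,
                     rng_seed: int = 0, separation: float = 1.0,
                     noise_sd: float = 0.02,
                     phenotypes: Mapping[str, StagePhenotype] | None = None,
                     ) -> list[FruitImage]:
    """Generate a shuffled, stage-labelled image set.

    ``n_per_stage`` is either one count applied to every stage or a
    mapping stage → count (so unbalanced designs such as 50/60/50 test
    sets can be emulated).  Per-image variation comes from the phenotype
    jitter inside :func:`generate_image`; each image gets its own derived
    seed so the whole set is reproducible from ``rng_seed``.
    """
    counts = _as_stage_counts(n_per_stage)
    if any(c < 1 for c in counts.values()):
        raise ValueError("need at least one image per requested stage")
    phenos = dict(phenotypes) if phenotypes is not None else default_phenotypes(separation)
    master = np.random.default_rng(rng_seed)
    images: list[FruitImage] = []
    for stage in STAGES:
        for i in range(counts[stage]):
            seed = int(master.integers(0, 2**31 - 1))
            img = generate_image(phenos[stage], size=size, rng_seed=seed,
                                 noise_sd=noise_sd)
            img.sample_id = f"{stage}_{i:04d}"
            images.append(img)
    order = master.permutation(len(images))
    return [images[i] for i in order]


def generate_property_table(
    counts_per_stage: int | Mapping[str, int],
    rng_seed: int = 0,
    reference: Mapping[str, Mapping[str, tuple[float, float]]] | None = None,
    sd_scale: float = 1.0,
) -> list[SamplePropertyRecord]:
    """Draw per-fruit property records stage by stage.

    Each property is drawn Normal(stage mean, stage SD) from ``reference``
    (default: the published Huaxin-cultivar stage table).  Moisture is
    drawn first and the fresh seed weight back-computed from the drawn dry
    weight, W_f = W_d / (1 − M_c/100), so the moisture identity holds
    exactly on every record.  ``sd_scale`` scales all SDs (0 gives
    degenerate draws at the stage means).  Values are clipped to their
    physical ranges.
    """
    counts = _as_stage_counts(counts_per_stage)
    if any(c < 2 for c in counts.values()):
        raise ValueError("need at least two records per stage")
    if sd_scale < 0:
        raise ValueError("sd_scale must be nonnegative")
    ref = reference if reference is not None else REFERENCE_PROPERTIES
    for prop, stages in ref.items():
        for stage, (_, sd) in stages.items():
            if sd < 0:
                raise ValueError(f"negative SD for {prop}/{stage}")

    rng = np.random.default_rng(rng_seed)
    records: list[SamplePropertyRecord] = []
    for stage in STAGES:
        for i in range(counts[stage]):
            draw = {}
            for prop in REFERENCE_PROPERTIES:
                mean, sd = ref[prop][stage]
                draw[prop] = rng.normal(mean, sd_scale * sd)
            moisture = float(np.clip(draw["moisture_pct"], 0.5, 95.0))
            dry = float(max(draw["dry_seed_weight_g"], 0.05))
            fresh = dry / (1.0 - moisture / 100.0)
            for prop in _PERCENT_PROPERTIES:
                draw[prop] = float(np.clip(draw[prop], 0.0, 100.0))
            records.append(SamplePropertyRecord(
                sample_id=f"{stage}_{i:04d}",
                stage=stage,
                transverse_diameter_mm=float(max(draw["transverse_diameter_mm"], 1.0)),
                vertical_diameter_mm=float(max(draw["vertical_diameter_mm"], 1.0)),
                fresh_seed_weight_g=fresh,
                dry_seed_weight_g=dry,
                moisture_pct=moisture,
                oil_pct=draw["oil_pct"],
                soluble_protein_pct=draw["soluble_protein_pct"],
                soluble_sugar_pct=draw["soluble_sugar_pct"],
                starch_pct=draw["starch_pct"],
            ))
    return records
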