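"""File I/O: image directories, property CSVs, manifests, result exports."""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path

import numpy as np
from PIL import Image

from camgrade.synthetic import FruitImage, SamplePropertyRecord, STAGES

_IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg"}


def read_image_dir(path: str | Path, strict: bool = False) -> list[FruitImage]:
    """Load every JPEG/PNG in a directory, sorted by filename.

    Corrupt files are skipped with a warning unless ``strict``.
    Real images carry no truth stage.
    """
    directory = Path(path)
    if not directory.is_dir():
        raise ValueError(f"not a directory: {directory}")
    files = sorted(p for p in directory.iterdir()
                   if p.suffix.lower() in _IMAGE_EXTENSIONS)
    if not files:
        raise ValueError(f"no JPEG/PNG images in {directory}")
    images = []
    for p in files:
        try:
            with Image.open(p) as im:
                arr = np.asarray(im.convert("RGB"))
        except OSError as exc:
            if strict:
                raise ValueError(f"corrupt image {p}: {exc}") from exc
            warnings.warn(f"skipping corrupt image {p}: {exc}", RuntimeWarning,
                          stacklevel=2)
            continue
        images.append(FruitImage(pixels=arr, sample_id=p.stem))
    if not images:
        raise ValueError(f"no readable images in {directory}")
    return images


def write_images(directory: str | Path, images: list[FruitImage],
                 seed: int | None = None) -> Path:
    """Write images as PNGs plus a manifest JSON mapping file → truth/seed."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "images": {}}
    for i, img in enumerate(images):
        name = f"{img.sample_id or f'img_{i:05d}'}.png"
        Image.fromarray(img.pixels).save(directory / name)
        manifest["images"][name] = {
            "truth_stage": img.truth_stage,
            "crack_bbox": list(img.crack_bbox) if img.crack_bbox else None,
        }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return directory


def write_property_csv(path: str | Path,
                       records: list[SamplePropertyRecord]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fields = SamplePropertyRecord.fieldnames()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(fields)
        for r in records:
            writer.writerow([getattr(r, f) for f in fields])
    return path


def read_property_csv(path: str | Path) -> list[SamplePropertyRecord]:
    """Read a property table; schema errors name the offending column."""
    path = Path(path)
    expected = SamplePropertyRecord.fieldnames()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in expected if c not in header]
        if missing:
            raise ValueError(f"property CSV {path} missing column(s): {missing}")
        records = []
        for lineno, row in enumerate(reader, start=2):
            kwargs: dict[str, object] = {}
            for col in expected:
                raw = row[col]
                if col in ("sample_id", "stage"):
                    kwargs[col] = raw
                else:
                    try:
                        kwargs[col] = float(raw)
                    except ValueError as exc:
                        raise ValueError(
                            f"{path}:{lineno}: column {col!r} is not numeric "
                            f"({raw!r})") from exc
            records.append(SamplePropertyRecord(**kwargs))
    return records


def write_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonify)
    return path


def _jsonify(obj):
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
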