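"""Seeded synthetic fruit-freshness image generator.

Produces desk-scale grayscale datasets emulating a three-class
fruit-quality grading task (fresh / mild spoilage / rotten): each image is
a bright disc (the "fruit") on a dark background, with a class-dependent
number of dark circular blemishes ("spoilage spots") and Gaussian pixel
noise, clipped to [0, 1]. The class signal is the spot density, monotone
in the class index, so task difficulty is controllable and interpretable.

The default configuration is 3 balanced classes of 50 images each (150
total) with spot densities 0.0 / 0.15 / 0.4. Images default to 16x16 so
full cross-validation experiments run in minutes; 100x100 is supported
for parity with typical preprocessing pipelines (resize, grayscale,
normalize to [0, 1]).

The spot count per image is Poisson with mean ``density * area`` where
``area`` is the fruit disc area measured in spot-sized units (disc area
divided by single-spot area), so the density reads as the expected
fraction of fruit surface covered by blemishes.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "SyntheticImageSpec",
    "generate_dataset",
    "separability_check",
    "save_dataset",
    "load_dataset",
    "export_png_dataset",
    "load_png_dataset",
    "augment_images",
]

_CLASS_NAMES = ("fresh", "mild", "rotten")


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Generator configuration; defaults define the package's study conditions."""

    n_classes: int = 3
    image_size: int = 16
    n_per_class: int = 50
    spot_density: tuple = (0.0, 0.15, 0.4)
    spot_radius: float = 1.0
    background_level: float = 0.15
    fruit_level: float = 0.85
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.image_size < 4 or self.image_size % 2:
            raise ValueError(f"image_size must be even and >= 4, got {self.image_size}")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be positive")
        dens = tuple(float(d) for d in self.spot_density)
        if len(dens) != self.n_classes:
            raise ValueError(
                f"spot_density needs {self.n_classes} entries, got {len(dens)}"
            )
        if any(d < 0 or d > 1 for d in dens):
            raise ValueError("spot densities must lie in [0, 1]")
        if any(b < a for a, b in zip(dens, dens[1:])):
            raise ValueError("spot_density must be non-decreasing across classes")
        if not 0 <= self.background_level <= 1 or not 0 <= self.fruit_level <= 1:
            raise ValueError("intensity levels must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.spot_radius <= 0:
            raise ValueError("spot_radius must be positive")
        object.__setattr__(self, "spot_density", dens)

    def to_dict(self) -> dict:
        return asdict(self)


def _render_image(spec: SyntheticImageSpec, density: float, rng: np.random.Generator) -> np.ndarray:
    n = spec.image_size
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    # fruit disc with mild jitter in center and radius
    cy, cx = (n - 1) / 2 + rng.uniform(-0.03, 0.03, 2) * n
    radius = 0.38 * n * (1 + rng.uniform(-0.03, 0.03))
    img = np.full((n, n), spec.background_level)
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    img[disc] = spec.fruit_level
    # spoilage spots: Poisson count, centers uniform on the disc
    disc_area = np.pi * radius**2
    spot_area = np.pi * spec.spot_radius**2
    mean_spots = density * disc_area / spot_area
    for _ in range(rng.poisson(mean_spots)):
        r = radius * np.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * np.pi)
        sy, sx = cy + r * np.sin(phi), cx + r * np.cos(phi)
        sr = spec.spot_radius * (1 + rng.uniform(-0.2, 0.2))
        spot = (yy - sy) ** 2 + (xx - sx) ** 2 <= sr**2
        img[spot & disc] = spec.background_level
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_dataset(spec: SyntheticImageSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate (images, labels): balanced classes, deterministic per seed.

    Images have shape (n_classes * n_per_class, image_size, image_size)
    with values in [0, 1]; labels are 0..n_classes-1 in class-block order.
    """
    rng = np.random.default_rng(spec.seed)
    images, labels = [], []
    for cls in range(spec.n_classes):
        for _ in range(spec.n_per_class):
            images.append(_render_image(spec, spec.spot_density[cls], rng))
            labels.append(cls)
    return np.stack(images), np.array(labels, dtype=int)


def separability_check(
    images: np.ndarray,
    labels: np.ndarray,
    train_fraction: float = 0.6,
    seed: int = 0,
) -> float:
    """Holdout accuracy of a mean-intensity threshold classifier.

    Fits per-class mean-intensity centroids on a train split and assigns
    each holdout image to the nearest centroid — a floor on task
    learnability that any real model should clear.
    """
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("separability check needs at least 2 classes")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for c in classes:  # per-class split so every centroid is defined
        idx = rng.permutation(np.flatnonzero(labels == c))
        n_train = max(1, int(round(train_fraction * len(idx))))
        train_parts.append(idx[:n_train])
        test_parts.append(idx[n_train:])
    train_idx = np.concatenate(train_parts)
    test_idx = np.concatenate(test_parts)
    if len(test_idx) == 0:
        raise ValueError("train_fraction leaves no holdout samples")
    mean_int = np.asarray(images).reshape(len(images), -1).mean(axis=1)
    centroids = np.array(
        [mean_int[train_idx][labels[train_idx] == c].mean() for c in classes]
    )
    pred = classes[np.argmin(np.abs(mean_int[test_idx, None] - centroids[None, :]), axis=1)]
    return float(np.mean(pred == labels[test_idx]))


def save_dataset(
    path: str | Path, images: np.ndarray, labels: np.ndarray, spec: SyntheticImageSpec
) -> None:
    """NPZ with images, labels, and a field-for-field spec echo."""
    np.savez(
        path,
        images=np.asarray(images, dtype=float),
        labels=np.asarray(labels, dtype=int),
        spec_json=np.array(json.dumps(spec.to_dict())),
    )


def load_dataset(path: str | Path) -> tuple[np.ndarray, np.ndarray, SyntheticImageSpec]:
    try:
        with np.load(path, allow_pickle=False) as data:
            images = np.asarray(data["images"], dtype=float)
            labels = np.asarray(data["labels"], dtype=int)
            d = json.loads(str(data["spec_json"]))
    except (KeyError, ValueError, OSError) as exc:
        raise ValueError(f"not a valid dataset file: {path} ({exc})") from exc
    d["spot_density"] = tuple(d["spot_density"])
    return images, labels, SyntheticImageSpec(**d)


def export_png_dataset(
    directory: str | Path, images: np.ndarray, labels: np.ndarray
) -> Path:
    """8-bit grayscale PNGs plus a labels.csv; returns the directory path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, lab) in enumerate(zip(images, labels)):
        name = f"img_{i:04d}.png"
        arr = np.round(np.clip(img, 0, 1) * 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(directory / name)
        rows.append((name, int(lab)))
    with open(directory / "labels.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label"])
        writer.writerows(rows)
    return directory


def load_png_dataset(directory: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Reload a PNG-exported dataset (values rescaled to [0, 1])."""
    directory = Path(directory)
    labels_file = directory / "labels.csv"
    if not labels_file.exists():
        raise ValueError(f"missing labels.csv in {directory}")
    images, labels = [], []
    with open(labels_file) as fh:
        for row in csv.DictReader(fh):
            arr = np.asarray(Image.open(directory / row["filename"]).convert("L"))
            images.append(arr.astype(float) / 255.0)
            labels.append(int(row["label"]))
    return np.stack(images), np.array(labels, dtype=int)


def augment_images(
    images: np.ndarray, labels: np.ndarray, n_augmented: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Classical-baseline augmentation: rotation (15 deg), shift (0.1),
    shear (0.1), zoom (0.1), horizontal flip.

    Provided for classical-baseline harnesses only; the quantum pipeline
    trains on unaugmented images (the quanvolution itself emits four
    channels per input).
    """
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    images = np.asarray(images, dtype=float)
    out_imgs, out_labels = [], []
    n = len(images)
    size = images.shape[1]
    for _ in range(n_augmented):
        i = int(rng.integers(n))
        img = images[i]
        angle = rng.uniform(-15, 15)
        img = ndimage.rotate(img, angle, reshape=False, mode="nearest")
        shift = rng.uniform(-0.1, 0.1, size=2) * size
        img = ndimage.shift(img, shift, mode="nearest")
        shear = rng.uniform(-0.1, 0.1)
        img = ndimage.affine_transform(
            img, np.array([[1.0, shear], [0.0, 1.0]]), mode="nearest"
        )
        zoom = 1 + rng.uniform(-0.1, 0.1)
        zoomed = ndimage.zoom(img, zoom, mode="nearest")
        if zoomed.shape[0] >= size:
            a = (zoomed.shape[0] - size) // 2
            img = zoomed[a : a + size, a : a + size]
        else:
            pad = size - zoomed.shape[0]
            img = np.pad(zoomed, ((0, pad), (0, pad)), mode="edge")
        if rng.uniform() < 0.5:
            img = img[:, ::-1]
        out_imgs.append(np.clip(img, 0.0, 1.0))
        out_labels.append(labels[i])
    return np.stack(out_imgs), np.array(out_labels, dtype=int)
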