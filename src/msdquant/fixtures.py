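"""Seeded synthetic data and miniature models.

The dataset stands in for a facial-expression benchmark in shape only:
48x48 grayscale images in seven classes.  Each class is a fixed texture
template — an oriented sinusoidal grating plus a centred Gaussian blob whose
width varies by class — and samples add per-image amplitude jitter and
Gaussian pixel noise.  Orientation structure makes spatial (depthwise)
filters informative while blob width makes channel-mixing (pointwise)
filters informative, so every layer kind of the miniature CNNs earns its
keep.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
from PIL import Image

from .nn import (
    Conv2d,
    DepthwiseConv2d,
    Flatten,
    FloatModel,
    GlobalAvgPool,
    Linear,
    ReLU,
)

__all__ = [
    "FixtureConfig",
    "SyntheticDataset",
    "class_templates",
    "make_dataset",
    "make_model",
    "train_model",
    "save_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class FixtureConfig:
    """Generation parameters of the synthetic 7-class image set."""

    n_classes: int = 7
    image_size: int = 48
    samples_per_class: int = 60  # per class, split train/test below
    train_fraction: float = 2 / 3
    noise: float = 0.25  # Gaussian pixel-noise sigma on the [0, 1] scale
    amplitude_jitter: float = 0.15  # per-sample contrast scaling half-range
    grating_wavelength: float = 7.0  # pixels
    seed: int = 0
    weight_init: str = "he_scaled"


@dataclass
class SyntheticDataset:
    train_images: np.ndarray  # (N, H, W) float64 in [0, 1]
    train_labels: np.ndarray
    test_images: np.ndarray
    test_labels: np.ndarray
    config: FixtureConfig

    @property
    def n_classes(self) -> int:
        return self.config.n_classes


def class_templates(cfg: FixtureConfig) -> np.ndarray:
    """Zero-mean texture template of each class, shape (K, H, W)."""
    s = cfg.image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    cx = cy = (s - 1) / 2.0
    out = np.empty((cfg.n_classes, s, s))
    for k in range(cfg.n_classes):
        theta = np.pi * k / cfg.n_classes
        phase = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
        grating = 0.22 * np.sin(2 * np.pi * phase / cfg.grating_wavelength)
        sigma = s / 12.0 * (1.0 + 0.8 * k / max(1, cfg.n_classes - 1))
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        blob = 0.20 * np.exp(-r2 / (2 * sigma**2))
        t = grating + blob
        out[k] = t - t.mean()
    return out


def make_dataset(cfg: FixtureConfig = FixtureConfig()) -> SyntheticDataset:
    """Render the labelled image set; byte-identical for identical configs."""
    rng = np.random.default_rng(cfg.seed)
    templates = class_templates(cfg)
    n_train = int(round(cfg.samples_per_class * cfg.train_fraction))
    n_test = cfg.samples_per_class - n_train
    s = cfg.image_size

    def render(count: int) -> Tuple[np.ndarray, np.ndarray]:
        images = np.empty((count * cfg.n_classes, s, s))
        labels = np.empty(count * cfg.n_classes, dtype=np.int64)
        i = 0
        for k in range(cfg.n_classes):
            for _ in range(count):
                a = 1.0 + cfg.amplitude_jitter * rng.uniform(-1.0, 1.0)
                img = 0.5 + a * templates[k]
                if cfg.noise > 0:
                    img = img + rng.normal(0.0, cfg.noise, size=(s, s))
                images[i] = np.clip(img, 0.0, 1.0)
                labels[i] = k
                i += 1
        return images, labels

    train_x, train_y = render(n_train)
    test_x, test_y = render(n_test)
    return SyntheticDataset(train_x, train_y, test_x, test_y, cfg)


def template_matcher_accuracy(dataset: SyntheticDataset) -> float:
    """Top-1 of a linear correlation classifier against the class templates."""
    templates = class_templates(dataset.config)
    t = templates.reshape(dataset.n_classes, -1)
    x = dataset.test_images.reshape(len(dataset.test_images), -1)
    x = x - x.mean(axis=1, keepdims=True)
    pred = np.argmax(x @ t.T, axis=1)
    return float(np.mean(pred == dataset.test_labels))


def make_model(arch: str = "mini", seed: int = 0, n_classes: int = 7,
               init: str = "he_scaled") -> FloatModel:
    """Build a miniature float CNN with deterministic initialization.

    ``mini`` (default): conv3x3/s2 -> relu -> depthwise3x3/s2 -> relu ->
    pointwise1x1 -> relu -> global-avgpool -> flatten -> linear head.
    ``tiny``: conv3x3/s2 -> relu -> global-avgpool -> flatten -> linear head.
    """
    rng = np.random.default_rng(seed)
    if arch == "mini":
        layers = [
            Conv2d(1, 8, k=3, stride=2, pad=1, rng=rng, init=init),
            ReLU(),
            DepthwiseConv2d(8, k=3, stride=2, pad=1, rng=rng, init=init),
            ReLU(),
            Conv2d(8, 16, k=1, rng=rng, init=init),
            ReLU(),
            GlobalAvgPool(),
            Flatten(),
            Linear(16, n_classes, rng=rng, init=init),
        ]
    elif arch == "tiny":
        layers = [
            Conv2d(1, 6, k=3, stride=2, pad=1, rng=rng, init=init),
            ReLU(),
            GlobalAvgPool(),
            Flatten(),
            Linear(6, n_classes, rng=rng, init=init),
        ]
    else:
        raise ValueError(f"unknown fixture architecture {arch!r}")
    return FloatModel(layers)


def train_model(
    model: FloatModel,
    dataset: SyntheticDataset,
    epochs: int = 25,
    lr: float = 5e-3,
    batch_size: int = 32,
    seed: int = 0,
) -> list:
    """Minimal Adam loop; returns the per-epoch mean training loss."""
    rng = np.random.default_rng(seed)
    x = dataset.train_images[:, None, :, :]
    y = dataset.train_labels
    layers = model.parameters()
    m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in layers]
    v = [{k: np.zeros_like(p) for k, p in l.params.items()} for l in layers]
    b1, b2, eps = 0.9, 0.999, 1e-8
    t = 0
    history = []
    for _ in range(epochs):
        order = rng.permutation(len(x))
        losses = []
        for start in range(0, len(x), batch_size):
            idx = order[start : start + batch_size]
            losses.append(model.loss_and_grad(x[idx], y[idx]))
            t += 1
            for li, layer in enumerate(layers):
                for k, p in layer.params.items():
                    g = layer.grads[k]
                    m[li][k] = b1 * m[li][k] + (1 - b1) * g
                    v[li][k] = b2 * v[li][k] + (1 - b2) * g * g
                    mhat = m[li][k] / (1 - b1**t)
                    vhat = v[li][k] / (1 - b2**t)
                    p -= lr * mhat / (np.sqrt(vhat) + eps)
        history.append(float(np.mean(losses)))
    return history


# ---------------------------------------------------------------------------
# on-disk dataset layout: directory of 8-bit grayscale PNGs + labels.csv


def save_dataset(dataset: SyntheticDataset, path) -> None:
    """Write the raster + manifest layout consumed by the simulator CLI."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for split, images, labels in (
        ("train", dataset.train_images, dataset.train_labels),
        ("test", dataset.test_images, dataset.test_labels),
    ):
        for i, (img, lab) in enumerate(zip(images, labels)):
            name = f"{split}_{i:05d}.png"
            arr = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(root / name)
            rows.append((name, int(lab), split))
    with open(root / "labels.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label", "split"])
        writer.writerows(rows)


def load_dataset(path, config: Optional[FixtureConfig] = None) -> SyntheticDataset:
    """Read a raster + manifest directory back; pixel values are x/255."""
    root = Path(path)
    splits: Dict[str, list] = {"train": [], "test": []}
    with open(root / "labels.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            arr = np.asarray(Image.open(root / row["filename"]), dtype=np.float64) / 255.0
            splits[row["split"]].append((arr, int(row["label"])))
    def stack(items):
        if not items:
            return np.empty((0, 0, 0)), np.empty(0, dtype=np.int64)
        xs = np.stack([a for a, _ in items])
        ys = np.asarray([l for _, l in items], dtype=np.int64)
        return xs, ys
    tr_x, tr_y = stack(splits["train"])
    te_x, te_y = stack(splits["test"])
    cfg = config or FixtureConfig()
    return SyntheticDataset(tr_x, tr_y, te_x, te_y, cfg)
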