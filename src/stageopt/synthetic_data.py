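"""Synthetic stand-ins for the staged-MRI image data and optimizer benchmarks.

The image generator emits a four-class 32x32 RGB dataset whose classes mimic
progressive structural change: each image is a centered bright disc with a
darker interior cavity, and both the cavity radius and the interior
intensity shift monotonically with the class index, scaled by a single
``separability`` knob (0 makes all four class-conditional distributions
identical).  Random per-image translation and Gaussian pixel noise provide
within-class variability.  This is a statistical stand-in, not an MRI
simulation: no anatomy, bias fields or scanner artifacts.

Also provided: Gaussian-cluster tabular surrogates for testing the tier-2
boosters without CNN training, and the standard sphere / Rastrigin /
Rosenbrock benchmark objectives for optimizer tests (returned negated, so
that maximization conventions apply and the optimum value is 0).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "SyntheticImageSpec",
    "make_images",
    "generate_images",
    "load_image_dir",
    "generate_tabular",
    "benchmark_objective",
    "CLASS_NAMES",
]

CLASS_NAMES = ("no_dementia", "very_mild", "mild", "moderate")

# default fixture counts mirror the published test-split supports
DEFAULT_COUNTS = (384, 336, 300, 300)


@dataclass
class SyntheticImageSpec:
    """Parameters of one synthetic image dataset.

    separability scales how far apart the per-class disc geometries are;
    noise_sd is the Gaussian pixel-noise level on a 0-1 intensity scale.
    """

    n_per_class: tuple[int, ...] = DEFAULT_COUNTS
    separability: float = 2.0
    noise_sd: float = 0.08
    image_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_class):
            raise ValueError("class counts must be non-negative")
        if self.separability < 0:
            raise ValueError("separability must be non-negative")


def _class_template(k: int, sep: float, size: int) -> np.ndarray:
    """Disc with an interior cavity; geometry drifts with class index k."""
    r = np.hypot(*np.mgrid[0:size, 0:size] - (size - 1) / 2.0)
    outer = size * 0.40
    # cavity radius and interior brightness shift by sep units per stage
    cavity = size * (0.06 + 0.028 * sep * k)
    interior = 0.55 - 0.09 * sep * k * 0.5
    img = np.zeros((size, size), dtype=np.float32)
    img[r <= outer] = 0.85
    img[r <= outer * 0.72] = interior
    img[r <= cavity] = 0.05
    return img


def make_images(spec: SyntheticImageSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate the dataset in memory.

    Returns (X, y): X is float32 of shape (n, size, size, 3) in [0, 1] with
    the grayscale pattern replicated over 3 channels; y is int labels 0-3.
    Deterministic given the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    xs, ys = [], []
    for k, n_k in enumerate(spec.n_per_class):
        base = _class_template(k, spec.separability, size)
        for _ in range(n_k):
            dy, dx = rng.integers(-2, 3, size=2)
            img = np.roll(np.roll(base, dy, axis=0), dx, axis=1)
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
            xs.append(np.clip(img, 0.0, 1.0))
            ys.append(k)
    X = np.stack(xs).astype(np.float32)[..., None].repeat(3, axis=-1)
    return X, np.asarray(ys, dtype=np.int64)


def generate_images(spec: SyntheticImageSpec, out_dir) -> Path:
    """Write the dataset as PNGs in one subdirectory per class, plus a
    ``manifest.csv`` (path, label).  Bitwise-identical on re-run."""
    out = Path(out_dir)
    X, y = make_images(spec)
    rows = []
    counters = {k: 0 for k in range(len(spec.n_per_class))}
    for img, k in zip(X, y):
        k = int(k)
        cls_dir = out / CLASS_NAMES[k]
        cls_dir.mkdir(parents=True, exist_ok=True)
        name = f"{CLASS_NAMES[k]}_{counters[k]:05d}.png"
        counters[k] += 1
        arr = (img * 255).round().astype(np.uint8)
        Image.fromarray(arr).save(cls_dir / name)
        rows.append((str(Path(CLASS_NAMES[k]) / name), k))
    with open(out / "manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["path", "label"])
        w.writerows(rows)
    return out


def load_image_dir(
    root, image_size: int = 32, class_names: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Load a directory-per-class image tree, resizing to RGB image_size^2.

    Class indices follow the sorted subdirectory names unless an explicit
    ordering is given (the four canonical stage names are recognized).
    """
    root = Path(root)
    subdirs = [d for d in sorted(root.iterdir()) if d.is_dir()]
    if class_names is None:
        names = [d.name for d in subdirs]
        if set(names) == set(CLASS_NAMES):
            class_names = list(CLASS_NAMES)
        else:
            class_names = names
    xs, ys = [], []
    for k, name in enumerate(class_names):
        d = root / name
        if not d.is_dir():
            raise FileNotFoundError(f"class directory missing: {d}")
        for f in sorted(d.iterdir()):
            if f.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            img = Image.open(f).convert("RGB").resize((image_size, image_size))
            xs.append(np.asarray(img, dtype=np.float32) / 255.0)
            ys.append(k)
    if not xs:
        raise ValueError(f"no images found under {root}")
    return np.stack(xs), np.asarray(ys, dtype=np.int64)


def generate_tabular(
    n_per_class: Sequence[int],
    n_features: int,
    separability: float,
    seed: int,
    direction_seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian clusters: class k sits at separability*k along a per-class
    random unit direction, unit covariance.  Returns (X, y).

    The class directions define the population; they default to the sample
    seed but can be pinned with ``direction_seed`` so that different seeds
    yield fresh samples from the same class-conditional distributions.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    rng = np.random.default_rng(seed)
    dir_rng = np.random.default_rng(
        seed if direction_seed is None else direction_seed
    )
    directions = dir_rng.normal(size=(len(n_per_class), n_features))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    xs, ys = [], []
    for k, n_k in enumerate(n_per_class):
        mean = separability * k * directions[k]
        xs.append(rng.normal(size=(n_k, n_features)) + mean)
        ys.append(np.full(n_k, k, dtype=np.int64))
    return np.concatenate(xs), np.concatenate(ys)


def _sphere(x: np.ndarray) -> float:
    return float(np.sum(x * x))


def _rastrigin(x: np.ndarray) -> float:
    return float(10 * x.size + np.sum(x * x - 10 * np.cos(2 * np.pi * x)))


def _rosenbrock(x: np.ndarray) -> float:
    return float(
        np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1 - x[:-1]) ** 2)
    )


_BENCHMARKS = {"sphere": _sphere, "rastrigin": _rastrigin, "rosenbrock": _rosenbrock}


class CountingObjective:
    """Wraps an objective so callers can observe the evaluation count."""

    def __init__(self, fn: Callable[[np.ndarray], float]):
        self._fn = fn
        self.n_calls = 0

    def __call__(self, x) -> float:
        self.n_calls += 1
        return self._fn(np.asarray(x, dtype=float))


def benchmark_objective(name: str, dim: int) -> CountingObjective:
    """Standard test function, negated for maximization (optimum value 0)."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if name not in _BENCHMARKS:
        raise ValueError(f"unknown benchmark {name!r}")
    fn = _BENCHMARKS[name]
    return CountingObjective(lambda x: -fn(x))
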