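"""Synthetic two-class fundus-like image corpus and augmentation suite.

Real fundus photographs of ocular tumors cannot be redistributed, so this
module draws a stand-in corpus: a textured circular fundus field with
vessel-like curves and a bright optic-disc blob, carrying one lesion per
image.  The benign class gets a single smooth, near-circular, low-contrast
lesion; the malignant class an irregular-border, higher-contrast lesion with
one to five satellite blobs.  Parameter ranges for the two classes overlap so
the classes are separable but not trivially so (a linear probe on stand-in
features should land in the 80-95% band, not at 100%).

The augmentation suite applies random rotation (+-30 degrees), horizontal and
vertical shifts (+-0.1 of the image), shear (+-0.2), zoom (0.8-1.2), optional
horizontal/vertical flips, and brightness scaling (0.8-1.2), with reflect
padding at the borders.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.transform import AffineTransform, resize, warp

__all__ = [
    "GeneratorConfig",
    "AugmentConfig",
    "ImageSample",
    "generate_dataset",
    "write_dataset",
    "load_dataset",
    "sample_augment_params",
    "apply_augment",
    "augment",
    "resize_for_model",
    "stratified_split",
    "MODEL_INPUT_SIZES",
]

CLASS_NAMES = ("benign", "malignant")

MODEL_INPUT_SIZES = {
    "vgg16": 224,
    "googlenet": 224,
    "alexnet": 256,
    "standin": 224,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Corpus parameters.

    Radii are fractions of the image side; irregularity is the relative
    amplitude of the harmonic perturbation of the lesion border; contrast is
    the blend weight of the lesion color against the fundus field.  Class
    ranges deliberately overlap.
    """

    n_per_class: int = 200
    image_size: int = 128
    seed: int = 0
    benign_radius: tuple[float, float] = (0.10, 0.17)
    malignant_radius: tuple[float, float] = (0.10, 0.18)
    benign_irregularity: tuple[float, float] = (0.02, 0.10)
    malignant_irregularity: tuple[float, float] = (0.10, 0.30)
    benign_contrast: tuple[float, float] = (0.10, 0.28)
    malignant_contrast: tuple[float, float] = (0.22, 0.50)
    satellite_count: tuple[int, int] = (1, 5)

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        for name in (
            "benign_radius",
            "malignant_radius",
            "benign_irregularity",
            "malignant_irregularity",
            "benign_contrast",
            "malignant_contrast",
        ):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} range must be non-degenerate")


@dataclass(frozen=True)
class AugmentConfig:
    """Sampling ranges of the augmentation suite (all closed intervals)."""

    rotation_deg: tuple[float, float] = (-30.0, 30.0)
    shift_frac: tuple[float, float] = (-0.1, 0.1)
    shear: tuple[float, float] = (-0.2, 0.2)
    zoom: tuple[float, float] = (0.8, 1.2)
    horizontal_flip: bool = True
    vertical_flip: bool = True
    brightness: tuple[float, float] = (0.8, 1.2)
    seed: int = 0


@dataclass
class ImageSample:
    """RGB uint8 image with binary label (0 benign, 1 malignant)."""

    image: np.ndarray
    label: int
    meta: dict = field(default_factory=dict)

    @property
    def class_name(self) -> str:
        return CLASS_NAMES[self.label]


def _fundus_field(size: int, rng: np.random.Generator) -> np.ndarray:
    """Textured circular fundus-like field with vessels and an optic disc."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cx = cy = (size - 1) / 2.0
    r = np.hypot(xx - cx, yy - cy) / size

    img = np.zeros((size, size, 3))
    disc = r < 0.47
    base = np.array([0.72, 0.34, 0.16]) * (1.0 + rng.uniform(-0.08, 0.08, size=3))
    falloff = np.clip(1.0 - 1.1 * r**2, 0.0, 1.0)
    img[disc] = base * falloff[disc, None]

    # low-frequency blotches
    for _ in range(4):
        bx, by = rng.uniform(0.25 * size, 0.75 * size, size=2)
        sigma = rng.uniform(0.15, 0.35) * size
        amp = rng.uniform(-0.05, 0.05)
        blob = amp * np.exp(-((xx - bx) ** 2 + (yy - by) ** 2) / (2 * sigma**2))
        img[..., 0] += blob
        img[..., 1] += 0.5 * blob

    # optic-disc-like bright spot
    ox = cx + rng.uniform(0.18, 0.30) * size * rng.choice([-1, 1])
    oy = cy + rng.uniform(-0.10, 0.10) * size
    od = np.exp(-((xx - ox) ** 2 + (yy - oy) ** 2) / (2 * (0.045 * size) ** 2))
    img += od[..., None] * np.array([0.25, 0.22, 0.10])

    # vessel-like curves radiating from near the optic disc
    vessel_color = np.array([0.35, 0.08, 0.05])
    for _ in range(6):
        ang = rng.uniform(0, 2 * math.pi)
        curv = rng.uniform(-0.04, 0.04)
        px, py = ox, oy
        for step in range(int(0.9 * size)):
            ang += curv * rng.uniform(0.5, 1.5)
            px += math.cos(ang)
            py += math.sin(ang)
            ix, iy = int(round(px)), int(round(py))
            if 0 <= ix < size and 0 <= iy < size and disc[iy, ix]:
                lo_y, hi_y = max(iy - 1, 0), min(iy + 1, size - 1) + 1
                lo_x, hi_x = max(ix - 1, 0), min(ix + 1, size - 1) + 1
                img[lo_y:hi_y, lo_x:hi_x] = (
                    0.75 * img[lo_y:hi_y, lo_x:hi_x] + 0.25 * vessel_color
                )

    img += rng.normal(0.0, 0.015, size=img.shape)
    img[~disc] *= 0.05
    return np.clip(img, 0.0, 1.0)


def _lesion_mask(
    size: int,
    center: tuple[float, float],
    radius: float,
    irregularity: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean mask with a harmonically perturbed polar boundary."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dx, dy = xx - center[0], yy - center[1]
    dist = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    boundary = np.full_like(theta, radius * size)
    for k in range(2, 7):
        amp = irregularity * rng.uniform(0.2, 1.0) / math.sqrt(k)
        phase = rng.uniform(0, 2 * math.pi)
        boundary *= 1.0 + amp * np.cos(k * theta + phase)
    return dist < boundary


def _render_sample(
    cfg: GeneratorConfig, label: int, rng: np.random.Generator
) -> ImageSample:
    size = cfg.image_size
    img = _fundus_field(size, rng)
    cx = cy = (size - 1) / 2.0

    if label == 0:
        radius = rng.uniform(*cfg.benign_radius)
        irregularity = rng.uniform(*cfg.benign_irregularity)
        contrast = rng.uniform(*cfg.benign_contrast)
        color = np.array([0.85, 0.72, 0.38])  # pale yellowish lesion
        n_sat = 0
    else:
        radius = rng.uniform(*cfg.malignant_radius)
        irregularity = rng.uniform(*cfg.malignant_irregularity)
        contrast = rng.uniform(*cfg.malignant_contrast)
        color = np.array([0.22, 0.10, 0.08])  # dark pigmented lesion
        n_sat = int(rng.integers(cfg.satellite_count[0], cfg.satellite_count[1] + 1))

    # lesion center inside the field
    ang = rng.uniform(0, 2 * math.pi)
    rad = rng.uniform(0.0, 0.22) * size
    center = (cx + rad * math.cos(ang), cy + rad * math.sin(ang))
    mask = _lesion_mask(size, center, radius, irregularity, rng)
    img[mask] = (1.0 - contrast) * img[mask] + contrast * color

    for _ in range(n_sat):
        sang = rng.uniform(0, 2 * math.pi)
        srad = radius * size * rng.uniform(1.2, 2.0)
        scenter = (center[0] + srad * math.cos(sang), center[1] + srad * math.sin(sang))
        smask = _lesion_mask(
            size, scenter, radius * rng.uniform(0.15, 0.35), irregularity, rng
        )
        img[smask] = (1.0 - contrast) * img[smask] + contrast * color

    meta = {
        "radius": radius,
        "irregularity": irregularity,
        "contrast": contrast,
        "satellites": n_sat,
    }
    return ImageSample(
        image=(np.clip(img, 0, 1) * 255).astype(np.uint8), label=label, meta=meta
    )


def generate_dataset(cfg: GeneratorConfig) -> list[ImageSample]:
    """Seeded two-class corpus, ``n_per_class`` images per label, interleaved."""
    rng = np.random.default_rng(cfg.seed)
    samples = []
    for i in range(cfg.n_per_class):
        for label in (0, 1):
            sample = _render_sample(cfg, label, rng)
            sample.meta["index"] = i
            samples.append(sample)
    return samples


def write_dataset(samples: Sequence[ImageSample], outdir) -> Path:
    """PNG files under ``benign/`` and ``malignant/`` plus a manifest CSV."""
    from PIL import Image

    outdir = Path(outdir)
    for name in CLASS_NAMES:
        (outdir / name).mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    counters = {0: 0, 1: 0}
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["filename", "label", "radius", "irregularity", "contrast", "satellites"]
        )
        for s in samples:
            idx = counters[s.label]
            counters[s.label] += 1
            rel = f"{s.class_name}/{s.class_name}_{idx:04d}.png"
            Image.fromarray(s.image).save(outdir / rel)
            writer.writerow(
                [
                    rel,
                    s.label,
                    s.meta.get("radius", ""),
                    s.meta.get("irregularity", ""),
                    s.meta.get("contrast", ""),
                    s.meta.get("satellites", ""),
                ]
            )
    return outdir


def load_dataset(directory) -> list[ImageSample]:
    """Read a two-class ``benign//malignant/`` folder of PNG/JPEG images."""
    from PIL import Image

    directory = Path(directory)
    samples = []
    for label, name in enumerate(CLASS_NAMES):
        class_dir = directory / name
        if not class_dir.is_dir():
            raise FileNotFoundError(f"expected class subfolder {class_dir}")
        for path in sorted(class_dir.iterdir()):
            if path.suffix.lower() in {".png", ".jpg", ".jpeg"}:
                img = np.asarray(Image.open(path).convert("RGB"))
                samples.append(ImageSample(image=img, label=label))
    return samples


def sample_augment_params(cfg: AugmentConfig, rng: np.random.Generator) -> dict:
    """Draw one set of augmentation parameters from the configured ranges."""
    return {
        "rotation_deg": float(rng.uniform(*cfg.rotation_deg)),
        "shift_x": float(rng.uniform(*cfg.shift_frac)),
        "shift_y": float(rng.uniform(*cfg.shift_frac)),
        "shear": float(rng.uniform(*cfg.shear)),
        "zoom": float(rng.uniform(*cfg.zoom)),
        "flip_h": bool(cfg.horizontal_flip and rng.uniform() < 0.5),
        "flip_v": bool(cfg.vertical_flip and rng.uniform() < 0.5),
        "brightness": float(rng.uniform(*cfg.brightness)),
    }


def _is_identity(params: dict) -> bool:
    return (
        params["rotation_deg"] == 0.0
        and params["shift_x"] == 0.0
        and params["shift_y"] == 0.0
        and params["shear"] == 0.0
        and params["zoom"] == 1.0
        and not params["flip_h"]
        and not params["flip_v"]
        and params["brightness"] == 1.0
    )


def apply_augment(image: np.ndarray, params: dict) -> np.ndarray:
    """Apply one sampled augmentation; same shape and dtype, reflect padding."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    out = image.astype(float)
    size_y, size_x = image.shape[:2]

    if not (
        params["rotation_deg"] == 0.0
        and params["shift_x"] == 0.0
        and params["shift_y"] == 0.0
        and params["shear"] == 0.0
        and params["zoom"] == 1.0
    ):
        center = np.array([(size_x - 1) / 2.0, (size_y - 1) / 2.0])
        to_origin = AffineTransform(translation=-center)
        core = AffineTransform(
            rotation=math.radians(params["rotation_deg"]),
            shear=params["shear"],
            scale=(params["zoom"], params["zoom"]),
        )
        back = AffineTransform(
            translation=center
            + np.array([params["shift_x"] * size_x, params["shift_y"] * size_y])
        )
        tform = to_origin + core + back
        out = warp(
            out, tform.inverse, mode="reflect", order=1, preserve_range=True
        )

    if params["flip_h"]:
        out = out[:, ::-1]
    if params["flip_v"]:
        out = out[::-1]

    out = out * params["brightness"]
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        return np.clip(np.rint(out), info.min, info.max).astype(image.dtype)
    return np.clip(out, 0.0, 1.0).astype(image.dtype)


def augment(
    image: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator
) -> np.ndarray:
    """Sample parameters from the configured ranges and apply them."""
    return apply_augment(image, sample_augment_params(cfg, rng))


def resize_for_model(image: np.ndarray, model_name: str) -> np.ndarray:
    """Bilinear resize to the backbone's expected square input size."""
    try:
        target = MODEL_INPUT_SIZES[model_name]
    except KeyError:
        raise ValueError(
            f"unknown model {model_name!r}; expected one of {sorted(MODEL_INPUT_SIZES)}"
        ) from None
    if image.shape[:2] == (target, target):
        return image.copy()
    out = resize(
        image.astype(float),
        (target, target, image.shape[2]),
        order=1,
        preserve_range=True,
        anti_aliasing=True,
    )
    if np.issubdtype(image.dtype, np.integer):
        return np.clip(np.rint(out), 0, 255).astype(image.dtype)
    return out.astype(image.dtype)


def stratified_split(
    samples: Sequence[ImageSample], train_frac: float = 0.7, seed: int = 0
) -> tuple[list[ImageSample], list[ImageSample]]:
    """Per-class shuffled split preserving the class ratio within one image."""
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[ImageSample] = []
    val: list[ImageSample] = []
    for label in (0, 1):
        members = [s for s in samples if s.label == label]
        order = rng.permutation(len(members))
        n_train = int(round(train_frac * len(members)))
        for rank, idx in enumerate(order):
            (train if rank < n_train else val).append(members[idx])
    return train, val
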