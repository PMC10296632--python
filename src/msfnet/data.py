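"""Dataset handling: ISIC-2018 folder reading, deterministic 7:1:2
splitting, the resize/crop/flip/rotate training pipeline, and a synthetic
dermoscopy generator.

The synthetic generator exists so the whole stack — blocks, network, loss,
metrics, training loop — can be exercised end to end without downloading
challenge data.  It emulates the classic hard cases of dermoscopy
segmentation: lesions of widely varying scale, irregular boundaries, low
contrast against the skin, and blurred edges.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import transform as sktransform

__all__ = [
    "Sample",
    "AugmentConfig",
    "SynthConfig",
    "load_isic_folder",
    "save_isic_folder",
    "split_dataset",
    "preprocess_train",
    "preprocess_eval",
    "generate_synthetic",
]


@dataclass
class Sample:
    """One dermoscopy image with its binary lesion mask, aligned pixelwise."""

    image: np.ndarray  # (H, W, 3) float in [0, 1]
    mask: np.ndarray   # (H, W) uint8 in {0, 1}
    id: str = ""


@dataclass
class AugmentConfig:
    """Geometry of the preprocessing pipeline (height, width ordering)."""

    resize_to: tuple[int, int] = (256, 342)
    crop_to: tuple[int, int] = (224, 300)
    rotation_range: tuple[float, float] = (-30.0, 30.0)
    horizontal_flip: bool = True
    vertical_flip: bool = True
    rotate: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.crop_to[0] > self.resize_to[0] or self.crop_to[1] > self.resize_to[1]:
            raise ValueError("crop size must fit inside the resize size")


@dataclass
class SynthConfig:
    """Controls of the synthetic lesion generator."""

    n_images: int = 8
    image_size: tuple[int, int] = (224, 300)
    lesion_area_fraction_range: tuple[float, float] = (0.03, 0.35)
    contrast: float = 0.35
    boundary_blur_sigma: float = 1.5
    irregularity: float = 0.25
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.lesion_area_fraction_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("lesion area fractions must satisfy 0 < lo < hi < 1")
        if self.boundary_blur_sigma < 0:
            raise ValueError("blur sigma must be >= 0")


# ---------------------------------------------------------------------------
# ISIC folder IO


def _mask_path(masks_dir: Path, sample_id: str) -> Path:
    return masks_dir / f"{sample_id}_segmentation.png"


def load_isic_folder(images_dir, masks_dir) -> list[Sample]:
    """Read an ISIC-2018 Task-1 style layout: ``ISIC_<id>.jpg|png`` images
    and ``ISIC_<id>_segmentation.png`` masks.  Masks are binarised at
    128/255.  Samples come back sorted by id."""
    images_dir, masks_dir = Path(images_dir), Path(masks_dir)
    image_files = sorted(
        p for p in images_dir.glob("*") if p.suffix.lower() in {".jpg", ".jpeg", ".png"}
    )
    if not image_files:
        warnings.warn(f"no images found in {images_dir}", stacklevel=2)
        return []
    samples = []
    for img_path in image_files:
        sample_id = img_path.stem
        mask_path = _mask_path(masks_dir, sample_id)
        if not mask_path.exists():
            raise FileNotFoundError(f"missing mask for {sample_id}: expected {mask_path}")
        try:
            image = np.asarray(Image.open(img_path).convert("RGB"), dtype=np.float32) / 255.0
            mask_raw = np.asarray(Image.open(mask_path).convert("L"))
        except OSError as exc:
            raise OSError(f"unreadable file for sample {sample_id}: {exc}") from exc
        mask = (mask_raw >= 128).astype(np.uint8)
        samples.append(Sample(image=image, mask=mask, id=sample_id))
    return samples


def save_isic_folder(samples: list[Sample], images_dir, masks_dir):
    """Write samples back in the same layout (PNG for both)."""
    images_dir, masks_dir = Path(images_dir), Path(masks_dir)
    images_dir.mkdir(parents=True, exist_ok=True)
    masks_dir.mkdir(parents=True, exist_ok=True)
    for s in samples:
        Image.fromarray((np.clip(s.image, 0, 1) * 255).astype(np.uint8)).save(
            images_dir / f"{s.id}.png"
        )
        Image.fromarray((s.mask * 255).astype(np.uint8)).save(_mask_path(masks_dir, s.id))


# ---------------------------------------------------------------------------
# splitting


def split_dataset(samples: list, ratios: tuple = (7, 1, 2), seed: int = 0):
    """Deterministic shuffled partition into train/val/test.

    Boundaries fall at ``ceil(n * cumulative_ratio)``, which reproduces the
    canonical 2594 -> (1816, 260, 518) division at 7:1:2 and keeps the
    partition exact (disjoint and covering) for every n.
    """
    if any(r <= 0 for r in ratios) or len(ratios) != 3:
        raise ValueError("ratios must be three positive numbers")
    n = len(samples)
    if n < 3:
        raise ValueError(f"need at least 3 samples to split, got {n}")
    total = sum(ratios)
    order = np.random.default_rng(seed).permutation(n)
    c1 = math.ceil(n * ratios[0] / total)
    c2 = math.ceil(n * (ratios[0] + ratios[1]) / total)
    train = [samples[i] for i in order[:c1]]
    val = [samples[i] for i in order[c1:c2]]
    test = [samples[i] for i in order[c2:]]
    return train, val, test


# ---------------------------------------------------------------------------
# preprocessing


def _resize(sample: Sample, size: tuple[int, int]) -> Sample:
    if sample.image.shape[:2] == tuple(size):
        return sample
    image = sktransform.resize(sample.image, size, order=1, mode="edge",
                               anti_aliasing=True, preserve_range=True).astype(np.float32)
    mask = sktransform.resize(sample.mask, size, order=0, mode="edge",
                              anti_aliasing=False, preserve_range=True).astype(np.uint8)
    return Sample(image=image, mask=mask, id=sample.id)


def _crop(sample: Sample, top: int, left: int, size: tuple[int, int]) -> Sample:
    h, w = size
    return Sample(
        image=sample.image[top: top + h, left: left + w],
        mask=sample.mask[top: top + h, left: left + w],
        id=sample.id,
    )


def preprocess_train(sample: Sample, cfg: AugmentConfig, rng: np.random.Generator) -> Sample:
    """Stochastic training pipeline: resize, random crop, random flips and a
    random rotation in the configured range, applied identically to image
    and mask (nearest-neighbour for the mask so it stays binary)."""
    s = _resize(sample, cfg.resize_to)
    max_top = cfg.resize_to[0] - cfg.crop_to[0]
    max_left = cfg.resize_to[1] - cfg.crop_to[1]
    top = int(rng.integers(0, max_top + 1))
    left = int(rng.integers(0, max_left + 1))
    s = _crop(s, top, left, cfg.crop_to)
    image, mask = s.image, s.mask
    if cfg.horizontal_flip and rng.random() < 0.5:
        image, mask = image[:, ::-1], mask[:, ::-1]
    if cfg.vertical_flip and rng.random() < 0.5:
        image, mask = image[::-1], mask[::-1]
    if cfg.rotate:
        angle = float(rng.uniform(*cfg.rotation_range))
        image = sktransform.rotate(image, angle, order=1, mode="edge",
                                   preserve_range=True).astype(np.float32)
        mask = sktransform.rotate(mask.astype(float), angle, order=0, mode="constant",
                                  cval=0, preserve_range=True).astype(np.uint8)
    return Sample(image=np.ascontiguousarray(image),
                  mask=np.ascontiguousarray(mask), id=sample.id)


def preprocess_eval(sample: Sample, cfg: AugmentConfig) -> Sample:
    """Deterministic pipeline: resize then centre-crop; no randomness."""
    s = _resize(sample, cfg.resize_to)
    top = (cfg.resize_to[0] - cfg.crop_to[0]) // 2
    left = (cfg.resize_to[1] - cfg.crop_to[1]) // 2
    return _crop(s, top, left, cfg.crop_to)


# ---------------------------------------------------------------------------
# synthetic dermoscopy


def _lesion_mask(shape, centre, radius, irregularity, rng) -> np.ndarray:
    """A filled ellipse whose radius is perturbed by a low-order sinusoidal
    series in the polar angle — an irregular but simply connected blob."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dy = (yy - centre[0]).astype(np.float64)
    dx = (xx - centre[1]).astype(np.float64)
    aspect = rng.uniform(0.7, 1.4)
    theta = np.arctan2(dy * aspect, dx)
    rr = np.hypot(dx, dy * aspect)
    wobble = np.zeros_like(theta)
    for k in range(2, 6):
        wobble += rng.uniform(0, irregularity / 2) * np.sin(k * theta + rng.uniform(0, 2 * np.pi))
    return (rr <= radius * (1.0 + wobble)).astype(np.uint8)


def generate_synthetic(cfg: SynthConfig) -> list[Sample]:
    """Produce ``n_images`` synthetic dermoscopy samples, deterministically
    under ``cfg.seed``.

    Each image is a textured skin-tone background with one lesion — a
    radially perturbed ellipse darker than the skin by ``contrast`` — whose
    painted edges are smoothed with a Gaussian of ``boundary_blur_sigma``
    pixels.  The ground-truth mask is the *unblurred* lesion support, so a
    large sigma reproduces the blurred-boundary failure case.  With
    ``contrast=0`` the lesion leaves no trace in the image at all while the
    mask stays nonempty (the worst-case fixture).
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size
    samples = []
    lo, hi = cfg.lesion_area_fraction_range
    for idx in range(cfg.n_images):
        # skin background: warm base tone + smooth low-frequency texture
        base = np.array([rng.uniform(0.75, 0.9), rng.uniform(0.55, 0.7), rng.uniform(0.45, 0.6)])
        texture = ndimage.gaussian_filter(rng.normal(0, 1, (h, w)), sigma=12)
        texture = texture / (np.abs(texture).max() + 1e-9) * 0.04
        image = np.clip(base[None, None, :] + texture[..., None], 0, 1)

        # rejection-sample an irregular lesion until its area is in range
        for _ in range(200):
            frac = rng.uniform(lo, hi)
            radius = math.sqrt(frac * h * w / math.pi)
            margin = radius * 0.7 + 2
            centre = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
            mask = _lesion_mask((h, w), centre, radius, cfg.irregularity, rng)
            if lo <= mask.mean() <= hi:
                break
        paint = mask.astype(np.float64)
        if cfg.boundary_blur_sigma > 0:
            paint = ndimage.gaussian_filter(paint, sigma=cfg.boundary_blur_sigma)
        # darken towards the lesion interior; strength = contrast
        image = image * (1.0 - cfg.contrast * paint[..., None])
        noise = rng.normal(0, 0.01, (h, w, 3))
        image = np.clip(image + noise, 0, 1).astype(np.float32)
        samples.append(Sample(image=image, mask=mask, id=f"SYN_{cfg.seed:04d}_{idx:04d}"))
    return samples
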