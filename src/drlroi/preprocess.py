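"""Slice conditioning: tumor-centered cropping, augmentation, class balance,
and the patient-level hold-out split.

Coordinates are 0-based and row-major; crops are half-open intervals.  The
crop window is centered on the mask centroid (rounded to the nearest pixel)
and padded with the image minimum where it overruns the frame — an
approximation of the dark air background of a cropped CT.  A lesion whose
bounding box exceeds the window is preserved in full and the crop is then
resized down to the window, so large tumors lose resolution but never get
truncated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize, rotate

from .phantom import Cohort, Sample


class EmptyMaskError(ValueError):
    """The segmentation mask has no foreground: the slice is unusable."""


class SplitError(ValueError):
    """Not enough patients in some class for the requested split."""


@dataclass(frozen=True)
class AugmentConfig:
    """Stochastic augmentation knobs; all-zero means identity."""

    rotation_degrees: tuple[float, float] = (-10.0, 10.0)
    crop_fraction: float = 0.1
    flip_horizontal: float = 0.5
    flip_vertical: float = 0.5
    jitter_brightness: float = 0.1
    jitter_contrast: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in ("flip_horizontal", "flip_vertical"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        for name in ("crop_fraction", "jitter_brightness", "jitter_contrast"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")

    def is_identity(self) -> bool:
        lo, hi = self.rotation_degrees
        return (lo == hi == 0.0 and self.crop_fraction == 0.0
                and self.flip_horizontal == 0.0 and self.flip_vertical == 0.0
                and self.jitter_brightness == 0.0 and self.jitter_contrast == 0.0)


def crop_to_tumor(image: np.ndarray, mask: np.ndarray, window: int = 128) -> np.ndarray:
    """Extract a ``window x window`` crop centered on the lesion.

    The center is the mask centroid rounded to the nearest pixel.  If the
    mask's bounding box is larger than the window in either dimension, the
    full bounding box is cropped instead and resized (bilinear) back to
    ``window x window`` so the lesion boundary is preserved.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise EmptyMaskError("mask has no foreground pixels")

    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    if (y1 - y0) > window or (x1 - x0) > window:
        box = image[y0:y1, x0:x1]
        return resize(box, (window, window), order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)

    cy = int(round(ys.mean()))
    cx = int(round(xs.mean()))
    top = cy - window // 2
    left = cx - window // 2
    out = np.full((window, window), image.min(), dtype=np.float64)
    src_y0, src_y1 = max(top, 0), min(top + window, image.shape[0])
    src_x0, src_x1 = max(left, 0), min(left + window, image.shape[1])
    if src_y0 < src_y1 and src_x0 < src_x1:
        out[src_y0 - top:src_y1 - top, src_x0 - left:src_x1 - left] = \
            image[src_y0:src_y1, src_x0:src_x1]
    return out


def augment(image: np.ndarray, config: AugmentConfig,
            rng: np.random.Generator) -> np.ndarray:
    """Apply rotation, crop-and-resize, flips and intensity jitter, in that
    order; output clipped to [0, 1].  Bit-exact identity when every knob is
    zero (each transform is skipped when its knob is zero)."""
    image = np.asarray(image, dtype=np.float64)
    out = image

    lo, hi = config.rotation_degrees
    if lo != 0.0 or hi != 0.0:
        angle = rng.uniform(lo, hi)
        out = rotate(out, angle, order=1, mode="edge", preserve_range=True)

    if config.crop_fraction > 0.0:
        H, W = out.shape
        f = rng.uniform(0.0, config.crop_fraction)
        ch = max(int(round(H * (1.0 - f))), 1)
        cw = max(int(round(W * (1.0 - f))), 1)
        top = rng.integers(0, H - ch + 1)
        left = rng.integers(0, W - cw + 1)
        out = resize(out[top:top + ch, left:left + cw], (H, W), order=1,
                     mode="edge", anti_aliasing=False, preserve_range=True)

    if config.flip_horizontal > 0.0 and rng.uniform() < config.flip_horizontal:
        out = out[:, ::-1]
    if config.flip_vertical > 0.0 and rng.uniform() < config.flip_vertical:
        out = out[::-1, :]

    if config.jitter_brightness > 0.0:
        b = 1.0 + rng.uniform(-config.jitter_brightness, config.jitter_brightness)
        out = out * b
    if config.jitter_contrast > 0.0:
        c = 1.0 + rng.uniform(-config.jitter_contrast, config.jitter_contrast)
        m = out.mean()
        out = (out - m) * c + m

    if out is image:
        return image
    return np.clip(out, 0.0, 1.0)


def balance_upsample(samples: list[Sample], rng: np.random.Generator) -> list[Sample]:
    """Resample minority-class slices with replacement until per-class slice
    counts are equal.  Originals are all retained; duplicates reference the
    same underlying Sample (augmentation later diversifies them)."""
    labels = np.array([s.label for s in samples])
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("balance_upsample needs both classes present")
    counts = {int(c): int((labels == c).sum()) for c in classes}
    majority = max(counts.values())
    out = list(samples)
    for c, n in counts.items():
        deficit = majority - n
        if deficit > 0:
            pool = [s for s in samples if s.label == c]
            picks = rng.integers(0, len(pool), size=deficit)
            out.extend(pool[i] for i in picks)
    return out


def split_cohort(cohort: Cohort, n_val_per_class: int,
                 seed: int) -> tuple[Cohort, Cohort]:
    """Patient-level hold-out split with a class-balanced validation cohort.

    Exactly ``n_val_per_class`` patients of each class go to validation; no
    patient appears in both cohorts.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[str]] = {0: [], 1: []}
    for pid in cohort.patient_ids:
        by_class[cohort.patient_label(pid)].append(pid)
    val_ids: set[str] = set()
    for c, pids in by_class.items():
        if n_val_per_class > 0 and len(pids) <= n_val_per_class:
            raise SplitError(
                f"class {c} has {len(pids)} patients; needs > {n_val_per_class}")
        chosen = rng.choice(len(pids), size=n_val_per_class, replace=False)
        val_ids.update(pids[i] for i in chosen)
    train = Cohort([s for s in cohort.samples if s.patient_id not in val_ids])
    val = Cohort([s for s in cohort.samples if s.patient_id in val_ids])
    return train, val


def crop_cohort(cohort: Cohort, window: int) -> Cohort:
    """Apply :func:`crop_to_tumor` to every slice; masks are cropped with the
    same geometry so downstream localisation checks stay aligned."""
    out = []
    for s in cohort.samples:
        image = crop_to_tumor(s.image, s.mask, window)
        mask = crop_to_tumor(s.mask.astype(np.float64), s.mask, window) > 0.5
        if not mask.any():
            mask = np.zeros_like(mask)
            mask[window // 2, window // 2] = True
        out.append(Sample(image=image, mask=mask, label=s.label,
                          patient_id=s.patient_id, slice_id=s.slice_id))
    return Cohort(out)


def config_to_dict(config: AugmentConfig) -> dict:
    return dataclasses.asdict(config)
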