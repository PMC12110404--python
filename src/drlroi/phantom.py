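"""Synthetic tumor-phantom cohorts for validating ROI-focused classifiers.

Each phantom slice emulates the statistical situation of a cropped
contrast-CT tumor slice: a single elliptical lesion ("ROI") whose interior
intensity statistics carry the entire class signal, surrounded by a
homogeneous parenchyma-like background cluttered with high-contrast
distractor structures that are independent of the class label.  Slices are
grouped into multi-slice "patients": lesion geometry is drawn once per
patient, while speckle and acquisition noise are redrawn per slice.

The two class-signal knobs are independent:

* ``roi_contrast`` — the positive class's lesion interior is brighter by
  this amount (difference of mean interior intensity between classes);
* ``roi_texture_freq`` — per-class spatial frequency of the zero-mean
  speckle field inside the lesion.

Setting the contrast to zero and equalising the texture frequencies makes
the label statistically independent of the pixels, which is the null
configuration used by the permutation-style checks in the tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter


class PhantomConfigError(ValueError):
    """Raised when a phantom configuration is geometrically impossible."""


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the phantom cohort generator.

    Defaults target the full-resolution regime (128 px slices); desk-scale
    studies shrink ``image_size`` and the radius range together.
    """

    n_patients_per_class: int = 20
    slices_per_patient: int | tuple[int, int] = 4
    image_size: int = 128
    roi_radius_range: tuple[float, float] = (12.0, 28.0)
    roi_contrast: float = 0.15
    roi_texture_freq: tuple[float, float] = (4.0, 10.0)
    texture_amplitude: float = 0.06
    background_distractor_count: int = 6
    distractor_contrast: float = 0.45
    background_level: float = 0.35
    center_jitter: float = 0.12
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise PhantomConfigError("image_size must be at least 32")
        if self.roi_contrast < 0:
            raise PhantomConfigError("roi_contrast must be non-negative")
        lo, hi = self.roi_radius_range
        if not (0 < lo <= hi):
            raise PhantomConfigError("roi_radius_range must be 0 < lo <= hi")
        # the ROI (plus jitter) must fit inside the frame
        max_center_offset = self.center_jitter * self.image_size
        if hi + max_center_offset > self.image_size / 2:
            raise PhantomConfigError(
                "ROI cannot fit: max radius + center jitter exceeds half the image"
            )
        if isinstance(self.slices_per_patient, tuple):
            a, b = self.slices_per_patient
            if not (1 <= a <= b):
                raise PhantomConfigError("slices_per_patient range must be 1 <= lo <= hi")
        elif self.slices_per_patient < 1:
            raise PhantomConfigError("slices_per_patient must be positive")


@dataclass(frozen=True)
class RoiGeometry:
    """Per-patient lesion geometry: ellipse center, semi-axes and tilt."""

    center: tuple[float, float]
    radii: tuple[float, float]
    angle: float

    def area(self) -> float:
        return np.pi * self.radii[0] * self.radii[1]


@dataclass
class Sample:
    image: np.ndarray          # float64 in [0, 1], shape (H, W)
    mask: np.ndarray           # bool, same shape
    label: int                 # 0 = negative, 1 = positive
    patient_id: str
    slice_id: str

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")
        if not self.mask.any():
            raise ValueError("mask has no foreground pixels")


@dataclass
class Cohort:
    samples: list[Sample]

    @property
    def class_counts(self) -> dict[int, int]:
        seen: dict[str, int] = {}
        for s in self.samples:
            seen[s.patient_id] = s.label
        counts: dict[int, int] = {0: 0, 1: 0}
        for label in seen.values():
            counts[label] += 1
        return counts

    @property
    def patient_ids(self) -> list[str]:
        out: list[str] = []
        for s in self.samples:
            if s.patient_id not in out:
                out.append(s.patient_id)
        return out

    def patient_label(self, patient_id: str) -> int:
        for s in self.samples:
            if s.patient_id == patient_id:
                return s.label
        raise KeyError(patient_id)

    def images(self) -> np.ndarray:
        return np.stack([s.image for s in self.samples])

    def masks(self) -> np.ndarray:
        return np.stack([s.mask for s in self.samples])

    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=int)

    def groups(self) -> np.ndarray:
        return np.array([s.patient_id for s in self.samples])

    def __len__(self) -> int:
        return len(self.samples)


def _ellipse_mask(shape: tuple[int, int], geometry: RoiGeometry) -> np.ndarray:
    H, W = shape
    cy, cx = geometry.center
    ry, rx = geometry.radii
    yy, xx = np.mgrid[0:H, 0:W]
    dy, dx = yy - cy, xx - cx
    ca, sa = np.cos(geometry.angle), np.sin(geometry.angle)
    u = ca * dy + sa * dx
    v = -sa * dy + ca * dx
    return (u / ry) ** 2 + (v / rx) ** 2 <= 1.0


def _speckle(shape: tuple[int, int], freq: float, amplitude: float,
             rng: np.random.Generator) -> np.ndarray:
    """Zero-mean band-limited speckle with RMS ``amplitude``.

    White noise is low-pass filtered with a Gaussian whose scale is set so
    that the dominant wavelength is roughly ``image_size / freq`` pixels.
    """
    noise = rng.standard_normal(shape)
    sigma = max(shape[0] / (4.0 * freq), 0.5)
    f = gaussian_filter(noise, sigma, mode="wrap")
    f -= f.mean()
    rms = np.sqrt(np.mean(f ** 2))
    if rms > 0:
        f *= amplitude / rms
    return f


def sample_geometry(config: PhantomConfig, rng: np.random.Generator) -> RoiGeometry:
    """Draw the per-patient lesion geometry."""
    half = config.image_size / 2.0
    jitter = config.center_jitter * config.image_size
    cy = half + rng.uniform(-jitter, jitter)
    cx = half + rng.uniform(-jitter, jitter)
    lo, hi = config.roi_radius_range
    ry = rng.uniform(lo, hi)
    rx = rng.uniform(lo, hi)
    angle = rng.uniform(0.0, np.pi)
    return RoiGeometry(center=(cy, cx), radii=(ry, rx), angle=angle)


def render_slice(label: int, geometry: RoiGeometry, config: PhantomConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Render one slice: lesion interior carries the class signal, the
    exterior carries label-independent distractors and acquisition noise."""
    H = W = config.image_size
    cy, cx = geometry.center
    ry, rx = geometry.radii
    if cy - max(ry, rx) < 0 or cy + max(ry, rx) > H or cx - max(ry, rx) < 0 or cx + max(ry, rx) > W:
        raise PhantomConfigError("ROI extends outside the image bounds")
    mask = _ellipse_mask((H, W), geometry)
    image = np.full((H, W), config.background_level)

    # class signal: mean shift (positive class only) + class-dependent speckle
    freq = config.roi_texture_freq[int(label)]
    texture = _speckle((H, W), freq, config.texture_amplitude, rng)
    texture -= texture[mask].mean()          # exact zero mean over the interior
    interior = config.background_level + config.roi_contrast * int(label) + texture
    image[mask] = interior[mask]

    # label-independent distractors strictly outside the ROI
    for _ in range(config.background_distractor_count):
        for _attempt in range(50):
            dy = rng.uniform(0, H)
            dx = rng.uniform(0, W)
            drad = rng.uniform(0.03, 0.08) * config.image_size
            dgeom = RoiGeometry(center=(dy, dx), radii=(drad, drad * rng.uniform(0.5, 1.0)),
                                angle=rng.uniform(0, np.pi))
            dmask = _ellipse_mask((H, W), dgeom)
            if not (dmask & mask).any():
                sign = 1.0 if rng.uniform() < 0.5 else -1.0
                image[dmask] += sign * config.distractor_contrast
                break

    if config.noise_sigma > 0:
        image += rng.normal(0.0, config.noise_sigma, size=(H, W))
    return np.clip(image, 0.0, 1.0), mask


def generate_cohort(config: PhantomConfig) -> Cohort:
    """Generate the full two-class, patient-grouped phantom cohort.

    Deterministic given ``config.seed``: all randomness flows through one
    :class:`numpy.random.Generator`.
    """
    rng = np.random.default_rng(config.seed)
    samples: list[Sample] = []
    patient_index = 0
    for label in (0, 1):
        for _ in range(config.n_patients_per_class):
            patient_id = f"P{patient_index:04d}"
            patient_index += 1
            if isinstance(config.slices_per_patient, tuple):
                lo, hi = config.slices_per_patient
                n_slices = int(rng.integers(lo, hi + 1))
            else:
                n_slices = int(config.slices_per_patient)
            geometry = sample_geometry(config, rng)
            for k in range(n_slices):
                image, mask = render_slice(label, geometry, config, rng)
                samples.append(Sample(image=image, mask=mask, label=label,
                                      patient_id=patient_id,
                                      slice_id=f"{patient_id}_S{k:03d}"))
    return Cohort(samples=samples)


# ---------------------------------------------------------------------------
# I/O: PNG slices + manifest CSV
# ---------------------------------------------------------------------------

def save_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write slices/masks as 8-bit grayscale PNGs and a manifest CSV.

    Returns the manifest path.  Columns: patient_id, slice_id, image_path,
    mask_path, label (paths relative to the manifest's directory).
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.samples:
        img_rel = f"images/{s.slice_id}.png"
        mask_rel = f"masks/{s.slice_id}.png"
        Image.fromarray(np.round(s.image * 255).astype(np.uint8)).save(out / img_rel)
        Image.fromarray((s.mask.astype(np.uint8) * 255)).save(out / mask_rel)
        rows.append({"patient_id": s.patient_id, "slice_id": s.slice_id,
                     "image_path": img_rel, "mask_path": mask_rel, "label": s.label})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(manifest_path: str | Path) -> Cohort:
    """Read a cohort back from a manifest CSV produced by :func:`save_cohort`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    required = {"patient_id", "slice_id", "image_path", "mask_path", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    samples = []
    for row in df.itertuples(index=False):
        image = np.asarray(Image.open(base / row.image_path), dtype=np.float64) / 255.0
        mask = np.asarray(Image.open(base / row.mask_path)) > 127
        samples.append(Sample(image=image, mask=mask, label=int(row.label),
                              patient_id=str(row.patient_id), slice_id=str(row.slice_id)))
    return Cohort(samples=samples)


def config_to_dict(config: PhantomConfig) -> dict:
    return dataclasses.asdict(config)
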