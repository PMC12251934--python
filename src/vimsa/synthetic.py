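"""Synthetic near-infrared-style eye images with pupil-center ground truth.

Real pupil datasets share a simple photometric structure: a dark elliptical
pupil inside a brighter iris disc, surrounded by an even brighter
sclera/skin field, contaminated by specular glints from active
illumination, occlusions (eyelids, mascara, glasses frames) and uneven
lighting.  The generator renders exactly that structure so the detector's
assumptions can be exercised end-to-end with exact labels:

* pupil: filled rotated ellipse at ``pupil_intensity``; a pixel belongs to
  the pupil iff its center satisfies the rotated-ellipse inequality ≤ 1
  (no anti-aliasing, so noise-free centroids are exact);
* iris: concentric disc at ``iris_intensity``; background at
  ``sclera_intensity``;
* nuisances, each optional: an additive linear illumination gradient, one
  bright glint disc overlapping the pupil, a dark occluder band across the
  top, i.i.d. Gaussian pixel noise; the result is clipped to [0, 255].

Coordinates are 0-based, origin top-left, x = column, y = row, pixel
centers at integer coordinates; labels are floats.

Label files are CSV with header ``filename,center_x,center_y``; images are
written as 8-bit single-channel PNG (PGM is accepted on read).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

GLINT_INTENSITY = 250.0


@dataclass
class SyntheticEyeConfig:
    image_width: int = 320
    image_height: int = 240
    pupil_radius_range: tuple[float, float] = (15.0, 40.0)
    pupil_eccentricity_range: tuple[float, float] = (0.6, 1.0)
    pupil_intensity: float = 30.0
    iris_intensity: float = 100.0
    sclera_intensity: float = 200.0
    glint_probability: float = 0.3
    glint_radius: float = 4.0
    occluder_probability: float = 0.2
    illumination_gradient_amplitude: float = 30.0
    noise_std: float = 5.0
    margin: float = 45.0
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.pupil_intensity <= 255):
            raise ValueError("pupil_intensity must be in [0, 255]")
        if not (0 <= self.iris_intensity <= 255):
            raise ValueError("iris_intensity must be in [0, 255]")
        if not (0 <= self.sclera_intensity <= 255):
            raise ValueError("sclera_intensity must be in [0, 255]")
        if not self.pupil_intensity < self.iris_intensity < self.sclera_intensity:
            raise ValueError(
                "intensity ordering violated: require "
                "pupil_intensity < iris_intensity < sclera_intensity")
        rmin, rmax = self.pupil_radius_range
        if not (0 < rmin <= rmax):
            raise ValueError("pupil_radius_range must satisfy 0 < min <= max")
        emin, emax = self.pupil_eccentricity_range
        if not (0 < emin <= emax <= 1):
            raise ValueError("pupil_eccentricity_range must lie in (0, 1]")
        if self.margin < rmax:
            raise ValueError("margin must be >= max pupil radius")
        for name in ("glint_probability", "occluder_probability"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        if self.image_width <= 2 * self.margin or self.image_height <= 2 * self.margin:
            raise ValueError("margin leaves no room for the pupil center")


@dataclass
class EyeImageSample:
    """One grayscale image grid plus its pupil-center label.

    ``pixels`` is h×w float64 in [0, 255]; ``center_x``/``center_y`` are
    the pupil-center column/row in pixels (0-based, origin top-left).
    """

    pixels: np.ndarray
    center_x: float
    center_y: float
    metadata: dict = field(default_factory=dict)
    filename: str | None = None
    discarded: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _ellipse_mask(h: int, w: int, cx: float, cy: float,
                  a: float, b: float, theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - cx
    dy = yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_eye_image(config: SyntheticEyeConfig,
                       rng: np.random.Generator,
                       center: tuple[float, float] | None = None) -> EyeImageSample:
    """Render one labeled synthetic eye image; deterministic given ``rng``."""
    config.validate()
    h, w = config.image_height, config.image_width
    m = config.margin
    if center is None:
        cx = rng.uniform(m, w - 1 - m)
        cy = rng.uniform(m, h - 1 - m)
    else:
        cx, cy = center
    a = rng.uniform(*config.pupil_radius_range)
    ratio = rng.uniform(*config.pupil_eccentricity_range)
    b = a * ratio
    theta = rng.uniform(0.0, np.pi)

    img = np.full((h, w), config.sclera_intensity, dtype=np.float64)
    iris_r = 2.2 * a
    img[_ellipse_mask(h, w, cx, cy, iris_r, iris_r, 0.0)] = config.iris_intensity
    img[_ellipse_mask(h, w, cx, cy, a, b, theta)] = config.pupil_intensity

    grad_phi = rng.uniform(0.0, 2 * np.pi)
    if config.illumination_gradient_amplitude > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        ramp = (np.cos(grad_phi) * (xx - (w - 1) / 2) + np.sin(grad_phi) * (yy - (h - 1) / 2))
        ramp /= max(h, w)
        img += config.illumination_gradient_amplitude * ramp

    has_glint = bool(rng.uniform() < config.glint_probability)
    glint_center = None
    glint_offset = rng.uniform(-0.5, 0.5, size=2) * a
    if has_glint:
        gx, gy = cx + glint_offset[0], cy + glint_offset[1]
        img[_ellipse_mask(h, w, gx, gy, config.glint_radius, config.glint_radius, 0.0)] = \
            GLINT_INTENSITY
        glint_center = (float(gx), float(gy))

    has_occluder = bool(rng.uniform() < config.occluder_probability)
    occ_rows = int(rng.uniform(0.10, 0.25) * h)
    occ_level = rng.uniform(10.0, 60.0)
    if has_occluder:
        img[:occ_rows] = np.minimum(img[:occ_rows], occ_level)

    if config.noise_std > 0:
        img += rng.normal(0.0, config.noise_std, size=img.shape)

    np.clip(img, 0.0, 255.0, out=img)
    meta = {
        "pupil_a": float(a), "pupil_b": float(b), "pupil_theta": float(theta),
        "has_glint": has_glint, "glint_center": glint_center,
        "has_occluder": has_occluder,
        "occluder_rows": occ_rows if has_occluder else 0,
        "gradient_phi": float(grad_phi),
    }
    return EyeImageSample(img, float(cx), float(cy), metadata=meta)


def generate_dataset(config: SyntheticEyeConfig, n: int,
                     rng: np.random.Generator | None = None
                     ) -> tuple[list[EyeImageSample], pd.DataFrame]:
    """Generate ``n`` samples plus their label table (filename, center_x, center_y)."""
    if n < 1:
        raise ValueError(f"dataset size must be >= 1, got {n}")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    samples = []
    rows = []
    for i in range(n):
        s = generate_eye_image(config, rng)
        s.filename = f"eye_{i:05d}.png"
        samples.append(s)
        rows.append((s.filename, s.center_x, s.center_y))
    labels = pd.DataFrame(rows, columns=["filename", "center_x", "center_y"])
    return samples, labels


def easy_config(width: int = 64, height: int = 48, seed: int = 0) -> SyntheticEyeConfig:
    """Nuisance-free configuration at a reduced frame size.

    No glints, occluders, illumination gradient or pixel noise; pupil
    geometry scaled to the frame.  This is the clean regime used by the
    scaled-down end-to-end learnability experiments.
    """
    scale = min(width, height) / 240.0
    rmax = max(3.0, 40.0 * scale)
    return SyntheticEyeConfig(
        image_width=width, image_height=height,
        pupil_radius_range=(max(2.0, 15.0 * scale), rmax),
        pupil_eccentricity_range=(0.7, 1.0),
        glint_probability=0.0, occluder_probability=0.0,
        illumination_gradient_amplitude=0.0, noise_std=0.0,
        glint_radius=max(1.0, 4.0 * scale), margin=rmax, seed=seed)


def save_dataset(samples: list[EyeImageSample], labels: pd.DataFrame, out_dir) -> Path:
    """Write PNG images and the label CSV to a dataset directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in samples:
        arr = np.clip(np.rint(s.pixels), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(out / s.filename)
    labels.to_csv(out / "labels.csv", index=False)
    return out


def load_dataset(data_dir) -> tuple[list[EyeImageSample], pd.DataFrame]:
    """Read a dataset directory (PNG/PGM images + labels.csv)."""
    data_dir = Path(data_dir)
    labels = pd.read_csv(data_dir / "labels.csv")
    samples = []
    for row in labels.itertuples(index=False):
        img = Image.open(data_dir / row.filename).convert("L")
        samples.append(EyeImageSample(
            np.asarray(img, dtype=np.float64),
            float(row.center_x), float(row.center_y), filename=row.filename))
    return samples, labels


def preprocess_image(sample: EyeImageSample, target_w: int = 320,
                     target_h: int = 240) -> EyeImageSample:
    """Standardize to the working frame, transforming the label with it.

    If the input is an exact integer multiple of the target in both
    dimensions (by the same factor), downscale by area averaging and scale
    the label by the same factor; otherwise center-crop to the target and
    translate the label by the crop offset.  Samples whose label leaves
    the crop are flagged ``discarded`` rather than clamped.
    """
    h, w = sample.pixels.shape
    if h < target_h or w < target_w:
        raise ValueError(
            f"input {w}x{h} smaller than target {target_w}x{target_h}")
    meta = dict(sample.metadata)
    if (h, w) == (target_h, target_w):
        return EyeImageSample(sample.pixels.copy(), sample.center_x, sample.center_y,
                              metadata=meta, filename=sample.filename)
    if w % target_w == 0 and h % target_h == 0 and w // target_w == h // target_h:
        k = w // target_w
        img = sample.pixels.reshape(target_h, k, target_w, k).mean(axis=(1, 3))
        meta["preprocess"] = {"mode": "scale", "factor": k}
        return EyeImageSample(img, sample.center_x / k, sample.center_y / k,
                              metadata=meta, filename=sample.filename)
    ox = (w - target_w) // 2
    oy = (h - target_h) // 2
    img = sample.pixels[oy:oy + target_h, ox:ox + target_w].copy()
    nx, ny = sample.center_x - ox, sample.center_y - oy
    out = EyeImageSample(img, nx, ny, metadata=meta, filename=sample.filename)
    out.metadata["preprocess"] = {"mode": "crop", "offset": (ox, oy)}
    if not (0 <= nx < target_w and 0 <= ny < target_h):
        out.discarded = True
        logger.warning("label left the crop window for %s; sample discarded",
                       sample.filename or "<in-memory sample>")
    return out


def original_frame_coords(x: float, y: float, preprocess: dict | None) -> tuple[float, float]:
    """Map working-frame coordinates back to the original image frame."""
    if not preprocess:
        return x, y
    if preprocess["mode"] == "scale":
        k = preprocess["factor"]
        return x * k, y * k
    ox, oy = preprocess["offset"]
    return x + ox, y + oy


def split_dataset(samples: list, train_fraction: float = 0.85,
                  rng: np.random.Generator | None = None) -> tuple[list, list]:
    """Random disjoint, exhaustive train/test partition with ⌊n·f⌉ training items."""
    if not samples:
        raise ValueError("cannot split an empty dataset")
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must be in (0, 1)")
    rng = rng if rng is not None else np.random.default_rng(0)
    n = len(samples)
    n_train = int(round(n * train_fraction))
    if n_train == 0 or n_train == n:
        logger.warning("degenerate split: %d train / %d test", n_train, n - n_train)
    order = rng.permutation(n)
    train = [samples[i] for i in order[:n_train]]
    test = [samples[i] for i in order[n_train:]]
    return train, test
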