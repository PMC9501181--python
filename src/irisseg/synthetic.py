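"""Deterministic synthetic eye images with ground-truth iris masks.

The generator emulates the two flavours of heterogeneity the segmentation
task faces: near-infrared-style grayscale captures (320 x 240, like close-up
NIR iris cameras) and visible-light RGB captures (400 x 300, like
unconstrained visible-spectrum acquisition).  Each sample contains a sclera
background, a textured iris annulus (band-limited radial sinusoid plus a
seeded smooth random field), a dark pupil disc, parabolic eyelid occluders,
eyelash strokes and specular highlights, plus additive Gaussian noise.

The ground-truth mask is the *visible iris annulus only*: pixels strictly
farther than the pupil radius and at most the iris radius from the centre,
minus the eyelid-occluded region.  The pupil, eyelids, lashes and
highlights are background.  Everything is a pure function of the spec and
its seed, so a (spec, seed) pair reproduces the image and mask
bit-for-bit.

With the default sampling ranges of :func:`generate_dataset`, mask
foreground fractions fall in roughly 2-20% of the image.
"""

from __future__ import annotations

import csv
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.draw import line as draw_line

__all__ = ["SyntheticEyeSpec", "generate_eye_sample", "annulus_mask",
           "generate_dataset", "load_manifest"]

MODALITY_SIZES = {"nir": (320, 240), "visible": (400, 300)}
EYELID_CURVATURE = 0.35  # parabola curvature in units of iris radius


@dataclass
class SyntheticEyeSpec:
    """Parametric description of one synthetic eye image."""

    modality: str = "nir"
    image_size: tuple | None = None      # (width, height); default by modality
    iris_center: tuple | None = None     # (x, y); default image centre
    iris_radius: float = 60.0
    pupil_radius: float = 22.0
    eyelid_coverage: float = 0.2
    n_eyelashes: int = 12
    n_specular_spots: int = 2
    texture_scale: float = 9.0
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.modality not in MODALITY_SIZES:
            raise ValueError(f"modality must be one of {set(MODALITY_SIZES)}")
        if self.image_size is None:
            self.image_size = MODALITY_SIZES[self.modality]
        self.image_size = tuple(int(v) for v in self.image_size)
        if self.iris_center is None:
            self.iris_center = (self.image_size[0] / 2, self.image_size[1] / 2)
        self.iris_center = tuple(float(v) for v in self.iris_center)
        if not 0 < self.pupil_radius < self.iris_radius:
            raise ValueError("need 0 < pupil_radius < iris_radius")
        if self.iris_radius >= min(self.image_size) / 2:
            raise ValueError("iris_radius must fit inside the image")
        if not 0 <= self.eyelid_coverage < 1:
            raise ValueError("eyelid_coverage must lie in [0, 1)")
        if self.n_eyelashes < 0 or self.n_specular_spots < 0:
            raise ValueError("occluder counts must be non-negative")


def _grids(spec: SyntheticEyeSpec):
    w, h = spec.image_size
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cx, cy = spec.iris_center
    r = np.hypot(xx - cx, yy - cy)
    return xx, yy, r


def _eyelid_occlusion(spec: SyntheticEyeSpec, xx, yy) -> np.ndarray:
    """Boolean map of pixels hidden by the upper/lower parabolic eyelids."""
    cx, cy = spec.iris_center
    ir, c = spec.iris_radius, spec.eyelid_coverage
    if c == 0:
        return np.zeros(xx.shape, dtype=bool)
    bend = EYELID_CURVATURE * (xx - cx) ** 2 / ir
    top = yy < cy - ir * (1 - c) + bend
    bottom = yy > cy + ir * (1 - c) - bend
    return top | bottom


def annulus_mask(spec: SyntheticEyeSpec) -> np.ndarray:
    """Ground-truth mask: visible iris annulus (uint8 {0, 1}, H x W)."""
    xx, yy, r = _grids(spec)
    annulus = (r > spec.pupil_radius) & (r <= spec.iris_radius)
    return (annulus & ~_eyelid_occlusion(spec, xx, yy)).astype(np.uint8)


def generate_eye_sample(spec: SyntheticEyeSpec):
    """Render one synthetic eye.

    Returns ``(image, mask)``: image is float32 in [0, 1], shaped (H, W)
    for NIR and (H, W, 3) for visible light; mask is uint8 {0, 1} (H, W).
    """
    rng = np.random.default_rng(spec.seed)
    xx, yy, r = _grids(spec)
    w, h = spec.image_size
    cx, cy = spec.iris_center
    ir, pr = spec.iris_radius, spec.pupil_radius

    annulus = (r > pr) & (r <= ir)
    pupil = r <= pr
    eyelid = _eyelid_occlusion(spec, xx, yy)

    # iris texture: radial sinusoid + seeded smooth random field
    radial = np.sin(2 * np.pi * (r - pr) / spec.texture_scale)
    theta = np.arctan2(yy - cy, xx - cx)
    spokes = np.sin(theta * rng.integers(8, 16) + rng.uniform(0, 2 * np.pi))
    rough = gaussian_filter(rng.standard_normal((h, w)), sigma=2.5)
    texture = 0.10 * radial + 0.05 * spokes + 0.08 * rough

    if spec.modality == "nir":
        img = np.full((h, w), 0.72)
        img += 0.05 * ((yy / h) - 0.5)          # mild illumination gradient
        img[annulus] = 0.38 + texture[annulus]
        img[pupil] = 0.06
        img[eyelid] = 0.58 + 0.04 * rough[eyelid]
        img = img[..., None]                    # render channels uniformly
        lash_color = np.array([0.10])
        spot_color = np.array([0.97])
    else:
        img = np.empty((h, w, 3))
        img[:] = (0.82, 0.70, 0.62)             # skin/sclera surround
        sclera = ~annulus & ~pupil & (r <= 1.6 * ir)
        img[sclera] = (0.93, 0.90, 0.88)
        iris_rgb = np.array([
            (0.36, 0.28, 0.18), (0.25, 0.38, 0.45), (0.30, 0.42, 0.28),
        ])[rng.integers(0, 3)]
        img[annulus] = iris_rgb + texture[annulus, None] * (1.0, 0.9, 0.8)
        img[pupil] = (0.05, 0.05, 0.05)
        img[eyelid] = (0.80, 0.64, 0.55)
        img[eyelid] += 0.04 * rough[eyelid, None]
        lash_color = np.array([0.10, 0.08, 0.06])
        spot_color = np.array([0.98, 0.98, 0.96])

    # eyelash strokes: short dark lines hanging from the lid boundaries
    for _ in range(spec.n_eyelashes):
        x0 = int(rng.uniform(cx - ir, cx + ir))
        top_side = rng.random() < 0.5
        depth = ir * (1 - spec.eyelid_coverage)
        y0 = cy - depth if top_side else cy + depth
        y0 = int(np.clip(y0 + EYELID_CURVATURE * (x0 - cx) ** 2 / ir
                         * (1 if top_side else -1), 1, h - 2))
        length = rng.uniform(0.15, 0.35) * ir
        angle = rng.uniform(-0.5, 0.5) + (math.pi / 2 if top_side else -math.pi / 2)
        x1 = int(np.clip(x0 + length * math.cos(angle), 0, w - 1))
        y1 = int(np.clip(y0 + length * math.sin(angle), 0, h - 1))
        rr, cc = draw_line(y0, int(np.clip(x0, 0, w - 1)), y1, x1)
        img[rr, cc] = lash_color

    # specular highlights: small bright Gaussian blobs near the pupil
    for _ in range(spec.n_specular_spots):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, 0.9 * pr)
        sx, sy = cx + rad * math.cos(ang), cy + rad * math.sin(ang)
        sigma = rng.uniform(1.5, 3.0)
        blob = np.exp(-((xx - sx) ** 2 + (yy - sy) ** 2) / (2 * sigma ** 2))
        img += blob[..., None] * (spot_color - img) * 0.95

    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    if spec.modality == "nir":
        img = img[..., 0]
    return img.astype(np.float32), annulus_mask(spec)


def _sample_spec(rng: np.random.Generator, modality: str) -> SyntheticEyeSpec:
    """Draw one spec from the documented parameter ranges."""
    w, h = MODALITY_SIZES[modality]
    short = min(w, h)
    ir = rng.uniform(0.18, 0.28) * short
    return SyntheticEyeSpec(
        modality=modality,
        iris_center=(w / 2 + rng.uniform(-0.05, 0.05) * w,
                     h / 2 + rng.uniform(-0.05, 0.05) * h),
        iris_radius=ir,
        pupil_radius=rng.uniform(0.25, 0.45) * ir,
        eyelid_coverage=rng.uniform(0.0, 0.35),
        n_eyelashes=int(rng.integers(0, 25)),
        n_specular_spots=int(rng.integers(0, 5)),
        texture_scale=rng.uniform(6.0, 14.0),
        noise_sd=rng.uniform(0.02, 0.05),
        seed=int(rng.integers(0, 2 ** 31 - 1)),
    )


def generate_dataset(n: int, modality_mix: float, out_dir, seed: int = 0):
    """Write ``n`` image/mask PNG pairs plus a CSV manifest.

    ``ceil(modality_mix * n)`` samples are NIR-style grayscale, the rest
    visible-light RGB.  Masks are stored with values {0, 255}.  Returns the
    manifest as a list of dicts (one per sample).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= modality_mix <= 1:
        raise ValueError("modality_mix must lie in [0, 1]")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_nir = math.ceil(modality_mix * n)
    manifest = []
    for i in range(n):
        modality = "nir" if i < n_nir else "visible"
        spec = _sample_spec(rng, modality)
        img, mask = generate_eye_sample(spec)
        stem = f"sample_{i:04d}"
        img_path = out / "images" / f"{stem}.png"
        mask_path = out / "masks" / f"{stem}.png"
        arr = (img * 255).round().astype(np.uint8)
        Image.fromarray(arr, mode="L" if arr.ndim == 2 else "RGB").save(img_path)
        Image.fromarray(mask * np.uint8(255), mode="L").save(mask_path)
        row = {"image_path": str(img_path), "mask_path": str(mask_path),
               **asdict(spec)}
        row["image_size"] = f"{spec.image_size[0]}x{spec.image_size[1]}"
        row["iris_center"] = f"{spec.iris_center[0]:.2f};{spec.iris_center[1]:.2f}"
        manifest.append(row)
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(manifest[0]))
        writer.writeheader()
        writer.writerows(manifest)
    return manifest


def load_manifest(path):
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))
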