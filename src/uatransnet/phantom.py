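"""Synthetic MRI-like tumor phantoms with known ground-truth masks.

Real tumor MRI slices show a bright, roughly elliptical lesion on darker
surrounding tissue, with blurred edges and acquisition noise.  The phantoms
here emulate exactly that prior — rotated ellipses of elevated intensity on
a uniform background, Gaussian edge blur, additive Gaussian noise — so the
whole pipeline (preprocessing, network, mean-teacher stage) is exercisable
without any clinical data.

Conventions: intensities live in [0, 1] internally; 8-bit grayscale PNG on
disk, rescaled on read/write.  ``rot90`` is counter-clockwise.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter, zoom

__all__ = ["PhantomSpec", "LabeledImage", "generate_phantom", "generate_dataset",
           "augment", "AUGMENT_OPS", "write_dataset", "read_dataset",
           "save_image", "load_image"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic tumor-image generator.

    Defaults give a 64x64 image with one tumor of 6-14 px semi-axes,
    foreground/background means 0.75/0.25, noise sd 0.05 and 1 px edge blur
    — a clearly brighter lesion, consistent with the prior that tumor tissue
    outshines surrounding healthy tissue.
    """

    image_size: tuple[int, int] = (64, 64)
    n_tumors: int = 1
    semi_axis_range: tuple[float, float] = (6.0, 14.0)
    fg_intensity: float = 0.75
    bg_intensity: float = 0.25
    noise_sd: float = 0.05
    edge_blur_sigma: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size
        if h < 1 or w < 1:
            raise ValueError("image_size must be positive")
        if self.n_tumors < 0:
            raise ValueError("n_tumors must be >= 0")
        lo, hi = self.semi_axis_range
        if not (0 < lo <= hi):
            raise ValueError("semi_axis_range must satisfy 0 < min <= max")
        if hi * 2 >= min(h, w):
            raise ValueError(
                f"tumor does not fit: max semi-axis {hi} too large for {h}x{w} image")
        if not self.fg_intensity > self.bg_intensity:
            raise ValueError("fg_intensity must exceed bg_intensity "
                             "(tumor is brighter than background)")
        if self.noise_sd < 0 or self.edge_blur_sigma < 0:
            raise ValueError("noise_sd and edge_blur_sigma must be nonnegative")


@dataclass
class LabeledImage:
    """An image/mask pair plus the provenance needed to regenerate it."""

    image: np.ndarray
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")


def _rasterize_ellipse(shape, center, axes, angle) -> np.ndarray:
    """Boolean mask of a rotated ellipse: pixel centers inside the inequality."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    dr, dc = rr - center[0], cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    a, b = axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> LabeledImage:
    """Draw one phantom: union of ellipse masks, two-level field, blur, noise."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    mask = np.zeros((h, w), dtype=np.uint8)
    tumors = []
    lo, hi = spec.semi_axis_range
    for _ in range(spec.n_tumors):
        a = rng.uniform(lo, hi)
        b = rng.uniform(lo, hi)
        m = max(a, b)
        # centers kept so the whole ellipse stays inside the frame
        cr = rng.uniform(m, h - 1 - m)
        cc = rng.uniform(m, w - 1 - m)
        angle = rng.uniform(0.0, np.pi)
        mask |= _rasterize_ellipse((h, w), (cr, cc), (a, b), angle).astype(np.uint8)
        tumors.append({"center": (round(cr, 3), round(cc, 3)),
                       "axes": (round(a, 3), round(b, 3)),
                       "angle": round(float(angle), 4)})
    field_ = np.where(mask, spec.fg_intensity, spec.bg_intensity).astype(np.float64)
    if spec.edge_blur_sigma > 0:
        field_ = gaussian_filter(field_, spec.edge_blur_sigma)
    if spec.noise_sd > 0:
        field_ = field_ + rng.normal(0.0, spec.noise_sd, size=(h, w))
    image = np.clip(field_, 0.0, 1.0)
    meta = {"spec": asdict(spec), "seed": spec.seed, "tumors": tumors}
    return LabeledImage(image=image, mask=mask, meta=meta)


def generate_dataset(spec: PhantomSpec, n: int, seed: int) -> list[LabeledImage]:
    """n independent phantoms with per-item seeds derived from `seed`."""
    if n < 1:
        raise ValueError("n must be >= 1")
    seeds = np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)
    items = []
    for i in range(n):
        item_spec = PhantomSpec(**{**asdict(spec), "seed": int(seeds[i])})
        items.append(generate_phantom(item_spec))
    return items


def _scale(item: LabeledImage, factor: float) -> LabeledImage:
    """Zoom about the image center, crop/pad back to the original frame."""
    img = zoom(item.image, factor, order=1)
    msk = zoom(item.mask.astype(np.float64), factor, order=0)
    out_i = np.full(item.image.shape, float(np.median(item.image)))
    out_m = np.zeros(item.mask.shape)
    h, w = item.image.shape
    zh, zw = img.shape
    if factor >= 1:
        r0, c0 = (zh - h) // 2, (zw - w) // 2
        out_i = img[r0:r0 + h, c0:c0 + w]
        out_m = msk[r0:r0 + h, c0:c0 + w]
    else:
        r0, c0 = (h - zh) // 2, (w - zw) // 2
        out_i[r0:r0 + zh, c0:c0 + zw] = img
        out_m[r0:r0 + zh, c0:c0 + zw] = msk
    return LabeledImage(np.clip(out_i, 0, 1), (out_m > 0.5).astype(np.uint8),
                        {**item.meta, "augment": f"scale{factor}"})


AUGMENT_OPS = ("rot90", "rot180", "rot270", "flip_h", "flip_v", "scale")


def augment(item: LabeledImage, op: str, scale_factor: float = 1.25) -> LabeledImage:
    """Apply one geometric op jointly to image and mask.

    Rotations are counter-clockwise; ``flip_h`` mirrors left-right,
    ``flip_v`` top-bottom; ``scale`` zooms by `scale_factor` about the center.
    """
    if op == "scale":
        return _scale(item, scale_factor)
    fns = {"rot90": lambda a: np.rot90(a, 1),
           "rot180": lambda a: np.rot90(a, 2),
           "rot270": lambda a: np.rot90(a, 3),
           "flip_h": np.fliplr,
           "flip_v": np.flipud}
    if op not in fns:
        raise ValueError(f"unknown augmentation {op!r}; choose from {AUGMENT_OPS}")
    f = fns[op]
    return LabeledImage(f(item.image).copy(), f(item.mask).copy(),
                        {**item.meta, "augment": op})


# ---------------------------------------------------------------------------
# disk I/O: 8-bit grayscale PNG + CSV manifest
# ---------------------------------------------------------------------------

def save_image(path, image: np.ndarray) -> None:
    Image.fromarray(np.round(np.clip(image, 0, 1) * 255).astype(np.uint8)).save(path)


def load_image(path) -> np.ndarray:
    """Read a grayscale image (PNG/TIFF or single-slice NIfTI) scaled to [0,1]."""
    path = Path(path)
    if path.suffix in (".nii", ".gz") or str(path).endswith(".nii.gz"):
        import nibabel as nib
        data = np.asanyarray(nib.load(str(path)).dataobj).squeeze()
        if data.ndim != 2:
            raise ValueError(f"expected a single-slice volume, got shape {data.shape}")
        lo, hi = float(data.min()), float(data.max())
        return (data - lo) / (hi - lo) if hi > lo else np.zeros_like(data, dtype=float)
    arr = np.asarray(Image.open(path).convert("L"), dtype=np.float64)
    return arr / 255.0


def write_dataset(items: list[LabeledImage], outdir) -> Path:
    """Write image/mask PNG pairs plus a CSV manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "image", "mask", "seed", "tumors"])
        for i, item in enumerate(items):
            img_name, mask_name = f"img_{i:05d}.png", f"mask_{i:05d}.png"
            save_image(outdir / img_name, item.image)
            save_image(outdir / mask_name, item.mask.astype(float))
            writer.writerow([i, img_name, mask_name,
                             item.meta.get("seed", ""),
                             json.dumps(item.meta.get("tumors", []))])
    return manifest


def read_dataset(manifest) -> list[LabeledImage]:
    manifest = Path(manifest)
    items = []
    with open(manifest) as fh:
        for row in csv.DictReader(fh):
            image = load_image(manifest.parent / row["image"])
            mask = (load_image(manifest.parent / row["mask"]) > 0.5).astype(np.uint8)
            items.append(LabeledImage(image, mask, {"id": row["id"], "seed": row["seed"]}))
    return items
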