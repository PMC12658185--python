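"""Seeded synthetic fundus phantoms for the four retinal-detachment classes.

Real multiclass RD fundus collections are not redistributable, so the test
bed is a generator of cartoonish but structurally meaningful phantoms: an
orange circular fundus disc on black background, dark curvilinear vessels
radiating from the disc centre, plus a class-specific cue —

* ``Healthy``  — no lesion;
* ``RRD``      — a bright, sharply edged wedge-shaped fold (rhegmatogenous
                 detachment flap) placed in the upper-left quadrant;
* ``ERD``      — a smooth bright dome (subretinal fluid) with no hard edge;
* ``TRD``      — a dark fibrous traction band crossing the disc.

Phantoms are deliberately not photorealistic: they exist to exercise every
pipeline stage and to be learnable, not to emulate camera optics.  All
randomness flows from the PhantomSpec seed, so images are bit-identical across
runs and platforms.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

CLASSES = ("ERD", "Healthy", "RRD", "TRD")


@dataclass(frozen=True)
class PhantomSpec:
    label: str
    size: int = 224
    disc_radius_frac: float = 0.46
    n_vessels: int = 6
    tortuosity: float = 0.12
    lesion_strength: float = 1.0
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.label not in CLASSES:
            raise ValueError(f"unknown class {self.label!r}; expected one of {CLASSES}")
        if self.size < 64:
            raise ValueError("size must be >= 64")
        if not 0 < self.disc_radius_frac <= 1:
            raise ValueError("disc_radius_frac must lie in (0, 1]")


def _disc_geometry(size: int):
    c = (size - 1) / 2.0
    rows = np.arange(size)[:, None] - c
    cols = np.arange(size)[None, :] - c
    rad = np.hypot(rows, cols)
    ang = np.arctan2(-rows, cols)  # standard orientation: up is +angle
    return c, rows, cols, rad, ang


def _draw_vessels(img: np.ndarray, radius: float, n: int, tortuosity: float,
                  rng: np.random.Generator) -> None:
    # roughly radial arcades: evenly spaced base angles with jitter, gentle
    # meander — keeps per-image vessel load stable across draws
    size = img.shape[0]
    c = (size - 1) / 2.0
    width = max(1, size // 80)
    for k in range(n):
        theta = 2 * np.pi * k / n + rng.uniform(-0.3, 0.3)
        r, col = c, c
        step = size / 150.0
        for _ in range(300):
            theta += rng.normal(0, tortuosity)
            r -= step * np.sin(theta)
            col += step * np.cos(theta)
            if not (0 <= r < size and 0 <= col < size):
                break
            if np.hypot(r - c, col - c) > 0.95 * radius:
                break
            ri, ci = int(r), int(col)
            sl = np.s_[max(ri - width, 0): ri + width + 1, max(ci - width, 0): ci + width + 1]
            img[sl] *= 0.45


def generate_fundus(spec: PhantomSpec) -> tuple[np.ndarray, str]:
    """Render one labelled phantom; returns (H x W x 3 uint8 image, label)."""
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    c, rows, cols, rad, ang = _disc_geometry(size)
    radius = spec.disc_radius_frac * size
    disc = rad <= radius
    shading = 1.0 - 0.35 * (rad / radius) ** 2

    img = np.zeros((size, size, 3))
    base = np.array([215.0, 130.0, 55.0])
    for ch in range(3):
        img[..., ch] = base[ch] * shading

    _draw_vessels(img[..., 0], radius, spec.n_vessels, spec.tortuosity, rng)
    img[..., 1] *= img[..., 0] / np.maximum(base[0] * shading, 1e-9)
    img[..., 2] *= img[..., 0] / np.maximum(base[0] * shading, 1e-9)

    s = spec.lesion_strength
    if spec.label == "RRD":
        # sharp-edged bright wedge in the upper-left quadrant
        a0 = np.deg2rad(115 + rng.uniform(-8, 8))
        span = np.deg2rad(38 + rng.uniform(-5, 5))
        in_wedge = (
            (np.abs(((ang - a0 + np.pi) % (2 * np.pi)) - np.pi) < span / 2)
            & (rad > 0.12 * radius) & (rad < 0.88 * radius)
        )
        img[in_wedge] += s * np.array([80.0, 125.0, 110.0])
    elif spec.label == "ERD":
        # broad smooth dome of subretinal fluid near the disc centre: no hard
        # edge, brightens the field and veils the vessels beneath it
        blob_r = rng.uniform(0.0, 0.15) * radius
        blob_a = rng.uniform(0, 2 * np.pi)
        br, bc = c - blob_r * np.sin(blob_a), c + blob_r * np.cos(blob_a)
        sig = rng.uniform(0.38, 0.44) * radius
        dome = np.exp(-((rows + c - br) ** 2 + (cols + c - bc) ** 2) / (2 * sig**2))
        alpha = np.clip(0.92 * s, 0.0, 1.0) * dome[..., None]
        fluid = np.array([235.0, 205.0, 120.0]) * shading[..., None]
        img = (1.0 - alpha) * img + alpha * fluid
    elif spec.label == "TRD":
        # dark fibrous band pulling across the disc, roughly along the
        # temporal arcade axis (narrow orientation range keeps the class
        # phenotype coherent)
        band_a = np.deg2rad(rng.uniform(25, 65))
        offset = rng.uniform(-0.12, 0.12) * radius
        d = rows * np.cos(band_a) + cols * np.sin(band_a) - offset
        wiggle = 0.06 * radius * np.sin(6 * (rows * np.sin(band_a) - cols * np.cos(band_a)) / radius)
        band = np.abs(d + wiggle) < 0.18 * radius
        img[band] *= max(1.0 - 0.85 * s, 0.0)
        img[band & (rng.random((size, size)) < 0.4)] *= 0.7

    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0, 255)
    img[~disc] = 0
    return img.astype(np.uint8), spec.label


def phantom_seed(master_seed: int, class_index: int, image_index: int) -> int:
    """Stable per-image seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), class_index, image_index])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_dataset(
    n_per_class: int,
    size: int = 224,
    seed: int = 0,
    out_dir: str | Path | None = None,
    **spec_kwargs,
):
    """Balanced labelled phantom set: 4 * n_per_class images.

    Returns (images array (n, size, size, 3) uint8, labels list, manifest rows
    [(relative path, class, per-image seed), ...]).  When ``out_dir`` is
    given, images are written as PNG in a directory-per-class layout with a
    ``manifest.csv`` alongside.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    images, labels, manifest = [], [], []
    for ci, cls in enumerate(CLASSES):
        for ii in range(n_per_class):
            s = phantom_seed(seed, ci, ii)
            img, lab = generate_fundus(PhantomSpec(label=cls, size=size, seed=s, **spec_kwargs))
            images.append(img)
            labels.append(lab)
            manifest.append((f"{cls}/{cls}_{ii:04d}.png", cls, s))
    images = np.stack(images)
    if out_dir is not None:
        out = Path(out_dir)
        for img, (rel, _, _) in zip(images, manifest):
            path = out / rel
            path.parent.mkdir(parents=True, exist_ok=True)
            Image.fromarray(img).save(path)
        with open(out / "manifest.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["path", "class", "seed"])
            writer.writerows(manifest)
    return images, labels, manifest


def load_dataset(root: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a directory-per-class image tree (``root/<class>/*.png``)."""
    root = Path(root)
    images, labels = [], []
    for cls in CLASSES:
        cdir = root / cls
        if not cdir.is_dir():
            continue
        for path in sorted(cdir.iterdir()):
            if path.suffix.lower() in {".png", ".jpg", ".jpeg"}:
                images.append(np.asarray(Image.open(path).convert("RGB")))
                labels.append(cls)
    if not images:
        raise FileNotFoundError(f"no class-directory images found under {root}")
    return np.stack(images), labels
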