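"""Seeded generator of synthetic two-channel autophagy HTS fields.

Each field is a 16-bit-style two-channel image (red = DsRed-like, green =
pHluorin-like) with a pixel-perfect ground-truth class mask over
{0 background, 1 phagophore, 2 autolysosome}.  Vesicles are rendered as
disks, blurred by a Gaussian PSF and degraded with Poisson shot noise plus
Gaussian read noise.  Faint clutter blobs emulate out-of-focus cellular
texture and are *not* part of the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import SimulationConfig
from .masks import PHAGOPHORE, AUTOLYSOSOME, validate_mask
from .evaluate import extract_bounding_boxes, BoundingBox


@dataclass
class VesicleSpec:
    """Ground-truth record for one simulated vesicle."""

    center: tuple[float, float]  # (row, col), 0-based
    radius: float
    class_id: int  # 1 phagophore, 2 autolysosome

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("vesicle radius must be >= 1 pixel")
        if self.class_id not in (PHAGOPHORE, AUTOLYSOSOME):
            raise ValueError("class_id must be 1 (phagophore) or 2 (autolysosome)")


@dataclass
class SyntheticSample:
    """One simulated field: image, clean mask, vesicle list and tight boxes."""

    image: np.ndarray  # (H, W, 2) float in [0, 1], channels (red, green)
    mask: np.ndarray  # (H, W) uint8 in {0, 1, 2}
    vesicles: list[VesicleSpec] = field(default_factory=list)
    boxes: list[BoundingBox] = field(default_factory=list)
    image_id: str = ""


def _disk_indices(center: tuple[float, float], radius: float, shape: tuple[int, int]):
    """Row/col indices of the pixels whose centre lies inside the disk."""
    r0, c0 = center
    h, w = shape
    rmin = max(int(np.floor(r0 - radius)), 0)
    rmax = min(int(np.ceil(r0 + radius)) + 1, h)
    cmin = max(int(np.floor(c0 - radius)), 0)
    cmax = min(int(np.ceil(c0 + radius)) + 1, w)
    rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
    inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    return rr[inside], cc[inside]


def _draw_vesicles(rng: np.random.Generator, cfg: SimulationConfig) -> list[VesicleSpec]:
    specs: list[VesicleSpec] = []
    for class_id, count_mean, (r_mean, r_sd) in (
        (PHAGOPHORE, cfg.phagophore_count_mean, cfg.phagophore_radius),
        (AUTOLYSOSOME, cfg.autolysosome_count_mean, cfg.autolysosome_radius),
    ):
        n = int(rng.poisson(count_mean))
        for _ in range(n):
            radius = float(max(rng.normal(r_mean, r_sd), 1.0))
            # keep the disk fully inside the field so its mask support is intact
            margin = min(radius, (min(cfg.height, cfg.width) - 1) / 2)
            row = float(rng.uniform(margin, cfg.height - 1 - margin))
            col = float(rng.uniform(margin, cfg.width - 1 - margin))
            specs.append(VesicleSpec(center=(row, col), radius=radius, class_id=class_id))
    # interleave classes in a seeded order so overlap resolution is not biased
    order = rng.permutation(len(specs))
    return [specs[i] for i in order]


def render_sample(cfg: SimulationConfig, rng: np.random.Generator, image_id: str = "") -> SyntheticSample:
    """Render one field; the mask records draw order (later vesicle wins overlaps)."""
    h, w = cfg.height, cfg.width
    profiles = {PHAGOPHORE: cfg.phagophore_profile, AUTOLYSOSOME: cfg.autolysosome_profile}
    signal = np.full((h, w, 2), cfg.background_level, dtype=np.float64)
    mask = np.zeros((h, w), dtype=np.uint8)

    vesicles = _draw_vesicles(rng, cfg)
    for ves in vesicles:
        rr, cc = _disk_indices(ves.center, ves.radius, (h, w))
        red, green = profiles[ves.class_id]
        signal[rr, cc, 0] = np.maximum(signal[rr, cc, 0], red)
        signal[rr, cc, 1] = np.maximum(signal[rr, cc, 1], green)
        mask[rr, cc] = ves.class_id

    # unlabelled clutter: faint blobs in both channels (out-of-focus debris)
    n_clutter = int(rng.poisson(cfg.clutter_density * h * w))
    for _ in range(n_clutter):
        radius = float(max(rng.normal(2.0, 0.8), 1.0))
        row, col = rng.uniform(0, h - 1), rng.uniform(0, w - 1)
        rr, cc = _disk_indices((row, col), radius, (h, w))
        level = rng.uniform(0.08, 0.16)
        signal[rr, cc, 0] = np.maximum(signal[rr, cc, 0], level)
        signal[rr, cc, 1] = np.maximum(signal[rr, cc, 1], level * rng.uniform(0.3, 1.0))

    blurred = np.stack(
        [ndimage.gaussian_filter(signal[..., c], cfg.psf_sigma) for c in range(2)], axis=-1
    )
    noisy = blurred
    if cfg.noise_poisson_scale > 0:
        noisy = rng.poisson(np.clip(noisy, 0, None) * cfg.noise_poisson_scale) / cfg.noise_poisson_scale
    if cfg.noise_gaussian_sd > 0:
        noisy = noisy + rng.normal(0.0, cfg.noise_gaussian_sd, size=noisy.shape)
    image = np.clip(noisy, 0.0, 1.0)

    boxes = extract_bounding_boxes(mask, image_id=image_id)
    return SyntheticSample(image=image, mask=mask, vesicles=vesicles, boxes=boxes, image_id=image_id)


def generate_dataset(cfg: SimulationConfig) -> list[SyntheticSample]:
    """Generate ``cfg.n_images`` seeded fields.

    Each image gets an independent child generator spawned from ``cfg.seed``,
    so the dataset is bit-reproducible and individual images do not depend on
    how many precede them.
    """
    seqs = np.random.SeedSequence(cfg.seed).spawn(cfg.n_images)
    return [
        render_sample(cfg, np.random.default_rng(seq), image_id=f"img_{i:04d}")
        for i, seq in enumerate(seqs)
    ]


def class_pixel_frequencies(masks: list[np.ndarray]) -> np.ndarray:
    """Pooled pixel frequency of each class {0, 1, 2} across masks."""
    counts = np.zeros(3, dtype=np.int64)
    for m in masks:
        validate_mask(m)
        counts += np.bincount(m.ravel(), minlength=3)[:3]
    return counts / counts.sum()
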