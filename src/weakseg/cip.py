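"""Conventional-image-processing weak labeler and controlled label corruption.

The labeler is a hand-engineered spot-segmentation pipeline of the kind used
to bootstrap training data in HTS screens: difference-of-Gaussians band-pass
-> white top-hat -> threshold -> area filter -> optional watershed split,
then a per-component class call from the green/red intensity ratio (acidic
autolysosomes lose green fluorescence, neutral phagophores keep it).

``corrupt_mask`` injects the three systematic weak-label error types —
missing detection, misclassification and incomplete segmentation — at
controlled rates, so the downstream network's robustness to each can be
measured against clean ground truth.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator
from skimage import filters, measure, morphology, segmentation
from skimage.feature import peak_local_max

from .config import CipConfig, ErrorModelConfig
from .masks import PHAGOPHORE, AUTOLYSOSOME, validate_mask


def enhance(channel: np.ndarray, config: CipConfig | None = None) -> np.ndarray:
    """Background-suppressed spot response: DoG band-pass then white top-hat.

    Non-negative by construction (negative DoG response is clipped before the
    top-hat, which itself is non-negative).
    """
    config = config or CipConfig()
    channel = np.asarray(channel, dtype=np.float64)
    if channel.ndim != 2:
        raise ValueError(f"expected a 2-D channel, got shape {channel.shape}")
    if not np.isfinite(channel).all():
        raise ValueError("channel contains non-finite values")
    dog = filters.difference_of_gaussians(channel, config.dog_sigma_narrow, config.dog_sigma_wide)
    dog = np.clip(dog, 0.0, None)
    footprint = morphology.disk(config.tophat_radius)
    return morphology.white_tophat(dog, footprint)


def _threshold(response: np.ndarray, config: CipConfig) -> np.ndarray:
    if config.threshold_mode == "fixed":
        return response > config.fixed_threshold
    # Otsu is meaningless on a (near-)constant response; call it background
    if response.max() - response.min() < 1e-9:
        return np.zeros_like(response, dtype=bool)
    return response > filters.threshold_otsu(response)


def _watershed_split(binary: np.ndarray) -> np.ndarray:
    """Split touching blobs on the distance transform; returns a label image."""
    distance = ndimage.distance_transform_edt(binary)
    coords = peak_local_max(distance, labels=binary, min_distance=3, exclude_border=False)
    markers = np.zeros_like(binary, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    if markers.max() == 0:
        return measure.label(binary, connectivity=2)
    return segmentation.watershed(-distance, markers, mask=binary)


def segment_events(red: np.ndarray, green: np.ndarray, config: CipConfig | None = None) -> np.ndarray:
    """Weak-label mask from a two-channel field.

    Detection runs on the pixelwise channel maximum so red-only events are
    found; classification compares each component's mean green to mean red:
    ratio >= ``ratio_tau`` -> phagophore (1), else autolysosome (2).
    """
    config = config or CipConfig()
    red = np.asarray(red, dtype=np.float64)
    green = np.asarray(green, dtype=np.float64)
    if red.shape != green.shape or red.ndim != 2:
        raise ValueError("red and green must be 2-D arrays of the same shape")

    response = enhance(np.maximum(red, green), config)
    binary = _threshold(response, config)

    if config.use_watershed:
        labels = _watershed_split(binary)
    else:
        labels = measure.label(binary, connectivity=2)

    mask = np.zeros(red.shape, dtype=np.uint8)
    eps = 1e-12
    for region in measure.regionprops(labels):
        if region.area < config.min_event_area:
            continue
        coords = tuple(region.coords.T)
        ratio = green[coords].mean() / (red[coords].mean() + eps)
        mask[coords] = PHAGOPHORE if ratio >= config.ratio_tau else AUTOLYSOSOME
    return mask


class CipLabeler(BaseEstimator):
    """Scikit-learn-style wrapper around the CIP weak labeler.

    Stateless (``fit`` only validates); ``predict`` maps a list of (H, W, 2)
    images to weak-label masks.
    """

    def __init__(
        self,
        dog_sigma_narrow: float = 1.0,
        dog_sigma_wide: float = 6.0,
        tophat_radius: int = 8,
        threshold_mode: str = "otsu",
        fixed_threshold: float = 0.05,
        min_event_area: int = 6,
        use_watershed: bool = True,
        ratio_tau: float = 0.5,
    ):
        self.dog_sigma_narrow = dog_sigma_narrow
        self.dog_sigma_wide = dog_sigma_wide
        self.tophat_radius = tophat_radius
        self.threshold_mode = threshold_mode
        self.fixed_threshold = fixed_threshold
        self.min_event_area = min_event_area
        self.use_watershed = use_watershed
        self.ratio_tau = ratio_tau

    def _config(self) -> CipConfig:
        return CipConfig(**self.get_params())

    def fit(self, X=None, y=None):
        self.config_ = self._config()
        return self

    def predict(self, X: list[np.ndarray]) -> list[np.ndarray]:
        config = self._config()
        return [segment_events(img[..., 0], img[..., 1], config) for img in X]


# ---------------------------------------------------------------------------
# controlled corruption


def _erode_component(component: np.ndarray, fraction: float) -> np.ndarray:
    """Keep the innermost (1 - fraction) of a component's pixels, min 1 pixel.

    Pixels are ranked by distance to the component's boundary so erosion peels
    from the outside in, mimicking incomplete segmentation outlines.
    """
    area = int(component.sum())
    keep = max(int(round(area * (1.0 - fraction))), 1)
    if keep >= area:
        return component
    distance = ndimage.distance_transform_edt(component)
    flat = np.argsort(distance.ravel(), kind="stable")[::-1]  # innermost first
    kept = np.zeros(component.size, dtype=bool)
    kept[flat[:keep]] = True
    return kept.reshape(component.shape) & component


def corrupt_mask(mask: np.ndarray, config: ErrorModelConfig) -> np.ndarray:
    """Apply the three weak-label error types per event, mutually exclusively.

    Events are 8-connected components of each class.  Per event: with
    ``p_miss`` delete it; otherwise with ``p_swap`` flip its class 1<->2;
    otherwise erode ``erosion_fraction`` of its area.  Never invents events.
    """
    mask = validate_mask(mask)
    rng = np.random.default_rng(config.seed)
    out = np.zeros_like(mask)
    swap = {PHAGOPHORE: AUTOLYSOSOME, AUTOLYSOSOME: PHAGOPHORE}
    for class_id in (PHAGOPHORE, AUTOLYSOSOME):
        labelled = measure.label(mask == class_id, connectivity=2)
        for region in measure.regionprops(labelled):
            u = rng.uniform()
            if u < config.p_miss:
                continue
            new_class = class_id
            if rng.uniform() < config.p_swap:
                new_class = swap[class_id]
            component = labelled == region.label
            if config.erosion_fraction > 0 and new_class == class_id:
                component = _erode_component(component, config.erosion_fraction)
            out[component] = new_class
    return out


class MaskCorrupter(BaseEstimator):
    """Transformer applying seeded weak-label corruption to a list of masks.

    Each mask gets an independent child seed spawned from ``seed`` so the
    corruption of one image does not depend on the rest of the list.
    """

    def __init__(self, p_miss: float = 0.0, p_swap: float = 0.0, erosion_fraction: float = 0.0, seed: int = 0):
        self.p_miss = p_miss
        self.p_swap = p_swap
        self.erosion_fraction = erosion_fraction
        self.seed = seed

    def fit(self, X=None, y=None):
        ErrorModelConfig(self.p_miss, self.p_swap, self.erosion_fraction, self.seed)
        return self

    def transform(self, X: list[np.ndarray]) -> list[np.ndarray]:
        seeds = np.random.SeedSequence(self.seed).generate_state(len(X)) % (2**31)
        return [
            corrupt_mask(
                m,
                ErrorModelConfig(self.p_miss, self.p_swap, self.erosion_fraction, int(s)),
            )
            for m, s in zip(X, seeds)
        ]

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
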