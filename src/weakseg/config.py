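"""Configuration dataclasses for the simulation, weak labeler, noise model and trainer.

All configs are plain dataclasses with eager validation so that a bad YAML file
fails at load time, not three stages into an experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
import yaml


class ConfigurationError(ValueError):
    """Raised when a config violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic two-channel autophagy image generator.

    The defaults are calibrated so that a pooled dataset reproduces the strong
    class imbalance of real HTS autophagy screens: roughly 95% background,
    2.3% phagophore and 2.4% autolysosome pixels.  Phagophores are neutral-pH
    vesicles, bright in both the red (DsRed-like) and green (pHluorin-like)
    channels; autolysosomes are acidic, so the green fluorophore is quenched
    and they appear in the red channel only, and they are larger on average.
    """

    width: int = 256
    height: int = 256
    n_images: int = 50
    seed: int = 1
    phagophore_count_mean: float = 39.0
    autolysosome_count_mean: float = 16.5
    phagophore_radius: tuple[float, float] = (3.5, 0.7)
    autolysosome_radius: tuple[float, float] = (5.5, 1.0)
    # per-class (red_intensity, green_intensity) peak values in [0, 1]
    phagophore_profile: tuple[float, float] = (0.70, 0.80)
    autolysosome_profile: tuple[float, float] = (0.85, 0.10)
    background_level: float = 0.05
    psf_sigma: float = 1.0
    noise_gaussian_sd: float = 0.01
    noise_poisson_scale: float = 400.0
    clutter_density: float = 2.0e-4

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ConfigurationError("image dimensions must be positive")
        if self.n_images <= 0:
            raise ConfigurationError("n_images must be positive")
        if self.phagophore_count_mean < 0 or self.autolysosome_count_mean < 0:
            raise ConfigurationError("count means must be >= 0")
        for name in ("phagophore_radius", "autolysosome_radius"):
            mean, sd = getattr(self, name)
            if mean <= 0 or sd < 0:
                raise ConfigurationError(f"{name} must have positive mean, non-negative sd")
        if self.autolysosome_radius[0] <= self.phagophore_radius[0]:
            raise ConfigurationError(
                "autolysosome mean radius must exceed phagophore mean radius"
            )
        for name in ("phagophore_profile", "autolysosome_profile"):
            r, g = getattr(self, name)
            if not (0.0 <= r <= 1.0 and 0.0 <= g <= 1.0):
                raise ConfigurationError(f"{name} intensities must be in [0, 1]")
        r, g = self.phagophore_profile
        if g < 0.8 * r:
            raise ConfigurationError("phagophore must be bright in both channels (green >= 0.8*red)")
        r, g = self.autolysosome_profile
        if g > 0.2 * r:
            raise ConfigurationError("autolysosome green must be quenched (green <= 0.2*red)")
        if not 0.0 <= self.background_level <= 1.0:
            raise ConfigurationError("background_level must be in [0, 1]")
        if self.psf_sigma <= 0:
            raise ConfigurationError("psf_sigma must be > 0")
        if self.noise_gaussian_sd < 0 or self.noise_poisson_scale < 0:
            raise ConfigurationError("noise parameters must be >= 0")
        if self.clutter_density < 0:
            raise ConfigurationError("clutter_density must be >= 0")


def full_scale_config(**overrides) -> SimulationConfig:
    """Preset matching the real screen's image geometry (680x512, two channels).

    Event counts scale with pixel area so pooled class frequencies stay at the
    desk calibration.
    """
    scale = (680 * 512) / (256 * 256)
    params = dict(
        width=680,
        height=512,
        phagophore_count_mean=39.0 * scale,
        autolysosome_count_mean=16.5 * scale,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@dataclass
class CipConfig:
    """Parameters of the conventional-image-processing weak labeler.

    The pipeline is difference-of-Gaussians band-pass -> white top-hat ->
    threshold -> area filter -> optional watershed split, with per-component
    classification by the green/red mean-intensity ratio (``ratio_tau``):
    phagophores keep green fluorescence, autolysosomes lose it.
    """

    dog_sigma_narrow: float = 1.0
    dog_sigma_wide: float = 6.0
    tophat_radius: int = 8
    threshold_mode: str = "otsu"
    fixed_threshold: float = 0.05
    min_event_area: int = 6
    use_watershed: bool = True
    ratio_tau: float = 0.5

    def __post_init__(self) -> None:
        if self.dog_sigma_narrow >= self.dog_sigma_wide:
            raise ConfigurationError("dog_sigma_narrow must be < dog_sigma_wide")
        if self.min_event_area < 1:
            raise ConfigurationError("min_event_area must be >= 1")
        if self.ratio_tau <= 0:
            raise ConfigurationError("ratio_tau must be > 0")
        if self.threshold_mode not in ("otsu", "fixed"):
            raise ConfigurationError("threshold_mode must be 'otsu' or 'fixed'")


@dataclass
class ErrorModelConfig:
    """Controlled weak-label corruption: the three systematic error types.

    Per event (8-connected component of one class), mutually exclusively:
    with ``p_miss`` the event is deleted (missing detection); otherwise with
    ``p_swap`` its class is flipped (misclassification); otherwise
    ``erosion_fraction`` of its area is shaved off the boundary (incomplete
    segmentation).
    """

    p_miss: float = 0.0
    p_swap: float = 0.0
    erosion_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_miss", "p_swap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.erosion_fraction < 1.0:
            raise ConfigurationError("erosion_fraction must be in [0, 1)")


@dataclass
class UNetSpec:
    """Architecture of the symmetric encoder-decoder segmentation network.

    One skip connection per pooling stage; channel widths double per stage
    starting at ``base_filters``.
    """

    depth: int = 3
    base_filters: int = 16
    n_classes: int = 3
    in_channels: int = 2

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ConfigurationError("depth must be >= 1")
        if self.base_filters < 1 or self.n_classes < 2 or self.in_channels < 1:
            raise ConfigurationError("invalid UNetSpec")

    @property
    def skip_connections(self) -> int:
        return self.depth


def desk_unet_spec() -> UNetSpec:
    """Reduced-width network for CPU-scale experiments on 128x128 crops."""
    return UNetSpec(depth=3, base_filters=8, n_classes=3, in_channels=2)


@dataclass
class TrainConfig:
    """SGDM training schedule.

    Defaults follow the weak-label (CDL) regime; the curated-data (MDL)
    regime differs only in the initial learning rate (0.001) and the split.
    """

    initial_lr: float = 0.002
    momentum: float = 0.9
    l2: float = 0.001
    lr_drop_factor: float = 0.8
    lr_drop_every: int = 3
    batch_size: int = 4
    epochs: int = 15
    augment: bool = True
    split: tuple[float, float, float] = (0.85, 0.10, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ConfigurationError("split fractions must sum to 1")
        if min(self.split) < 0:
            raise ConfigurationError("split fractions must be non-negative")
        for name in ("initial_lr", "momentum", "lr_drop_factor"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.batch_size < 1 or self.epochs < 1 or self.lr_drop_every < 1:
            raise ConfigurationError("batch_size, epochs, lr_drop_every must be >= 1")


def mdl_train_config(**overrides) -> TrainConfig:
    """Training schedule for the manually-curated regime."""
    params = dict(initial_lr=0.001, split=(0.80, 0.10, 0.10))
    params.update(overrides)
    return TrainConfig(**params)


def desk_train_config(**overrides) -> TrainConfig:
    """Schedule for desk-scale experiments (hundreds of SGD steps, not ~10^5).

    The relative schedule (momentum 0.9, L2 0.001, x0.8 drop every 3 epochs,
    batch 4) is unchanged; the initial learning rate is raised to 0.2 because
    a run of a few hundred mini-batch updates sits in a different step-size
    regime than a full-scale run of ~10^5 updates, and 10 epochs on a few
    hundred small images is where the desk-scale loss plateaus.
    """
    params = dict(initial_lr=0.2, epochs=10)
    params.update(overrides)
    return TrainConfig(**params)


_CONFIG_CLASSES = {
    "simulation": SimulationConfig,
    "cip": CipConfig,
    "noise": ErrorModelConfig,
    "unet": UNetSpec,
    "train": TrainConfig,
}


def load_yaml_config(path: str | Path, kind: str):
    """Load one config section (``simulation``/``cip``/``noise``/``unet``/``train``)."""
    cls = _CONFIG_CLASSES[kind]
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if kind in raw:
        raw = raw[kind]
    for key, value in list(raw.items()):
        if isinstance(value, list):
            raw[key] = tuple(value)
    return cls(**raw)


def config_to_dict(cfg) -> dict:
    return asdict(cfg)
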