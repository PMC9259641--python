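"""End-to-end orchestration of the weak-label bootstrapping experiments.

``run_cdl`` simulates a dataset, produces weak labels (either by running the
conventional-image-processing labeler on the images, or by corrupting the
ground-truth masks at controlled error rates), trains the U-net on them and
evaluates both the network's predictions and the weak labels themselves
against clean ground truth on a held-out test set.  ``run_mdl`` trains on a
small curated label set instead (here: clean ground-truth masks standing in
for expert-corrected annotations, optionally overridden by mask PNGs dropped
into a ``corrected/`` directory, the scriptable replacement for a GUI
correction step).  ``compare_methods`` lines the reports up side by side.

All stage seeds derive from a single master seed by fixed offsets, so every
non-training stage is bit-reproducible from the stored config.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as wio
from .cip import CipLabeler, MaskCorrupter
from .config import (
    CipConfig,
    ErrorModelConfig,
    SimulationConfig,
    TrainConfig,
    UNetSpec,
    config_to_dict,
    desk_unet_spec,
)
from .evaluate import SegMetricsReport, detection_report, evaluate_segmentation, extract_bounding_boxes
from .simulate import generate_dataset
from .train import split_dataset, train_model

# fixed offsets deriving stage seeds from the master seed
_SEED_OFFSETS = {"simulate": 11, "corrupt": 23, "split": 37, "train": 53}


def stage_seed(master_seed: int, stage: str) -> int:
    return (master_seed + _SEED_OFFSETS[stage]) % (2**31)


@dataclass
class ExperimentConfig:
    """Master configuration for a CDL/MDL/CIP-only experiment."""

    mode: str = "cdl"  # {"cdl", "mdl", "cip_only"}
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    cip: CipConfig = field(default_factory=CipConfig)
    noise: ErrorModelConfig | None = None  # None -> weak labels come from CIP
    train: TrainConfig = field(default_factory=TrainConfig)
    unet: UNetSpec = field(default_factory=desk_unet_spec)
    curated_fraction: float = 0.15  # MDL: fraction of the training pool that is curated
    output_dir: Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("cdl", "mdl", "cip_only"):
            raise ValueError("mode must be 'cdl', 'mdl' or 'cip_only'")

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "sim": config_to_dict(self.sim),
            "cip": config_to_dict(self.cip),
            "noise": config_to_dict(self.noise) if self.noise else None,
            "train": config_to_dict(self.train),
            "unet": config_to_dict(self.unet),
            "curated_fraction": self.curated_fraction,
            "seed": self.seed,
        }

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class ExperimentResult:
    """Reports plus provenance for one experiment run."""

    mode: str
    seg_reports: dict[str, SegMetricsReport]
    detection_reports: dict
    training_log: list | None
    provenance: dict
    artifact_paths: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "seg_reports": {k: v.to_dict() for k, v in self.seg_reports.items()},
            "detection_reports": self.detection_reports,
            "training_log": self.training_log,
            "provenance": self.provenance,
            "artifact_paths": {k: str(v) for k, v in self.artifact_paths.items()},
        }


def _weak_labels(samples, config: ExperimentConfig) -> list[np.ndarray]:
    """Weak training labels: real CIP output, or controlled corruption of truth."""
    if config.noise is not None:
        corrupter = MaskCorrupter(
            p_miss=config.noise.p_miss,
            p_swap=config.noise.p_swap,
            erosion_fraction=config.noise.erosion_fraction,
            seed=config.noise.seed if config.noise.seed else stage_seed(config.seed, "corrupt"),
        )
        return corrupter.fit_transform([s.mask for s in samples])
    labeler = CipLabeler(**{k: getattr(config.cip, k) for k in (
        "dog_sigma_narrow", "dog_sigma_wide", "tophat_radius", "threshold_mode",
        "fixed_threshold", "min_event_area", "use_watershed", "ratio_tau")})
    return labeler.fit().predict([s.image for s in samples])


def _provenance(config: ExperimentConfig) -> dict:
    return {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "master_seed": config.seed,
        "stage_seeds": {k: stage_seed(config.seed, k) for k in _SEED_OFFSETS},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }


def _write_result(result: ExperimentResult, output_dir: Path | None) -> None:
    if output_dir is None:
        return
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    path = output_dir / f"{result.mode}_result.json"
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2, default=str)
    result.artifact_paths["result_json"] = path


def _detection_vs_truth(pred_masks, truth_masks, ids):
    method_boxes = []
    truth_boxes = []
    for pm, tm, image_id in zip(pred_masks, truth_masks, ids):
        method_boxes += extract_bounding_boxes(pm, image_id=image_id, source="method")
        truth_boxes += extract_bounding_boxes(tm, image_id=image_id, source="human")
    return detection_report(method_boxes, truth_boxes).to_dict()


def run_cdl(config: ExperimentConfig) -> ExperimentResult:
    """Weak-label bootstrapping: train on noisy labels, test against clean truth.

    The returned ``seg_reports`` contain the trained network's test-set report
    (``"cdl"``) and the weak labels' own report on the same test images
    (``"weak_labels"``) — the pair whose comparison quantifies generalisation
    beyond the label noise.
    """
    try:
        sim_cfg = SimulationConfig(**{**config_to_dict(config.sim), "seed": stage_seed(config.seed, "simulate")})
        samples = generate_dataset(sim_cfg)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    try:
        weak = _weak_labels(samples, config)
    except Exception as exc:
        raise RuntimeError(f"stage 'weak_labels' failed: {exc}") from exc

    ids = list(range(len(samples)))
    train_ids, val_ids, test_ids = split_dataset(ids, config.train.split, stage_seed(config.seed, "split"))

    try:
        model = train_model(
            [samples[i].image for i in train_ids],
            [weak[i] for i in train_ids],
            config.train,
            config.unet,
            validation_data=(
                [samples[i].image for i in val_ids],
                [weak[i] for i in val_ids],
            ) if val_ids else None,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'train' failed: {exc}") from exc

    test_images = [samples[i].image for i in test_ids]
    test_truth = [samples[i].mask for i in test_ids]
    test_weak = [weak[i] for i in test_ids]
    preds = model.predict(test_images)

    seg_reports = {
        "cdl": evaluate_segmentation(preds, test_truth),
        "weak_labels": evaluate_segmentation(test_weak, test_truth),
    }
    det = {
        "cdl": _detection_vs_truth(preds, test_truth, [samples[i].image_id for i in test_ids]),
        "weak_labels": _detection_vs_truth(test_weak, test_truth, [samples[i].image_id for i in test_ids]),
    }
    result = ExperimentResult(
        mode="cdl",
        seg_reports=seg_reports,
        detection_reports=det,
        training_log=model.training_log_,
        provenance=_provenance(config),
    )
    result.provenance["test_ids"] = test_ids
    _write_result(result, config.output_dir)
    return result


def _load_corrected(corrected_dir: Path | None, ids, masks):
    """Merge expert-corrected mask PNGs (by image id) over the given masks."""
    if corrected_dir is None:
        return masks
    corrected_dir = Path(corrected_dir)
    out = []
    for i, m in zip(ids, masks):
        path = corrected_dir / f"img_{i:04d}_mask.png"
        out.append(wio.read_mask_png(path) if path.exists() else m)
    return out


def run_mdl(config: ExperimentConfig, corrected_dir: str | Path | None = None) -> ExperimentResult:
    """Curated-label training: a small expert-quality set, same architecture.

    Clean ground-truth masks stand in for expert-corrected labels; PNGs in
    ``corrected_dir`` (named ``img_NNNN_mask.png``) override them.
    """
    sim_cfg = SimulationConfig(**{**config_to_dict(config.sim), "seed": stage_seed(config.seed, "simulate")})
    samples = generate_dataset(sim_cfg)
    ids = list(range(len(samples)))
    train_ids, val_ids, test_ids = split_dataset(ids, config.train.split, stage_seed(config.seed, "split"))

    # curated subset: a fraction of the training pool, as expert correction is costly
    n_curated = max(int(round(len(train_ids) * config.curated_fraction)), config.train.batch_size)
    curated_ids = train_ids[:n_curated]
    if len(curated_ids) < config.train.batch_size:
        raise ValueError("curated set smaller than the mini-batch size")
    curated_masks = _load_corrected(corrected_dir, curated_ids, [samples[i].mask for i in curated_ids])

    model = train_model(
        [samples[i].image for i in curated_ids],
        curated_masks,
        config.train,
        config.unet,
        validation_data=(
            [samples[i].image for i in val_ids],
            [samples[i].mask for i in val_ids],
        ) if val_ids else None,
    )
    test_images = [samples[i].image for i in test_ids]
    test_truth = [samples[i].mask for i in test_ids]
    preds = model.predict(test_images)
    result = ExperimentResult(
        mode="mdl",
        seg_reports={"mdl": evaluate_segmentation(preds, test_truth)},
        detection_reports={
            "mdl": _detection_vs_truth(preds, test_truth, [samples[i].image_id for i in test_ids])
        },
        training_log=model.training_log_,
        provenance=_provenance(config),
    )
    result.provenance["test_ids"] = test_ids
    result.provenance["n_curated"] = len(curated_ids)
    _write_result(result, config.output_dir)
    return result


def run_cip_only(config: ExperimentConfig) -> ExperimentResult:
    """Evaluate the conventional labeler itself against clean ground truth."""
    sim_cfg = SimulationConfig(**{**config_to_dict(config.sim), "seed": stage_seed(config.seed, "simulate")})
    samples = generate_dataset(sim_cfg)
    ids = list(range(len(samples)))
    _, _, test_ids = split_dataset(ids, config.train.split, stage_seed(config.seed, "split"))
    labeler = CipLabeler(**{k: getattr(config.cip, k) for k in (
        "dog_sigma_narrow", "dog_sigma_wide", "tophat_radius", "threshold_mode",
        "fixed_threshold", "min_event_area", "use_watershed", "ratio_tau")})
    test_images = [samples[i].image for i in test_ids]
    test_truth = [samples[i].mask for i in test_ids]
    preds = labeler.fit().predict(test_images)
    result = ExperimentResult(
        mode="cip_only",
        seg_reports={"cip": evaluate_segmentation(preds, test_truth)},
        detection_reports={
            "cip": _detection_vs_truth(preds, test_truth, [samples[i].image_id for i in test_ids])
        },
        training_log=None,
        provenance=_provenance(config),
    )
    result.provenance["test_ids"] = test_ids
    _write_result(result, config.output_dir)
    return result


_AGG_KEYS = ("global_accuracy", "mean_accuracy", "mean_iou", "weighted_iou", "mean_bfs")


def compare_methods(reports: dict[str, SegMetricsReport], baseline: str = "cip") -> dict:
    """Side-by-side aggregated metrics plus relative improvement over a baseline.

    All reports must have been computed on the identical test set (checked via
    pixel totals).
    """
    totals = {name: r.confusion.n_pixels for name, r in reports.items()}
    if len(set(totals.values())) > 1:
        raise ValueError(f"reports cover different test sets (pixel totals {totals})")
    table = {name: {k: getattr(r, k) for k in _AGG_KEYS} for name, r in reports.items()}
    out = {"metrics": table, "per_class": {
        name: [m.to_dict() for m in r.per_class] for name, r in reports.items()
    }, "confusions_row_normalized": {
        name: r.confusion.row_normalized().tolist() for name, r in reports.items()
    }}
    if baseline in reports:
        base = table[baseline]
        out["relative_improvement_over_" + baseline] = {
            name: {
                k: ((table[name][k] - base[k]) / base[k] if base[k] else float("nan"))
                for k in _AGG_KEYS
            }
            for name in reports
            if name != baseline
        }
    return out
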