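"""File formats: 16-bit two-channel TIFFs, indexed mask PNGs, box CSVs.

Images are stored as 16-bit TIFF with the two fluorescence channels as
samples-per-pixel (red first, green second, recorded in the description
tag); an optional 8-bit RGB PNG rendering puts the channels in the red and
green planes with blue zeroed.  Label masks are single-channel 8-bit PNGs
over {0, 1, 2}.  Bounding boxes are CSV with 0-based half-open coordinates.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .evaluate import BoundingBox
from .masks import validate_mask

BOX_COLUMNS = ["image_id", "class_id", "row_min", "col_min", "row_max", "col_max"]


def write_image_tiff(path: str | Path, image: np.ndarray) -> None:
    """(H, W, 2) float in [0, 1] -> 16-bit two-sample TIFF."""
    path = Path(path)
    if image.ndim != 3 or image.shape[-1] != 2:
        raise ValueError("expected an (H, W, 2) image")
    scaled = np.clip(np.asarray(image, dtype=np.float64), 0, 1)
    data = np.round(scaled * 65535).astype(np.uint16)
    try:
        tifffile.imwrite(path, data, photometric="minisblack", description="channels=red,green")
    except OSError as exc:
        raise OSError(f"failed to write TIFF {path}: {exc}") from exc


def read_image_tiff(path: str | Path) -> np.ndarray:
    """16-bit two-channel TIFF -> (H, W, 2) float in [0, 1]."""
    data = tifffile.imread(Path(path))
    if data.ndim == 3 and data.shape[0] == 2:  # stored as two pages
        data = data.transpose(1, 2, 0)
    if data.ndim != 3 or data.shape[-1] != 2:
        raise ValueError(f"{path}: expected a two-channel image, got shape {data.shape}")
    return data.astype(np.float64) / 65535.0


def write_image_png(path: str | Path, image: np.ndarray) -> None:
    """(H, W, 2) float -> 8-bit RGB PNG, channels in red/green, blue zeroed."""
    if image.ndim != 3 or image.shape[-1] != 2:
        raise ValueError("expected an (H, W, 2) image")
    scaled = np.clip(np.asarray(image, dtype=np.float64), 0, 1)
    rgb = np.zeros(image.shape[:2] + (3,), dtype=np.uint8)
    rgb[..., 0] = np.round(scaled[..., 0] * 255)
    rgb[..., 1] = np.round(scaled[..., 1] * 255)
    iio.imwrite(Path(path), rgb)


def read_image_png(path: str | Path) -> np.ndarray:
    """8-bit RGB PNG -> (H, W, 2) float; red and green planes become channels."""
    rgb = iio.imread(Path(path))
    if rgb.ndim != 3 or rgb.shape[-1] < 2:
        raise ValueError(f"{path}: expected an RGB image")
    return rgb[..., :2].astype(np.float64) / 255.0


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    """Label mask -> single-channel 8-bit PNG with raw class indices."""
    iio.imwrite(Path(path), validate_mask(mask).astype(np.uint8))


def read_mask_png(path: str | Path) -> np.ndarray:
    mask = iio.imread(Path(path))
    if mask.ndim == 3:  # tolerate greyscale saved as RGB
        mask = mask[..., 0]
    return validate_mask(mask.astype(np.uint8))


def write_boxes_csv(path: str | Path, boxes: list[BoundingBox]) -> None:
    rows = [
        {
            "image_id": b.image_id,
            "class_id": b.class_id,
            "row_min": b.row_min,
            "col_min": b.col_min,
            "row_max": b.row_max,
            "col_max": b.col_max,
        }
        for b in boxes
    ]
    pd.DataFrame(rows, columns=BOX_COLUMNS).to_csv(Path(path), index=False)


def read_boxes_csv(path: str | Path, source: str = "method") -> list[BoundingBox]:
    df = pd.read_csv(Path(path))
    return [
        BoundingBox(
            image_id=str(row.image_id),
            class_id=int(row.class_id),
            row_min=int(row.row_min),
            col_min=int(row.col_min),
            row_max=int(row.row_max),
            col_max=int(row.col_max),
            source=source,
        )
        for row in df.itertuples()
    ]


def write_sample(sample, directory: str | Path, write_png: bool = False) -> dict[str, Path]:
    """Write one synthetic sample's image, mask and boxes into a directory.

    Returns the mapping of artifact kind to path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = sample.image_id or "sample"
    paths = {
        "image": directory / f"{stem}.tiff",
        "mask": directory / f"{stem}_mask.png",
        "boxes": directory / f"{stem}_boxes.csv",
    }
    write_image_tiff(paths["image"], sample.image)
    write_mask_png(paths["mask"], sample.mask)
    write_boxes_csv(paths["boxes"], sample.boxes)
    if write_png:
        paths["png"] = directory / f"{stem}.png"
        write_image_png(paths["png"], sample.image)
    return paths


def read_sample(directory: str | Path, stem: str):
    """Read back (image, mask, boxes) written by ``write_sample``."""
    directory = Path(directory)
    image = read_image_tiff(directory / f"{stem}.tiff")
    mask = read_mask_png(directory / f"{stem}_mask.png")
    boxes = read_boxes_csv(directory / f"{stem}_boxes.csv")
    return image, mask, boxes
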