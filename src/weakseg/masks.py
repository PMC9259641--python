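"""Label-mask conventions shared across the package.

A label mask is a 2-D ``uint8`` array over the three retained classes.
"""

from __future__ import annotations

import numpy as np

BACKGROUND = 0
PHAGOPHORE = 1
AUTOLYSOSOME = 2

CLASS_NAMES = {BACKGROUND: "background", PHAGOPHORE: "phagophore", AUTOLYSOSOME: "autolysosome"}
N_CLASSES = 3


def validate_mask(mask: np.ndarray) -> np.ndarray:
    """Check a label mask is 2-D over {0, 1, 2}; returns it unchanged."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"label mask must be 2-D, got shape {mask.shape}")
    if mask.size and (mask.min() < 0 or mask.max() > 2):
        raise ValueError("label mask values must be in {0, 1, 2}")
    return mask


def one_hot(mask: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    """(H, W) labels -> (n_classes, H, W) one-hot float array."""
    mask = validate_mask(mask)
    out = np.zeros((n_classes,) + mask.shape, dtype=np.float64)
    for c in range(n_classes):
        out[c] = mask == c
    return out
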