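"""Reading and writing images, masks and polygon JSON.

RGB frames are stored as 8-bit PNG/JPEG and mapped to [0, 1] floats by
division with 255. Segmentation maps are single-channel 8-bit PNGs whose
pixel value is the class index (0..6).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .scheme import N_CLASSES


def load_image(path: str | Path) -> np.ndarray:
    """Load an 8-bit RGB image as an H x W x 3 float array in [0, 1]."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return arr.astype(np.float64) / 255.0


def save_image(path: str | Path, img: np.ndarray) -> None:
    """Save a [0, 1] float image as 8-bit (format from the extension)."""
    arr = np.clip(np.asarray(img), 0.0, 1.0)
    iio.imwrite(path, (np.round(arr * 255.0)).astype(np.uint8))


def load_mask(path: str | Path) -> np.ndarray:
    """Load a class-index mask from a single-channel 8-bit PNG."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    mask = arr.astype(np.int64)
    if mask.max(initial=0) >= N_CLASSES:
        raise ValueError(f"mask {path} holds indices >= {N_CLASSES}")
    return mask


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    mask = np.asarray(mask)
    if mask.min(initial=0) < 0 or mask.max(initial=0) >= N_CLASSES:
        raise ValueError("mask values must be class indices in 0..6")
    iio.imwrite(path, mask.astype(np.uint8))


def _json_default(o):
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.floating):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def save_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def load_json(path: str | Path):
    return json.loads(Path(path).read_text())
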