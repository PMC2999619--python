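"""File-format helpers: 8-bit RGB images, single-channel label masks,
YAML/JSON configs."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .stain import CLASS_NAMES


def write_image(path, image: np.ndarray) -> None:
    iio.imwrite(Path(path), image)


def read_image(path) -> np.ndarray:
    image = iio.imread(Path(path))
    if image.ndim == 3 and image.shape[2] == 4:  # drop alpha
        image = image[..., :3]
    if image.ndim != 3 or image.shape[2] != 3 or image.dtype != np.uint8:
        raise ValueError(f"{path}: expected an 8-bit RGB image")
    return image


def write_mask(path, mask: np.ndarray) -> None:
    mask = np.asarray(mask)
    if not set(np.unique(mask).astype(int).tolist()) <= set(CLASS_NAMES):
        raise ValueError("mask contains labels outside the five known classes")
    iio.imwrite(Path(path), mask.astype(np.uint8))


def read_mask(path) -> np.ndarray:
    mask = iio.imread(Path(path))
    if mask.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel label mask")
    if not set(np.unique(mask).astype(int).tolist()) <= set(CLASS_NAMES):
        raise ValueError(f"{path}: mask contains unknown labels")
    return mask.astype(np.uint8)


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text) or {}
    return json.loads(text)


def dump_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_coerce))


def _coerce(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serialisable: {type(x)}")
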