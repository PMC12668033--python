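"""File formats: tiles (PNG/TIFF), masks, stain sidecars, crop tables."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .instances import InstanceMask
from .types import RGBTile, StainBasis


def read_tile(path, white_point: float = 255.0,
              pixel_size_um: float = 0.45) -> RGBTile:
    """Read an 8-bit RGB tile from PNG or TIFF (alpha dropped)."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return RGBTile(arr.astype(float), white_point=white_point,
                   pixel_size_um=pixel_size_um)


def write_tile(path, tile: RGBTile):
    arr = np.clip(np.round(tile.pixels), 0, 255).astype(np.uint8)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def write_mask_png(path, mask: np.ndarray):
    """Binary mask as single-channel 8-bit PNG (0/255)."""
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def read_mask_png(path) -> np.ndarray:
    return np.asarray(iio.imread(path)) > 127


def write_instance_tiff(path, inst: InstanceMask):
    """Instance labels as 16-bit single-channel TIFF."""
    if inst.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many instances for uint16")
    tifffile.imwrite(Path(path), inst.labels.astype(np.uint16))


def read_instance_tiff(path) -> InstanceMask:
    labels = tifffile.imread(path).astype(np.int32)
    return InstanceMask(labels, int(labels.max()))


def write_probability_tiff(path, prob: np.ndarray):
    """Probability map as 32-bit float TIFF (debug output)."""
    tifffile.imwrite(Path(path), np.asarray(prob, dtype=np.float32))


def write_stain_sidecar(path, basis: StainBasis, normalizer: float, seed: int):
    """JSON sidecar with the fitted stain model (W row-major)."""
    payload = {
        "W": [[float(v) for v in row] for row in basis.W],
        "stain_names": list(basis.stain_names),
        "normalizer": float(normalizer),
        "seed": int(seed),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_stain_sidecar(path):
    payload = json.loads(Path(path).read_text())
    basis = StainBasis(np.asarray(payload["W"]),
                       stain_names=tuple(payload["stain_names"]))
    return basis, payload["normalizer"], payload["seed"]
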