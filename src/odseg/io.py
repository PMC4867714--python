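"""Image, mask and report I/O shared by the CLI and the library."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import InvalidInputError
from .preprocess import FundusImage

__all__ = ["read_fundus", "read_mask", "write_mask", "write_raster"]


def read_fundus(path: str | Path) -> FundusImage:
    """Read an RGB fundus image (PNG/JPEG/TIFF); RGBA alpha is dropped."""
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidInputError(
            f"{path}: expected a 3-channel RGB image, got shape {arr.shape}"
        )
    return FundusImage(np.asarray(arr, dtype=np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a ground-truth/prediction mask: any nonzero pixel counts as true."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3].max(axis=-1)
    return np.asarray(arr) > 0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as 8-bit PNG, 0 = background, 255 = optic disc."""
    out = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    iio.imwrite(path, out)


def write_raster(path: str | Path, raster: np.ndarray) -> None:
    """Write a [0, 1] raster as 8-bit PNG (×255, rounded half up)."""
    arr = np.asarray(raster, dtype=np.float64)
    out = np.floor(np.clip(arr, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
    iio.imwrite(path, out)
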