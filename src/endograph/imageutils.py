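"""Shared image helpers: dtype/grayscale normalisation and file loading.

All pipeline stages operate on 2-D float64 arrays with intensities in [0, 1],
0-based pixel-center coordinates, x = column, y = row.  Color input is reduced
with ITU-R BT.601 luma weights everywhere (descriptors, NCC, SSD alike).
"""
from __future__ import annotations

import numpy as np

from .exceptions import InvalidInputError

# ITU-R BT.601 luma weights for RGB -> gray.
_BT601 = np.array([0.299, 0.587, 0.114])


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Return a 2-D float64 intensity array in [0, 1].

    Accepts 2-D grayscale or 3-D RGB/RGBA arrays of integer or float dtype.
    Integer input is scaled by its dtype range; float input is assumed to be
    in [0, 1] already (values are clipped).
    """
    arr = np.asarray(image)
    if arr.ndim == 3:
        if arr.shape[2] not in (3, 4):
            raise InvalidInputError(
                f"expected RGB(A) last axis of 3 or 4, got {arr.shape[2]}"
            )
        arr = _scale_to_unit(arr[..., :3]) @ _BT601
        return np.clip(arr, 0.0, 1.0)
    if arr.ndim != 2:
        raise InvalidInputError(f"expected a 2-D image, got ndim={arr.ndim}")
    return np.clip(_scale_to_unit(arr), 0.0, 1.0)


def _scale_to_unit(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(np.float64) / float(info.max)
    return arr.astype(np.float64)


def load_image(path) -> np.ndarray:
    """Read a PNG/JPEG file as a [0, 1] grayscale float array."""
    import imageio.v3 as iio

    return to_grayscale(iio.imread(path))


def save_image(path, image: np.ndarray) -> None:
    """Write a [0, 1] float array (or uint8 RGB) as an 8-bit image file."""
    import imageio.v3 as iio

    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = (np.clip(arr, 0.0, 1.0) * 255.0).round().astype(np.uint8)
    iio.imwrite(path, arr)
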