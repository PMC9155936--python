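"""Reading and writing 2-D grayscale images on the canonical 0-255 float scale.

Integer inputs of any bit depth are rescaled linearly so full scale maps to
255; multi-channel inputs are collapsed to luminance.  Output files are
8-bit grayscale (clip to [0, 255], round half-to-even).  ``.npy`` files act
as a lossless numeric-array container for bit-exact round trips — no
rescaling or quantization is applied to them.

The in-memory representation is a plain 2-D ``float64`` numpy array;
(row, column) indexing, origin top-left.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np

__all__ = ["load_image", "save_image"]

_LUMA = np.array([0.299, 0.587, 0.114])


def _validate(img: np.ndarray, source: object) -> np.ndarray:
    if img.ndim != 2 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError(f"{source}: expected a non-empty 2-D image, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError(f"{source}: image contains non-finite values")
    return img


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Load a PNG/TIFF/``.npy`` file as a float64 image on the 0-255 scale.

    RGB(A) images are converted to luminance (0.299 R + 0.587 G + 0.114 B);
    integer images are rescaled by ``255 / (2**bits - 1)``.  ``.npy`` arrays
    are returned as stored (cast to float64).
    """
    path = os.fspath(path)
    if path.endswith(".npy"):
        arr = np.load(path)
        return _validate(np.asarray(arr, dtype=float), path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # plugins raise a zoo of error types
        raise OSError(f"cannot read image file {path!r}: {exc}") from exc
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            arr = np.asarray(arr, dtype=float)[:, :, :3] @ _LUMA
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        scale = 255.0 / info.max if info.max != 255 else 1.0
        out = arr.astype(float) * scale
    else:
        out = arr.astype(float)
    return _validate(out, path)


def save_image(image: np.ndarray, path: str | os.PathLike) -> None:
    """Write an image to 8-bit grayscale PNG/TIFF, or bit-exact ``.npy``.

    For 8-bit outputs values are clipped to [0, 255] and rounded
    half-to-even, so a load/save round trip moves any pixel by at most 0.5
    and integer-valued images in range survive exactly.
    """
    img = _validate(np.asarray(image, dtype=float), "save_image input")
    path = os.fspath(path)
    if path.endswith(".npy"):
        np.save(path, img)
        return
    quantized = np.rint(np.clip(img, 0.0, 255.0)).astype(np.uint8)
    try:
        iio.imwrite(path, quantized)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot write image file {path!r}: {exc}") from exc
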