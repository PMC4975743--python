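"""Reading and writing grayscale images on their native intensity scale.

Intensities are never silently normalized to [0, 1]: the KL fidelity
weight ``beta`` and PSNR's 255^2 peak constant are scale-dependent, so
8-bit data stays on [0, 255] and 16-bit on [0, 65535].  RGB inputs are
collapsed to luminance with a logged warning.  Float TIFF round-trips
are lossless.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

logger = logging.getLogger("tgvdeblur")

__all__ = ["read_image", "write_image"]

#: Rec. 709 luminance weights used for RGB -> gray conversion
_LUMA = np.array([0.2126, 0.7152, 0.0722])


def read_image(path: "str | Path") -> np.ndarray:
    """Load a PNG/TIFF image as a float array on its native scale."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        if arr.shape[-1] == 4:  # drop alpha
            arr = arr[..., :3]
        if arr.shape[-1] == 3:
            logger.warning("RGB input %s converted to grayscale by luminance", path)
            arr = arr.astype(float) @ _LUMA
        elif arr.shape[-1] == 1:
            arr = arr[..., 0]
        else:
            raise ValueError(f"unsupported channel count {arr.shape[-1]} in {path}")
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image in {path}, got shape {arr.shape}")
    return arr.astype(float)


def write_image(img: np.ndarray, path: "str | Path", dtype: str = "uint8") -> None:
    """Write an image, inverse-mapping to the requested depth with clipping.

    dtype: ``uint8`` (PNG/TIFF, clip to [0, 255]), ``uint16`` (TIFF,
    clip to [0, 65535]) or ``float32`` (lossless TIFF).
    """
    path = Path(path)
    img = np.asarray(img, dtype=float)
    suffix = path.suffix.lower()
    if dtype == "uint8":
        out = np.clip(np.round(img), 0, 255).astype(np.uint8)
    elif dtype == "uint16":
        out = np.clip(np.round(img), 0, 65535).astype(np.uint16)
        if suffix == ".png":
            raise ValueError("16-bit output requires a TIFF path")
    elif dtype == "float32":
        if suffix not in (".tif", ".tiff"):
            raise ValueError("float32 output requires a TIFF path")
        out = img.astype(np.float32)
    else:
        raise ValueError(f"unsupported output dtype {dtype!r}")
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)
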