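"""Thin raster reading layer over tifffile / imageio / Pillow."""

from __future__ import annotations

import os

import numpy as np

IMAGE_EXTENSIONS = {"tif", "tiff", "png", "jpg", "jpeg"}


def read_image(path: str) -> np.ndarray:
    ext = os.path.splitext(path)[1].lstrip(".").lower()
    if ext in ("tif", "tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path))
    import imageio.v3 as iio

    return np.asarray(iio.imread(path))


def can_decode(path: str) -> bool:
    try:
        img = read_image(path)
    except Exception:
        return False
    return img.size > 0
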