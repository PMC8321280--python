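"""Reading, writing, and normalizing 2-D MR slices and binary masks.

The pipeline works on a fixed 256x256 grayscale grid with intensities in
[0, 1]; this module converts between that working representation and the
on-disk formats (8-bit PNG/TIFF rasters, NIfTI-1 volumes) and maps result
masks back to the native resolution of the input slice.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import nibabel as nib
import numpy as np
from skimage.transform import resize as _sk_resize

#: Rec.601 luma weights used to collapse RGB inputs to one channel.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Side length of the square working grid every slice is resampled to.
WORKING_SIZE = 256

__all__ = [
    "GrayImage",
    "read_slice",
    "write_mask",
    "normalize_image",
    "resize_to_working",
    "mask_to_original",
    "as_mask",
]


@dataclass(frozen=True)
class GrayImage:
    """A single grayscale slice with a declared encoding range.

    Parameters
    ----------
    pixels
        2-D float array, row-major, 0-based indexing.
    value_range
        The (min, max) of the encoding, e.g. ``(0, 255)`` for 8-bit input
        or ``(0, 1)`` after :func:`normalize_image`.
    """

    pixels: np.ndarray
    value_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("GrayImage requires a nonempty 2-D pixel grid")
        lo, hi = self.value_range
        if lo > hi:
            raise ValueError("value_range must satisfy min <= max")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def as_mask(arr: np.ndarray) -> np.ndarray:
    """Coerce an array to a strictly boolean 2-D mask."""
    m = np.asarray(arr)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    return m.astype(bool)


def _to_gray(arr: np.ndarray) -> np.ndarray:
    """Collapse trailing color channels with Rec.601 luma weights."""
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            w = np.asarray(LUMA_WEIGHTS)
            return arr.astype(float) @ w
        if arr.shape[2] == 1:
            return arr[:, :, 0].astype(float)
        raise ValueError(f"unsupported channel count: {arr.shape[2]}")
    return arr.astype(float)


def read_slice(path: str | os.PathLike, slice_index: int | None = None) -> GrayImage:
    """Read one 2-D grayscale slice from a PNG/TIFF raster or NIfTI volume.

    RGB rasters are converted to a single luminance channel. For NIfTI
    volumes ``slice_index`` selects the axial plane (third axis); it is
    required for 3-D inputs and rejected for 2-D ones.

    Raises
    ------
    IOError
        if the file cannot be read.
    IndexError
        if ``slice_index`` is outside the volume.
    ValueError
        for unsupported formats or missing/superfluous ``slice_index``.
    """
    path = os.fspath(path)
    ext = path.lower()
    if ext.endswith((".nii", ".nii.gz")):
        try:
            vol = np.asanyarray(nib.load(path).dataobj).astype(float)
        except FileNotFoundError:
            raise IOError(f"cannot read NIfTI file: {path}")
        if vol.ndim == 2:
            if slice_index is not None:
                raise ValueError("slice_index given for a 2-D NIfTI image")
            data = vol
        elif vol.ndim >= 3:
            vol = vol.reshape(vol.shape[:3])
            if slice_index is None:
                raise ValueError("slice_index required for a 3-D volume")
            if not 0 <= slice_index < vol.shape[2]:
                raise IndexError(
                    f"slice_index {slice_index} out of range [0, {vol.shape[2]})"
                )
            data = vol[:, :, slice_index]
        else:
            raise ValueError(f"unsupported NIfTI dimensionality: {vol.ndim}")
        lo = float(min(data.min(), 0.0))
        hi = float(data.max()) if data.max() > lo else lo + 1.0
        return GrayImage(data, (lo, hi))

    if ext.endswith((".png", ".tif", ".tiff")):
        try:
            arr = iio.imread(path)
        except FileNotFoundError:
            raise IOError(f"cannot read image file: {path}")
        if slice_index is not None:
            raise ValueError("slice_index is only valid for NIfTI volumes")
        data = _to_gray(arr)
        hi = 65535.0 if arr.dtype == np.uint16 else 255.0
        return GrayImage(data, (0.0, hi))

    raise ValueError(f"unsupported format: {path} (expected PNG, TIFF or NIfTI)")


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a binary mask as an 8-bit image (foreground 255, background 0)."""
    m = as_mask(mask)
    out = np.where(m, 255, 0).astype(np.uint8)
    try:
        iio.imwrite(os.fspath(path), out)
    except FileNotFoundError:
        raise IOError(f"cannot write mask to: {path}")


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read an 8-bit mask image back into a boolean array (nonzero = True)."""
    img = read_slice(path)
    return img.pixels > (img.value_range[1] / 2.0)


def normalize_image(img: GrayImage) -> GrayImage:
    """Linearly map ``value_range`` onto [0, 1].

    A constant image maps to all zeros: a flat slice carries no segmentable
    signal, and the zero image keeps every downstream stage well defined.
    """
    lo, hi = img.value_range
    if hi > lo and img.pixels.max() > img.pixels.min():
        out = (img.pixels - lo) / (hi - lo)
        out = np.clip(out, 0.0, 1.0)
    else:
        out = np.zeros_like(img.pixels)
    return GrayImage(out, (0.0, 1.0))


def resize_to_working(
    img: GrayImage, size: tuple[int, int] = (WORKING_SIZE, WORKING_SIZE)
) -> GrayImage:
    """Bilinearly resample a slice to the working grid (default 256x256)."""
    if img.shape == size:
        return img
    out = _sk_resize(
        img.pixels, size, order=1, mode="edge", anti_aliasing=False,
        preserve_range=True,
    )
    out = np.clip(out, *img.value_range)
    return GrayImage(out, img.value_range)


def mask_to_original(mask: np.ndarray, original_shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor resample a working-grid mask to the native shape."""
    m = as_mask(mask)
    if m.shape == tuple(original_shape):
        return m
    out = _sk_resize(
        m.astype(float), original_shape, order=0, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return out > 0.5


def resize_mask_to_working(
    mask: np.ndarray, size: tuple[int, int] = (WORKING_SIZE, WORKING_SIZE)
) -> np.ndarray:
    """Nearest-neighbor resample a native-shape mask onto the working grid."""
    m = as_mask(mask)
    if m.shape == tuple(size):
        return m
    out = _sk_resize(
        m.astype(float), size, order=0, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return out > 0.5
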