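"""Skull stripping by Otsu thresholding and morphological cleanup.

The brain is isolated from a normalized slice in a fixed sequence:
threshold at the Otsu level, open with a disk, dilate with the same disk,
keep the largest connected component, close, fill holes, and zero out
everything outside the resulting mask. The bright skull ring survives
thresholding but — being a smaller component than the brain, separated
from it by the dark CSF gap — is discarded by the largest-component step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import closing, dilation, disk, opening

from .imgio import GrayImage, as_mask

__all__ = ["StripResult", "otsu_threshold", "largest_blob", "fill_holes", "strip_skull"]

#: Default disk structuring-element radius (pixels on the 256x256 grid).
DEFAULT_SELEM_RADIUS = 3

# Foreground components use 8-connectivity, hole filling uses 4-connected
# background: the standard dual pairing that avoids topological paradoxes.
_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = ndi.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class StripResult:
    """Output of :func:`strip_skull`.

    Attributes
    ----------
    stripped
        The input slice with all non-brain pixels set to 0.
    brain_mask
        Boolean brain mask (at most one connected component).
    otsu_threshold
        The threshold used, on the image's intensity scale.
    """

    stripped: GrayImage
    brain_mask: np.ndarray
    otsu_threshold: float


def otsu_threshold(img: GrayImage) -> float:
    """Histogram threshold maximizing between-class variance (256 bins).

    A constant image has no two classes to separate; its constant value is
    returned by convention.
    """
    px = img.pixels
    if px.max() == px.min():
        return float(px.flat[0])
    return float(threshold_otsu(px, nbins=256))


def largest_blob(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component.

    Ties break toward the component whose first pixel comes earliest in
    row-major order (scipy labels components in raster order, so the
    lowest-numbered label among the maxima is that component). An empty
    mask is returned unchanged.
    """
    m = as_mask(mask)
    labels, n = ndi.label(m, structure=_STRUCT8)
    if n == 0:
        return np.zeros_like(m)
    counts = np.bincount(labels.ravel())[1:]  # skip background
    best = int(np.argmax(counts)) + 1  # argmax returns the first maximum
    return labels == best


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background regions not 4-connected to the image border."""
    return ndi.binary_fill_holes(as_mask(mask), structure=_STRUCT4)


def strip_skull(img: GrayImage, selem_radius: int = DEFAULT_SELEM_RADIUS) -> StripResult:
    """Remove skull and non-brain tissue from a normalized slice.

    Parameters
    ----------
    img
        Slice normalized to value_range (0, 1).
    selem_radius
        Radius in pixels of the disk structuring element shared by the
        opening, dilation, and closing steps (default 3 at 256x256).

    Returns
    -------
    StripResult
        Brain-only intensities, the brain mask, and the threshold used.
        If thresholding plus opening leaves no foreground, the mask and
        stripped image are empty and a warning is emitted.
    """
    if img.value_range != (0.0, 1.0):
        raise ValueError("strip_skull expects a normalized image (value_range (0, 1))")
    if selem_radius < 1:
        raise ValueError("selem_radius must be >= 1")

    t = otsu_threshold(img)
    bw = img.pixels > t
    se = disk(selem_radius)
    bw = opening(bw, se)
    bw = dilation(bw, se)
    if not bw.any():
        warnings.warn("skull stripping produced an empty brain mask", stacklevel=2)
        empty = np.zeros(img.shape, dtype=bool)
        return StripResult(GrayImage(np.zeros(img.shape), (0.0, 1.0)), empty, t)
    bw = largest_blob(bw)
    bw = closing(bw, se)
    bw = fill_holes(bw)
    stripped = np.where(bw, img.pixels, 0.0)
    return StripResult(GrayImage(stripped, (0.0, 1.0)), bw, t)
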