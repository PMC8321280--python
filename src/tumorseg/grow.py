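"""Tolerance-based seeded region growing.

From a seed pixel, a connected region is grown breadth-first: a frontier
pixel is accepted when its intensity lies within ``tolerance`` of the
reference level. The reference is either the running mean of the region
accepted so far (classic seeded region growing, robust to a slightly
off-peak seed) or the fixed seed reference (which makes the result an
exact connected component of a thresholded image, and hence checkable
against an independent flood-fill oracle). The default tolerance of 0.1
on [0, 1]-normalized intensities reflects the near-homogeneous appearance
of tumor regions on FLAIR; ring-shaped results around a dark necrotic
core are rescued afterwards by hole filling.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np

from .imgio import GrayImage, as_mask
from .seeds import SeedPoint
from .skullstrip import fill_holes

__all__ = ["GrowParams", "CandidateROI", "region_grow", "postprocess_roi"]

_OFFSETS4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_OFFSETS8 = _OFFSETS4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


@dataclass(frozen=True)
class GrowParams:
    """Region-growing parameters.

    Attributes
    ----------
    tolerance
        Maximum absolute intensity difference from the reference level,
        on the [0, 1] scale (default 0.1).
    connectivity
        Pixel neighborhood, 4 or 8 (default 8).
    criterion
        ``"running_mean"`` compares each candidate to the evolving region
        mean; ``"fixed_seed"`` compares to the constant seed reference.
    max_region_fraction
        Growth stops once the region exceeds this fraction of the image
        area — a guard against flooding a near-uniform slice.
    """

    tolerance: float = 0.1
    connectivity: int = 8
    criterion: str = "running_mean"
    max_region_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.tolerance <= 1.0:
            raise ValueError("tolerance must lie in [0, 1]")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.criterion not in ("running_mean", "fixed_seed"):
            raise ValueError("criterion must be 'running_mean' or 'fixed_seed'")
        if not 0.0 < self.max_region_fraction <= 1.0:
            raise ValueError("max_region_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class CandidateROI:
    """A grown region: mask, originating seed, parameters, pixel count."""

    mask: np.ndarray
    seed: SeedPoint
    params: GrowParams
    n_pixels: int
    degenerate: bool = False
    metrics: object | None = None


def region_grow(
    img: GrayImage,
    seed: SeedPoint,
    params: GrowParams | None = None,
    brain_mask: np.ndarray | None = None,
) -> CandidateROI:
    """Grow a connected region from ``seed`` under the tolerance criterion.

    Pixels are visited in FIFO (breadth-first) order, which makes the
    running-mean variant deterministic. When ``brain_mask`` is supplied,
    stripped-out pixels are never accepted regardless of tolerance.

    The seed pixel itself must satisfy the criterion against the seed
    reference; if it does not (e.g. a seed landing on a stripped-out zero
    pixel), an empty region flagged ``degenerate`` is returned.

    Raises
    ------
    IndexError
        if the seed position lies outside the image.
    """
    if params is None:
        params = GrowParams()
    h, w = img.shape
    r0, c0 = seed.position
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise IndexError(f"seed position {seed.position} outside image {img.shape}")

    px = img.pixels
    allowed = as_mask(brain_mask) if brain_mask is not None else None
    if allowed is not None and allowed.shape != img.shape:
        raise ValueError("brain_mask shape must match the image")
    tol = params.tolerance
    offsets = _OFFSETS8 if params.connectivity == 8 else _OFFSETS4
    running = params.criterion == "running_mean"
    cap = int(params.max_region_fraction * h * w)

    mask = np.zeros((h, w), dtype=bool)
    seed_ok = abs(px[r0, c0] - seed.reference_intensity) <= tol
    if allowed is not None and not allowed[r0, c0]:
        seed_ok = False
    if not seed_ok:
        return CandidateROI(mask, seed, params, 0, degenerate=True)

    mask[r0, c0] = True
    n = 1
    total = float(px[r0, c0])
    mu = total / n if running else seed.reference_intensity
    queue: deque[tuple[int, int]] = deque([(r0, c0)])
    while queue and n < cap:
        r, c = queue.popleft()
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if not (0 <= rr < h and 0 <= cc < w) or mask[rr, cc]:
                continue
            if allowed is not None and not allowed[rr, cc]:
                continue
            if abs(px[rr, cc] - mu) <= tol:
                mask[rr, cc] = True
                n += 1
                if running:
                    total += float(px[rr, cc])
                    mu = total / n
                queue.append((rr, cc))
                if n >= cap:
                    break
    return CandidateROI(mask, seed, params, n)


def postprocess_roi(roi: CandidateROI) -> CandidateROI:
    """Fill holes in a grown region (rescues dark necrotic tumor cores).

    Monotone: the output mask is a superset of the input mask.
    """
    filled = fill_holes(roi.mask)
    return replace(roi, mask=filled, n_pixels=int(filled.sum()))
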