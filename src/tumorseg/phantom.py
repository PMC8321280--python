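"""Synthetic 2-D brain-slice phantoms with known ground truth.

Each phantom emulates the gross structure of an axial FLAIR slice: dark
background, a bright elliptical skull ring, a mid-intensity brain
ellipse separated from the ring by a dark CSF gap, and a hyperintense
circular tumor inside the brain (optionally with a dark necrotic core,
which exercises the fill-hole rescue). Additive Gaussian noise is applied
and the result clipped to [0, 1]. Ground-truth tumor and brain masks are
returned alongside the image, so every pipeline stage is testable without
clinical data.

The skull ring is deliberately brighter than brain tissue so the
stripping stage has real work to do: thresholding keeps the ring, and
only the largest-component selection discards it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .imgio import GrayImage

__all__ = ["PhantomSpec", "generate_phantom", "generate_suite"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity parameters of one phantom slice.

    Default intensities — background 0.0, brain 0.45, skull 0.8, tumor
    0.9, noise sigma 0.02 — make the tumor the brightest interior
    structure (FLAIR-like) while keeping Otsu's threshold between
    background and tissue.
    """

    size: tuple[int, int] = (256, 256)
    brain_axes: tuple[float, float] = (90.0, 70.0)
    skull_thickness: float = 5.0
    skull_gap: float = 10.0
    tumor_center: tuple[float, float] = (100.0, 150.0)
    tumor_radius: float = 18.0
    tumor_intensity: float = 0.9
    brain_intensity: float = 0.45
    skull_intensity: float = 0.8
    core_dark: bool = False
    core_radius_fraction: float = 0.5
    core_intensity: float = 0.1
    noise_sigma: float = 0.02
    rng_seed: int = 0


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  axes: tuple[float, float]) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    a, b = axes
    return ((rr - center[0]) / a) ** 2 + ((cc - center[1]) / b) ** 2 <= 1.0


def _disk_mask(shape: tuple[int, int], center: tuple[float, float],
               radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _validate(spec: PhantomSpec) -> None:
    h, w = spec.size
    cr, cc = h / 2.0, w / 2.0
    a, b = spec.brain_axes
    violations = []
    if spec.tumor_intensity <= spec.brain_intensity:
        violations.append("tumor_intensity must exceed brain_intensity")
    # Conservative containment: the tumor disk, inflated by its radius,
    # must stay inside the brain ellipse.
    tr, tc = spec.tumor_center
    margin = spec.tumor_radius
    if ((tr - cr) / (a - margin)) ** 2 + ((tc - cc) / (b - margin)) ** 2 > 1.0:
        violations.append("tumor disk must lie entirely inside the brain ellipse")
    ring_outer = max(a, b) + spec.skull_gap + spec.skull_thickness
    if ring_outer >= min(cr, cc):
        violations.append("skull ring must fit inside the image")
    if spec.skull_gap <= 0:
        violations.append("skull_gap must be positive (ring and brain disjoint)")
    if violations:
        raise ValueError("invalid phantom spec: " + "; ".join(violations))


def generate_phantom(spec: PhantomSpec) -> tuple[GrayImage, np.ndarray, np.ndarray]:
    """Render one phantom slice.

    Returns
    -------
    (image, tumor_truth, brain_truth)
        The noisy slice as a normalized :class:`GrayImage`, the exact
        tumor-disk mask (including the dark core when ``core_dark``),
        and the brain-ellipse mask. Deterministic for a fixed
        ``rng_seed``.
    """
    _validate(spec)
    h, w = spec.size
    center = (h / 2.0, w / 2.0)
    a, b = spec.brain_axes

    brain = _ellipse_mask(spec.size, center, (a, b))
    ring_outer = _ellipse_mask(
        spec.size, center,
        (a + spec.skull_gap + spec.skull_thickness,
         b + spec.skull_gap + spec.skull_thickness),
    )
    ring_inner = _ellipse_mask(
        spec.size, center, (a + spec.skull_gap, b + spec.skull_gap)
    )
    skull = ring_outer & ~ring_inner
    tumor = _disk_mask(spec.size, spec.tumor_center, spec.tumor_radius)

    img = np.zeros(spec.size, dtype=float)
    img[skull] = spec.skull_intensity
    img[brain] = spec.brain_intensity
    img[tumor] = spec.tumor_intensity
    if spec.core_dark:
        core = _disk_mask(
            spec.size, spec.tumor_center,
            spec.tumor_radius * spec.core_radius_fraction,
        )
        img[core] = spec.core_intensity

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.rng_seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=spec.size)
    img = np.clip(img, 0.0, 1.0)
    return GrayImage(img, (0.0, 1.0)), tumor, brain


def generate_suite(
    n: int,
    base_spec: PhantomSpec | None = None,
    master_seed: int = 0,
    radius_range: tuple[float, float] = (12.0, 24.0),
    center_jitter: float = 40.0,
    tumor_intensity_range: tuple[float, float] = (0.78, 0.95),
) -> list[tuple[GrayImage, np.ndarray, np.ndarray]]:
    """Generate ``n`` phantoms with randomized tumor geometry and contrast.

    Tumor radius, center offset from the brain center, and tumor
    intensity are drawn uniformly from the stated ranges; draws that
    would push the tumor outside the brain ellipse are re-jittered
    toward the center. Seeds derive deterministically from
    ``master_seed``, so the suite is reproducible across runs. The
    default intensity range keeps tumor contrast at least ~0.3 above
    the brain level.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base_spec if base_spec is not None else PhantomSpec()
    rng = np.random.default_rng(master_seed)
    h, w = base.size
    cr, cc = h / 2.0, w / 2.0
    a, b = base.brain_axes
    out = []
    for i in range(n):
        radius = float(rng.uniform(*radius_range))
        intensity = float(rng.uniform(*tumor_intensity_range))
        # rejection-sample a center keeping the inflated disk inside the brain
        while True:
            dr = float(rng.uniform(-center_jitter, center_jitter))
            dc = float(rng.uniform(-center_jitter, center_jitter))
            if ((dr / (a - radius)) ** 2 + (dc / (b - radius)) ** 2) <= 0.95:
                break
        spec = replace(
            base,
            tumor_center=(cr + dr, cc + dc),
            tumor_radius=radius,
            tumor_intensity=intensity,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(generate_phantom(spec))
    return out
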