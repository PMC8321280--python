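"""Automatic seed-point initialization from block mean intensities.

The working image is partitioned into non-overlapping square tiles
(default 8x8 pixels, i.e. 1024 tiles on the 256x256 grid). Each tile's
mean intensity is computed and the centers of the k brightest tiles
(default 5) become the seed points for region growing. On FLAIR-like
contrast the tumor is the brightest interior structure, so its tiles
dominate the ranking once the skull has been stripped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imgio import GrayImage

__all__ = ["BlockStat", "SeedPoint", "compute_block_stats", "select_seeds"]

DEFAULT_BLOCK_SIZE = 8
DEFAULT_K_SEEDS = 5


@dataclass(frozen=True)
class BlockStat:
    """One tile: origin (top-left pixel), center coordinate, mean intensity."""

    block_origin: tuple[int, int]
    center: tuple[int, int]
    mean_intensity: float


@dataclass(frozen=True)
class SeedPoint:
    """A seed position and the mean intensity of its originating tile."""

    position: tuple[int, int]
    reference_intensity: float


def compute_block_stats(img: GrayImage, block_size: int = DEFAULT_BLOCK_SIZE) -> list[BlockStat]:
    """Mean intensity of every non-overlapping tile, in row-major tile order.

    The tile center is the pixel at offset ``(block_size - 1) // 2`` from
    the tile origin along each axis — ``origin + (3, 3)`` for 8x8 tiles.

    Raises
    ------
    ValueError
        if the image dimensions are not divisible by ``block_size``
        (resize to the working grid first).
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    h, w = img.shape
    if h % block_size or w % block_size:
        raise ValueError(
            f"image shape {img.shape} not divisible by block_size {block_size}"
        )
    nb_r, nb_c = h // block_size, w // block_size
    means = img.pixels.reshape(nb_r, block_size, nb_c, block_size).mean(axis=(1, 3))
    off = (block_size - 1) // 2
    stats: list[BlockStat] = []
    for bi in range(nb_r):
        r0 = bi * block_size
        for bj in range(nb_c):
            c0 = bj * block_size
            stats.append(
                BlockStat((r0, c0), (r0 + off, c0 + off), float(means[bi, bj]))
            )
    return stats


def select_seeds(stats: list[BlockStat], k: int = DEFAULT_K_SEEDS) -> list[SeedPoint]:
    """Seed points at the centers of the k highest-mean tiles.

    Ordered by descending mean intensity; ties break toward earlier
    row-major tile order (the sort is stable over the input order). If
    fewer than k tiles are given, all are returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not stats:
        raise ValueError("no block statistics to select seeds from")
    ranked = sorted(stats, key=lambda s: -s.mean_intensity)
    return [SeedPoint(s.center, s.mean_intensity) for s in ranked[:k]]
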