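import numpy as np
import pytest
from scipy import ndimage as ndi

from tumorseg import GrowParams, SeedPoint, postprocess_roi, region_grow
from tumorseg.imgio import GrayImage

from conftest import make_image


def flood_fill_oracle(pixels, seed_pos, ref, tol, connectivity=8):
    """Independent oracle for the fixed-seed criterion: the connected
    component of {|I - ref| <= tol} containing the seed, via labeling."""
    ok = np.abs(pixels - ref) <= tol
    if not ok[seed_pos]:
        return np.zeros_like(ok)
    struct = ndi.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    labels, _ = ndi.label(ok, structure=struct)
    return labels == labels[seed_pos]


def fixed(tol, conn=8):
    return GrowParams(tolerance=tol, connectivity=conn, criterion="fixed_seed",
                      max_region_fraction=1.0)


class TestFixedSeedCriterion:
    def test_homogeneous_patch_recovered_exactly(self, rng):
        px = np.full((16, 16), 0.2)
        patch = np.zeros((16, 16), dtype=bool)
        patch[4:9, 3:11] = True  # 40 pixels
        px[patch] = 0.9
        roi = region_grow(make_image(px), SeedPoint((5, 5), 0.9), fixed(0.1))
        assert np.array_equal(roi.mask, patch)
        assert roi.n_pixels == 40

    def test_zero_tolerance_is_equality_flood_fill(self, rng):
        px = (rng.integers(0, 4, (12, 12)) / 4.0)
        seed = (6, 6)
        roi = region_grow(GrayImage(px), SeedPoint(seed, float(px[seed])), fixed(0.0))
        oracle = flood_fill_oracle(px, seed, px[seed], 0.0)
        assert np.array_equal(roi.mask, oracle)

    def test_uniform_image_floods_entirely(self):
        roi = region_grow(make_image(np.full((10, 10), 0.5)),
                          SeedPoint((5, 5), 0.5), fixed(0.05))
        assert roi.mask.all()

    @pytest.mark.parametrize("conn", [4, 8])
    def test_matches_oracle_on_random_grids(self, conn, rng):
        for _ in range(30):
            px = rng.uniform(0, 1, (16, 16))
            seed = (int(rng.integers(16)), int(rng.integers(16)))
            tol = float(rng.uniform(0.05, 0.5))
            ref = float(px[seed])
            roi = region_grow(GrayImage(px), SeedPoint(seed, ref),
                              fixed(tol, conn))
            oracle = flood_fill_oracle(px, seed, ref, tol, conn)
            assert np.array_equal(roi.mask, oracle)

    def test_tolerance_monotonicity(self, rng):
        px = rng.uniform(0, 1, (16, 16))
        seed = (8, 8)
        ref = float(px[seed])
        masks = [
            region_grow(GrayImage(px), SeedPoint(seed, ref), fixed(t)).mask
            for t in (0.05, 0.15, 0.3, 0.6)
        ]
        for small, big in zip(masks, masks[1:]):
            assert np.all(big >= small)


class TestRunningMean:
    def test_deterministic_across_runs(self, rng):
        px = rng.uniform(0, 1, (32, 32))
        sp = SeedPoint((16, 16), float(px[16, 16]))
        a = region_grow(GrayImage(px), sp)
        b = region_grow(GrayImage(px), sp)
        assert np.array_equal(a.mask, b.mask)

    def test_region_contains_seed_and_is_connected(self, rng):
        px = rng.uniform(0.4, 0.6, (24, 24))
        sp = SeedPoint((12, 12), float(px[12, 12]))
        roi = region_grow(GrayImage(px), sp)
        assert roi.mask[12, 12]
        labels, n = ndi.label(roi.mask, structure=np.ones((3, 3), bool))
        assert n == 1

    def test_tracks_slow_gradient_where_fixed_seed_stops(self):
        # intensity ramps 0.5 -> 0.95 across columns; running mean follows
        px = np.tile(np.linspace(0.5, 0.95, 32), (8, 1))
        sp = SeedPoint((4, 0), 0.5)
        run = region_grow(GrayImage(px), sp,
                          GrowParams(tolerance=0.1, max_region_fraction=1.0))
        fix = region_grow(GrayImage(px), sp, fixed(0.1))
        assert run.n_pixels > fix.n_pixels


class TestGuards:
    def test_seed_outside_image_raises(self):
        with pytest.raises(IndexError):
            region_grow(make_image(np.zeros((8, 8))), SeedPoint((9, 0), 0.0))

    def test_seed_on_stripped_pixel_is_degenerate(self):
        px = np.full((8, 8), 0.9)
        px[4, 4] = 0.0  # stripped-out pixel
        roi = region_grow(make_image(px), SeedPoint((4, 4), 0.9), fixed(0.1))
        assert roi.degenerate and roi.n_pixels == 0

    def test_brain_mask_excludes_outside_pixels(self):
        px = np.full((10, 10), 0.5)
        brain = np.zeros((10, 10), dtype=bool)
        brain[2:8, 2:8] = True
        roi = region_grow(make_image(px), SeedPoint((5, 5), 0.5),
                          fixed(0.5), brain_mask=brain)
        assert np.array_equal(roi.mask, brain)

    def test_max_region_fraction_caps_growth(self):
        roi = region_grow(
            make_image(np.full((20, 20), 0.5)), SeedPoint((10, 10), 0.5),
            GrowParams(tolerance=0.5, max_region_fraction=0.25),
        )
        assert roi.n_pixels == 100  # 0.25 * 400

    @pytest.mark.parametrize(
        "kwargs",
        [dict(tolerance=1.5), dict(connectivity=6), dict(criterion="magic"),
         dict(max_region_fraction=0.0)],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GrowParams(**kwargs)


class TestPostprocess:
    def test_ring_region_core_filled(self):
        px = np.full((20, 20), 0.2)
        rr, cc = np.ogrid[:20, :20]
        d2 = (rr - 10) ** 2 + (cc - 10) ** 2
        ring = (d2 <= 49) & (d2 > 16)
        px[ring] = 0.9
        roi = region_grow(make_image(px), SeedPoint((10, 3), 0.9), fixed(0.1))
        assert np.array_equal(roi.mask, ring)
        filled = postprocess_roi(roi)
        assert filled.mask[10, 10]  # core rescued
        assert filled.n_pixels == int(filled.mask.sum())
        assert np.all(filled.mask >= roi.mask)

    def test_solid_region_unchanged(self):
        px = np.full((10, 10), 0.2)
        px[3:7, 3:7] = 0.9
        roi = region_grow(make_image(px), SeedPoint((5, 5), 0.9), fixed(0.1))
        assert np.array_equal(postprocess_roi(roi).mask, roi.mask)
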