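import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from phenopam.segmentation import (
    DegenerateImageError,
    assign_plants,
    clean_mask,
    make_roi_grid,
    yen_threshold,
)


def brute_force_yen(image: np.ndarray, nbins: int = 256) -> int:
    """Independent oracle: scan every candidate threshold and evaluate the
    entropic-correlation criterion C(t) = 2 ln(P1 (1-P1)) - ln(S1 S2)
    directly from per-threshold histogram sums (exact Python integers,
    normalisation cancelled analytically)."""
    dmax = np.iinfo(image.dtype).max
    counts, _ = np.histogram(image, bins=nbins, range=(0, dmax + 1))
    counts = [int(c) for c in counts]
    N = sum(counts)
    total_sq = sum(c * c for c in counts)
    best_t, best_c = None, -math.inf
    for t in range(nbins):
        n1 = sum(counts[: t + 1])
        s1 = sum(c * c for c in counts[: t + 1])
        s2 = total_sq - s1
        if not (0 < n1 < N) or s1 <= 0 or s2 <= 0:
            continue
        c = 2.0 * (math.log(n1) + math.log(N - n1)) - (math.log(s1) + math.log(s2))
        if c > best_c:  # strict: ties keep the smallest t
            best_c, best_t = c, t
    assert best_t is not None
    width = (dmax + 1) / nbins
    return int((best_t + 1) * width) - 1


def random_test_image(rng: np.random.Generator, dtype: str) -> np.ndarray:
    """Bimodal, uniform, or few-level random image."""
    hi = np.iinfo(dtype).max
    kind = rng.integers(3)
    n = 2500
    if kind == 0:  # two-Gaussian mixture
        mus = rng.uniform(0.05, 0.95, size=2) * hi
        sds = rng.uniform(0.01, 0.1, size=2) * hi
        w = rng.uniform(0.2, 0.8)
        a = rng.normal(mus[0], sds[0], int(n * w))
        b = rng.normal(mus[1], sds[1], n - int(n * w))
        vals = np.concatenate([a, b])
    elif kind == 1:  # uniform
        vals = rng.uniform(0, hi, n)
    else:  # few discrete levels: exercises exact tie handling
        levels = rng.integers(0, hi + 1, size=rng.integers(2, 6))
        vals = rng.choice(levels, size=n)
    return np.clip(np.rint(vals), 0, hi).astype(dtype).reshape(50, 50)


class TestYenThreshold:
    @pytest.mark.parametrize("dtype", ["uint8", "uint16"])
    @pytest.mark.parametrize("seed", range(15))
    def test_matches_brute_force_oracle(self, dtype, seed):
        img = random_test_image(np.random.default_rng(seed), dtype)
        if img.min() == img.max():
            pytest.skip("degenerate draw")
        assert yen_threshold(img) == brute_force_yen(img)

    def test_matches_skimage_on_8bit(self):
        # independent library cross-check (identical binning on uint8)
        from skimage.filters import threshold_yen

        rng = np.random.default_rng(42)
        img = np.clip(
            np.concatenate(
                [rng.normal(60, 12, 3000), rng.normal(190, 18, 2000)]
            ).round(),
            0,
            255,
        ).astype(np.uint8).reshape(50, 100)
        assert yen_threshold(img) == int(threshold_yen(img))

    def test_perfectly_separable_image(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img[:, 5:] = 255
        t = yen_threshold(img)
        assert 0 <= t < 255
        np.testing.assert_array_equal(img > t, img == 255)

    def test_constant_image_is_degenerate(self):
        with pytest.raises(DegenerateImageError):
            yen_threshold(np.full((8, 8), 7, dtype=np.uint8))

    def test_16bit_binned_not_truncated(self):
        # the same scene scaled from 8 to 16 bit must give the scaled threshold
        rng = np.random.default_rng(5)
        img8 = np.clip(
            np.concatenate([rng.normal(50, 10, 2000), rng.normal(200, 15, 2000)]),
            0, 255,
        ).astype(np.uint8).reshape(40, 100)
        img16 = (img8.astype(np.uint16)) * 257  # maps 255 -> 65535
        t8, t16 = yen_threshold(img8), yen_threshold(img16)
        assert t16 // 256 == t8


class TestCleanMask:
    def test_speck_removed_blob_kept(self):
        m = np.zeros((40, 40), dtype=bool)
        m[2:4, 2:4] = True  # 4-px speck
        m[10:35, 10:30] = True  # 500-px blob
        out = clean_mask(m, min_object_px=50, max_hole_px=0)
        assert not out[2:4, 2:4].any()
        assert out[10:35, 10:30].all()

    def test_small_hole_filled(self):
        m = np.ones((30, 30), dtype=bool)
        m[0, :] = m[-1, :] = m[:, 0] = m[:, -1] = False
        m[10:12, 10:15] = False  # 10-px hole
        out = clean_mask(m, min_object_px=0, max_hole_px=25)
        assert out[10:12, 10:15].all()

    def test_hole_of_exactly_max_hole_px_stays_open(self):
        m = np.ones((30, 30), dtype=bool)
        m[10:12, 10:15] = False  # exactly 10 px
        out = clean_mask(m, min_object_px=0, max_hole_px=10)
        assert not out[10:12, 10:15].any()

    def test_zero_parameters_are_identity(self):
        rng = np.random.default_rng(0)
        m = rng.random((30, 30)) > 0.6
        np.testing.assert_array_equal(clean_mask(m, 0, 0), m)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            clean_mask(np.zeros((4, 4), dtype=bool), -1, 0)

    @given(
        m=hnp.arrays(bool, (25, 25), elements=st.booleans()),
        min_obj=st.integers(0, 20),
        max_hole=st.integers(0, 20),
    )
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_idempotent(self, m, min_obj, max_hole):
        once = clean_mask(m, min_obj, max_hole)
        np.testing.assert_array_equal(clean_mask(once, min_obj, max_hole), once)


class TestRoiGrid:
    def test_2x4_grid(self):
        layout = make_roi_grid(2, 4, (120, 85), (220, 156), 60, (480, 640))
        assert layout.n_roi == 8
        # row-major numbering: position 5 starts the second row
        assert layout.centers[4][0] > layout.centers[0][0]
        assert layout.centers[4][1] == layout.centers[0][1]

    def test_3x3_grid_nine_pots(self):
        layout = make_roi_grid(3, 3, (80, 120), 150, 60, (480, 640))
        assert layout.n_roi == 9

    def test_circles_pairwise_disjoint(self):
        layout = make_roi_grid(1, 2, (70, 70), 140, 50, (140, 300))
        overlap = layout.circle_mask(1) & layout.circle_mask(2)
        assert not overlap.any()

    def test_overlapping_circles_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_roi_grid(1, 2, (70, 70), 100, 51, (200, 400))

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            make_roi_grid(1, 2, (40, 40), 140, 50, (140, 300))


class TestSegmentFrame:
    def test_plants_of_unequal_brightness_all_recovered(self, small_layout):
        """The threshold stays at the plant/background gap even when plants
        differ markedly in absolute brightness (textured leaves)."""
        from phenopam.segmentation import segment_frame

        rng = np.random.default_rng(3)
        shape = small_layout.image_shape
        img = np.full(shape, 200.0)
        for center, level in (((70, 70), 3200.0), ((70, 210), 4800.0)):
            m = _disk(shape, center, 15)
            img[m] = level * np.exp(rng.normal(0, 0.04, int(m.sum())))
        img = np.clip(img + rng.normal(0, 80, shape), 0, 65535).astype(np.uint16)
        seg = segment_frame(img, small_layout)
        assert all(c > 500 for c in seg.pixel_counts)
        assert all(f.complete and f.independent for f in seg.flags)


def _disk(shape, center, r):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= r**2


class TestAssignPlants:
    def test_two_disjoint_disks(self, small_layout):
        shape = small_layout.image_shape
        mask = _disk(shape, (70, 70), 20) | _disk(shape, (70, 210), 20)
        seg = assign_plants(mask, small_layout)
        assert all(f.complete and f.independent for f in seg.flags)
        assert seg.pixel_counts[0] == _disk(shape, (70, 70), 20).sum()
        assert sum(seg.pixel_counts) == mask.sum()

    def test_dumbbell_flags_both_not_independent(self, small_layout):
        shape = small_layout.image_shape
        mask = _disk(shape, (70, 70), 20) | _disk(shape, (70, 210), 20)
        mask[68:73, 70:210] = True  # bridge
        seg = assign_plants(mask, small_layout)
        assert [f.independent for f in seg.flags] == [False, False]
        assert all(f.complete for f in seg.flags)

    def test_border_clipped_disk_not_complete(self, small_layout):
        shape = small_layout.image_shape
        mask = _disk(shape, (0, 70), 25) | _disk(shape, (70, 210), 20)
        seg = assign_plants(mask, small_layout)
        assert [f.complete for f in seg.flags] == [False, True]

    def test_empty_roi_has_zero_pixels(self, small_layout):
        mask = _disk(small_layout.image_shape, (70, 70), 15)
        seg = assign_plants(mask, small_layout)
        assert seg.pixel_counts == [int(mask.sum()), 0]
        assert seg.flags[1].complete and seg.flags[1].independent

    def test_component_outside_all_rois_diagnosed(self, small_layout):
        shape = small_layout.image_shape
        stray = _disk(shape, (15, 150), 6)
        mask = _disk(shape, (70, 70), 15) | stray
        seg = assign_plants(mask, small_layout)
        assert seg.n_unassigned_components == 1
        assert seg.unassigned_px == stray.sum()
        assert sum(seg.pixel_counts) <= mask.sum()

    @pytest.mark.parametrize("shift", [(0, 0), (3, -4), (-5, 6)])
    def test_flags_invariant_under_small_translation(self, small_layout, shift):
        shape = small_layout.image_shape
        base = _disk(shape, (70 + shift[0], 70 + shift[1]), 15) | _disk(
            shape, (70 + shift[0], 210 + shift[1]), 15
        )
        seg = assign_plants(base, small_layout)
        assert [(f.complete, f.independent) for f in seg.flags] == [
            (True, True),
            (True, True),
        ]
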