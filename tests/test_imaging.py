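import numpy as np
import pytest
from hypothesis import given, strategies as st

from mechanotf.imaging import (
    cytoskeleton_area_ratio,
    heterochromatin_foci,
    i80_i20,
    nuclei_metrics,
    otsu_threshold,
    peripheral_fraction,
    segment_nuclei,
    spheroid_spread_area,
)
from mechanotf.simulate import (
    ImageBenchParams,
    generate_nucleus_image,
    generate_spheroid_image,
)


def brute_force_otsu_8bit(pixels: np.ndarray) -> float:
    """Literal exhaustive search over all 255 cut points of the
    between-class-variance objective (independent oracle)."""
    pixels = pixels.astype(float)
    best_t, best_var = None, -1.0
    for t in range(255):
        lo, hi = pixels[pixels <= t], pixels[pixels > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0 = lo.size / pixels.size
        var = w0 * (1 - w0) * (lo.mean() - hi.mean()) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return float(best_t)


class TestOtsu:
    def test_two_level_image_split_exactly(self):
        vals = np.array([10] * 50 + [200] * 50)
        t = otsu_threshold(vals)
        assert 10 <= t < 200
        assert ((vals > t) == (vals == 200)).all()

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            otsu_threshold(np.full(100, 7))

    def test_matches_exhaustive_oracle_on_random_nuclei(self, rng):
        for _ in range(100):
            n = int(rng.integers(50, 400))
            mode = rng.integers(30, 100), rng.integers(120, 220)
            pixels = np.concatenate([
                rng.normal(mode[0], 15, n).clip(0, 255),
                rng.normal(mode[1], 20, n // 2).clip(0, 255),
            ]).astype(np.uint8)
            if np.unique(pixels).size < 2:
                continue
            ours = otsu_threshold(pixels)
            oracle = brute_force_otsu_8bit(pixels)
            assert ours == oracle

    def test_agrees_with_skimage_on_8bit(self, rng):
        from skimage.filters import threshold_otsu

        pixels = np.concatenate([
            rng.normal(60, 10, 500), rng.normal(180, 12, 300)
        ]).clip(0, 255).astype(np.uint8)
        ours = otsu_threshold(pixels)
        theirs = threshold_otsu(pixels, nbins=256)
        # conventions differ by at most one gray level at the cut
        assert abs(ours - theirs) <= 1


class TestI80I20:
    def test_uniform_nucleus_is_one(self):
        img = np.full((20, 20), 100.0)
        mask = np.ones((20, 20), dtype=int)
        assert i80_i20(img, mask, 1) == 1.0

    def test_linear_interpolation_convention(self):
        img = np.array([[10, 20, 30, 40, 50]], dtype=float)
        mask = np.ones((1, 5), dtype=int)
        with pytest.raises(ValueError, match="10 pixels"):
            i80_i20(img, mask, 1)
        img = np.repeat(img, 2, axis=0)  # 10 pixels, same distribution
        mask = np.ones((2, 5), dtype=int)
        assert i80_i20(img, mask, 1) == pytest.approx(42.0 / 18.0, abs=1e-9)

    @given(scale=st.floats(min_value=0.1, max_value=100.0))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(4)
        img = rng.uniform(10, 200, (16, 16))
        mask = np.ones((16, 16), dtype=int)
        base = i80_i20(img, mask, 1)
        assert i80_i20(img * scale, mask, 1) == pytest.approx(base, rel=1e-9)

    def test_times_seven_invariance(self):
        rng = np.random.default_rng(9)
        img = rng.uniform(5, 250, (20, 20))
        mask = np.ones((20, 20), dtype=int)
        assert i80_i20(img * 7, mask, 1) == pytest.approx(i80_i20(img, mask, 1),
                                                          rel=1e-12)

    def test_all_zero_nucleus_reported_missing(self):
        img = np.zeros((10, 10))
        mask = np.ones((10, 10), dtype=int)
        assert i80_i20(img, mask, 1) is None


class TestSegmentation:
    def test_recovers_disjoint_nuclei(self):
        img, truth = generate_nucleus_image(ImageBenchParams(seed=3))
        mask = segment_nuclei(img)
        gt = truth.nucleus_mask
        assert mask.max() == gt.max()
        for nid in range(1, gt.max() + 1):
            g = gt == nid
            jac = max(
                ((g & (mask == k)).sum() / (g | (mask == k)).sum())
                for k in range(1, mask.max() + 1)
            )
            assert jac >= 0.9

    def test_blank_image_empty_mask(self):
        assert segment_nuclei(np.zeros((64, 64))).max() == 0

    def test_touching_ellipses_split(self):
        # two overlapping ellipses with distinct centers
        yy, xx = np.mgrid[0:80, 0:120]
        e1 = ((yy - 40) / 18.0) ** 2 + ((xx - 45) / 20.0) ** 2 <= 1
        e2 = ((yy - 40) / 18.0) ** 2 + ((xx - 78) / 20.0) ** 2 <= 1
        img = np.where(e1 | e2, 5000.0, 100.0)
        mask = segment_nuclei(img, split_min_distance=8)
        assert mask.max() == 2


class TestFoci:
    def test_planted_focus_count_recovered(self):
        img, truth = generate_nucleus_image(ImageBenchParams(seed=3))
        for nid, expected in truth.focus_counts.items():
            _, m = heterochromatin_foci(img, truth.nucleus_mask, nid)
            assert m["focus_count"] == expected

    def test_constant_nucleus_has_no_foci(self):
        img = np.full((30, 30), 50.0)
        mask = np.zeros((30, 30), dtype=int)
        mask[5:25, 5:25] = 1
        _, m = heterochromatin_foci(img, mask, 1)
        assert m["focus_count"] == 0 and m["total_focus_area"] == 0

    def test_planted_area_within_ten_percent(self):
        img, truth = generate_nucleus_image(
            ImageBenchParams(seed=6, noise_sd=50.0)
        )
        planted = (truth.focus_mask > 0).sum()
        total = 0
        for nid in truth.focus_counts:
            _, m = heterochromatin_foci(img, truth.nucleus_mask, nid)
            total += m["total_focus_area"]
        assert total == pytest.approx(planted, rel=0.10)

    def test_focus_area_bounded_by_nucleus_area(self):
        img, truth = generate_nucleus_image(ImageBenchParams(seed=2))
        df = nuclei_metrics(img, truth.nucleus_mask)
        assert (df["total_focus_area"] <= df["nucleus_area"]).all()
        assert (df["i80_i20"] >= 1.0).all()


class TestPeripheralFraction:
    def _nucleus(self):
        yy, xx = np.mgrid[0:41, 0:41]
        return (yy - 20) ** 2 + (xx - 20) ** 2 <= 15**2

    def test_all_in_shell_is_one(self):
        nucleus = self._nucleus()
        from scipy import ndimage as ndi
        from skimage.morphology import disk

        core = ndi.binary_erosion(nucleus, disk(3))
        foci = nucleus & ~core
        assert peripheral_fraction(foci, nucleus, 3) == 1.0

    def test_all_in_core_is_zero(self):
        nucleus = self._nucleus()
        foci = np.zeros_like(nucleus)
        foci[18:23, 18:23] = True
        assert peripheral_fraction(foci, nucleus, 3) == 0.0

    def test_partition_sums_to_one(self, rng):
        nucleus = self._nucleus()
        foci = nucleus & (rng.random(nucleus.shape) < 0.2)
        pf = peripheral_fraction(foci, nucleus, 3)
        from scipy import ndimage as ndi
        from skimage.morphology import disk

        core = ndi.binary_erosion(nucleus, disk(3))
        core_frac = (foci & core).sum() / foci.sum()
        assert pf + core_frac == pytest.approx(1.0, abs=1e-12)

    def test_shell_wider_than_nucleus_gives_one(self):
        nucleus = np.zeros((20, 20), dtype=bool)
        nucleus[8:12, 8:12] = True
        foci = nucleus.copy()
        assert peripheral_fraction(foci, nucleus, 10) == 1.0

    def test_monotone_in_planted_bias(self):
        def mean_pf(bias, seed):
            img, truth = generate_nucleus_image(
                ImageBenchParams(seed=seed, peripheral_bias=bias)
            )
            vals = []
            for nid in range(1, truth.nucleus_mask.max() + 1):
                fm, _ = heterochromatin_foci(img, truth.nucleus_mask, nid)
                pf = peripheral_fraction(fm, truth.nucleus_mask == nid, 3)
                if not np.isnan(pf):
                    vals.append(pf)
            return np.mean(vals)

        assert mean_pf(0.9, 5) > mean_pf(0.1, 5)


class TestSpheroid:
    def test_disc_area_within_five_percent(self):
        dapi, _, _ = generate_spheroid_image(
            ImageBenchParams(seed=11, core_radius=50, migration_radius=50, n_cells=0)
        )
        m = spheroid_spread_area(dapi)
        assert m.spread_area == pytest.approx(np.pi * 50**2, rel=0.05)

    def test_spread_increases_with_migration_radius(self):
        areas = []
        for r in (60, 90, 120):
            dapi, _, _ = generate_spheroid_image(
                ImageBenchParams(seed=11, migration_radius=r)
            )
            areas.append(spheroid_spread_area(dapi).spread_area)
        assert areas[0] < areas[1] < areas[2]

    def test_spread_at_least_core(self):
        dapi, _, _ = generate_spheroid_image(ImageBenchParams(seed=4))
        m = spheroid_spread_area(dapi)
        assert m.spread_area >= m.core_area > 0

    def test_blank_image_rejected(self):
        with pytest.raises(ValueError, match="blank"):
            spheroid_spread_area(np.zeros((64, 64)))

    def test_pixel_size_conversion(self):
        dapi, _, _ = generate_spheroid_image(
            ImageBenchParams(seed=11, core_radius=40, migration_radius=40, n_cells=0)
        )
        px = spheroid_spread_area(dapi)
        um = spheroid_spread_area(dapi, pixel_size=0.5)
        assert um.units == "um^2"
        assert um.spread_area == pytest.approx(px.spread_area * 0.25)


class TestCytoskeletonRatio:
    def _core(self, shape, radius=50):
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        c = shape[0] // 2
        return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2

    def test_actin_confined_to_core_is_zero(self):
        core = self._core((201, 201))
        actin = np.where(core, 4000.0, 100.0)
        assert cytoskeleton_area_ratio(actin, core) == 0.0

    def test_planted_ring_ratio(self):
        core = self._core((301, 301), 50)
        ring = self._core((301, 301), 70) & ~self._core((301, 301), 60)
        actin = np.where(core | ring, 4000.0, 100.0)
        expected = ring.sum() / core.sum()
        assert cytoskeleton_area_ratio(actin, core) == pytest.approx(expected, rel=0.10)

    def test_invariant_to_intensity_rescaling(self):
        _, actin, _ = generate_spheroid_image(ImageBenchParams(seed=8))
        core = self._core(actin.shape, 50)
        assert cytoskeleton_area_ratio(actin * 3.5, core) == pytest.approx(
            cytoskeleton_area_ratio(actin, core)
        )

    def test_zero_core_rejected(self):
        with pytest.raises(ValueError, match="core"):
            cytoskeleton_area_ratio(np.ones((10, 10)), np.zeros((10, 10), dtype=bool))
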