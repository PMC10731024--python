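import numpy as np
import pytest

from spheroquant import invasion, synth
from spheroquant.invasion import (
    count_protrusions_proxy,
    detect_filopodia,
    filopodia_summary,
    invasion_area,
    relative_invasion,
)


def disk_image(radius_px, size, value=200.0):
    yy, xx = np.mgrid[0:size, 0:size]
    c = size / 2
    img = np.zeros((size, size))
    img[(xx - c) ** 2 + (yy - c) ** 2 <= radius_px**2] = value
    return img


class TestInvasionArea:
    def test_disk_area_within_one_percent(self):
        img = disk_image(200, 512)
        m = invasion_area(img, "fixed", 100.0, pixel_size_um=1.0)
        assert m.area_um2 == pytest.approx(np.pi * 200**2, rel=0.01)

    def test_size_filter_at_printed_bound(self):
        img = np.zeros((400, 700))
        img[10:170, 10:170] = 200.0  # 160² = 25,600 µm²
        img[200:300, 200:300] = 200.0  # 100² = 10,000 µm²
        m = invasion_area(img, "fixed", 100.0, min_area_um2=20000, pixel_size_um=1.0)
        assert m.area_um2 == pytest.approx(160 * 160)
        assert m.n_components == 1

    def test_all_retained_components_above_bound(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 255, (300, 300))
        img[50:250, 50:250] += 300
        m = invasion_area(img, "otsu", pixel_size_um=1.0)
        from skimage import measure

        for region in measure.regionprops(measure.label(m.mask, connectivity=2)):
            assert region.area >= 20000

    def test_blank_image_warns_zero(self):
        with pytest.warns(UserWarning):
            m = invasion_area(np.zeros((64, 64)), "fixed", 10.0, pixel_size_um=1.0)
        assert m.area_um2 == 0.0

    def test_scale_consistency(self):
        """The same physical disk sampled twice as finely: area within 2%."""
        a1 = invasion_area(disk_image(100, 256), "fixed", 100.0, pixel_size_um=1.0)
        a2 = invasion_area(disk_image(200, 512), "fixed", 100.0, pixel_size_um=0.5)
        assert a2.area_um2 == pytest.approx(a1.area_um2, rel=0.02)


class TestRelativeInvasion:
    def test_constant_series_is_one(self):
        s = relative_invasion([1000.0, 1000.0, 1000.0])
        np.testing.assert_array_equal(s.relative, 1.0)

    def test_radius_doubling_quadruples(self):
        m0 = invasion_area(disk_image(100, 512), "fixed", 100.0, pixel_size_um=1.0)
        m1 = invasion_area(disk_image(200, 512), "fixed", 100.0, pixel_size_um=1.0)
        s = relative_invasion([m0, m1])
        assert s.relative[1] == pytest.approx(4.0, rel=0.01)

    def test_generator_growth_matches_analytic(self):
        series, gt = synth.gen_spheroid_series(
            radius_um=90, growth_per_day=0.3, n_timepoints=4, seed=2
        )
        ms = [invasion_area(s["image"], "fixed", 100.0, pixel_size_um=1.0) for s in series]
        rel = relative_invasion(ms).relative
        np.testing.assert_allclose(rel, gt.params["relative_area"], rtol=0.02)

    def test_zero_initial_area_rejected(self):
        with pytest.raises(ValueError):
            relative_invasion([0.0, 10.0])


class TestProtrusionProxy:
    def test_smooth_disk_zero(self):
        mask = disk_image(120, 400) > 0
        assert count_protrusions_proxy(mask, cell_area_um2=200, opening_radius_um=40) == 0

    def test_four_lobes_counted(self):
        angles = np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
        series, _ = synth.gen_spheroid_series(
            radius_um=120, n_lobes=4, lobe_cells=4.0, cell_area_um2=200.0,
            n_timepoints=1, lobe_angles=angles, seed=0,
        )
        n = count_protrusions_proxy(
            series[0]["mask"], cell_area_um2=200.0, min_cells=3, opening_radius_um=40
        )
        assert n == 4

    def test_small_lobes_below_cell_rule(self):
        angles = np.array([0.0, np.pi])
        series, _ = synth.gen_spheroid_series(
            radius_um=120, n_lobes=2, lobe_cells=2.0, cell_area_um2=200.0,
            n_timepoints=1, lobe_angles=angles, seed=0,
        )
        n = count_protrusions_proxy(
            series[0]["mask"], cell_area_um2=200.0, min_cells=3, opening_radius_um=40
        )
        assert n == 0

    def test_proxy_matches_lobe_count_over_seeds(self):
        for seed in range(5):
            angles = np.linspace(0, 2 * np.pi, 3, endpoint=False) + 0.1 * seed
            series, _ = synth.gen_spheroid_series(
                radius_um=120, n_lobes=3, lobe_cells=5.0, cell_area_um2=200.0,
                n_timepoints=1, lobe_angles=angles, seed=seed,
            )
            n = count_protrusions_proxy(
                series[0]["mask"], cell_area_um2=200.0, min_cells=3, opening_radius_um=40
            )
            assert n == 3

    def test_excessive_opening_radius(self):
        mask = disk_image(20, 128) > 0
        with pytest.raises(ValueError):
            count_protrusions_proxy(mask, 200.0, opening_radius_um=60)


class TestFilopodia:
    @staticmethod
    def spur_series(n=5, length=10.0, ps=0.5, radius=40.0):
        angles = np.linspace(0, 2 * np.pi, n, endpoint=False) + 0.2
        series, _ = synth.gen_spheroid_series(
            radius_um=radius, n_filopodia=n, filopodia_len_um=length,
            n_timepoints=1, image_um=160, pixel_size_um=ps,
            filopodia_angles=angles, seed=0,
        )
        return series[0]["image"]

    def test_five_spurs_detected_with_length(self):
        img = self.spur_series(n=5, length=10.0, ps=0.5)
        fset = detect_filopodia(img, body_threshold=100, skeleton_min_length_um=2,
                                pixel_size_um=0.5)
        assert fset.count == 5
        assert np.allclose(fset.lengths_um, 10.0, atol=1.5)

    def test_min_length_filter(self):
        img = self.spur_series(n=4, length=1.0, ps=0.5)
        fset = detect_filopodia(img, body_threshold=100, skeleton_min_length_um=2,
                                pixel_size_um=0.5)
        assert fset.count == 0

    def test_no_structures_outside_body(self):
        img = disk_image(60, 256)
        fset = detect_filopodia(img, body_threshold=100, pixel_size_um=1.0)
        assert fset.count == 0
        density, mean_len = filopodia_summary(fset)
        assert density == 0.0 and np.isnan(mean_len)

    def test_empty_body_raises(self):
        with pytest.raises(ValueError):
            detect_filopodia(np.zeros((64, 64)), body_threshold=10)

    def test_summary_arithmetic(self):
        fset = invasion.FilopodiaSet(lengths_um=[8.0, 10.0, 12.0], boundary_length_um=100.0)
        density, mean_len = filopodia_summary(fset)
        assert density == pytest.approx(0.03)
        assert mean_len == pytest.approx(10.0)

    def test_density_matches_generator(self):
        img = self.spur_series(n=6, length=8.0, ps=0.5, radius=40.0)
        fset = detect_filopodia(img, body_threshold=100, skeleton_min_length_um=2,
                                pixel_size_um=0.5)
        density, _ = filopodia_summary(fset)
        expected = 6 / (2 * np.pi * 40.0)
        assert density == pytest.approx(expected, rel=0.25)
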