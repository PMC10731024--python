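import numpy as np
import pytest
from scipy import special

from spheroquant import synth
from spheroquant.synth import (
    expected_axial_order,
    gen_fiber_field,
    gen_flow_pair,
    gen_force_curve,
    gen_junction_image,
    gen_nc_cells,
    gen_nuclei,
    gen_orientation_field,
    gen_spheroid_series,
    hertz_force_nN,
    sample_axial_angles,
)


class TestDeterminism:
    """Identical (parameters, seed) must reproduce outputs bit-exactly."""

    def test_fiber_field(self):
        a, _ = gen_fiber_field(2.0, n_fibers=50, image_px=64, seed=7)
        b, _ = gen_fiber_field(2.0, n_fibers=50, image_px=64, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_flow_pair(self):
        (a1, b1), _ = gen_flow_pair((1, 0), noise_sd=2.0, image_px=64, seed=7)
        (a2, b2), _ = gen_flow_pair((1, 0), noise_sd=2.0, image_px=64, seed=7)
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(b1, b2)

    def test_force_curve(self):
        c1, _ = gen_force_curve(400, noise_sd=0.02, seed=9)
        c2, _ = gen_force_curve(400, noise_sd=0.02, seed=9)
        np.testing.assert_array_equal(c1.force_nN, c2.force_nN)

    def test_different_seeds_differ(self):
        a, _ = gen_fiber_field(2.0, n_fibers=50, image_px=64, seed=1)
        b, _ = gen_fiber_field(2.0, n_fibers=50, image_px=64, seed=2)
        assert not np.array_equal(a, b)


class TestFiberField:
    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            gen_fiber_field(-1.0)

    def test_expected_order_limits(self):
        assert expected_axial_order(np.inf) == 1.0
        assert expected_axial_order(0.0) == 0.0

    def test_expected_order_monte_carlo_oracle(self):
        """E[cos 2Δθ] over 10⁶ axial von Mises draws matches I₁(κ)/I₀(κ)."""
        rng = np.random.default_rng(42)
        kappa = 2.0
        theta = sample_axial_angles(kappa, 0.3, 1_000_000, rng)
        mc = np.mean(np.cos(2.0 * (theta - 0.3)))
        closed = special.i1(kappa) / special.i0(kappa)
        assert mc == pytest.approx(closed, abs=3e-3)
        assert expected_axial_order(kappa) == pytest.approx(closed, rel=1e-12)

    def test_parallel_fibers_all_same_angle(self):
        _, gt = gen_fiber_field(np.inf, mean_angle=0.8, n_fibers=20, image_px=64, seed=0)
        assert np.allclose(gt.params["angles"], 0.8)
        assert gt.params["expected_order"] == 1.0


class TestFlowPair:
    def test_zero_displacement_identical_frames(self):
        (a, b), _ = gen_flow_pair((0.0, 0.0), noise_sd=0.0, image_px=64, seed=0)
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_integer_shift_matches_roll_oracle(self):
        ps = 0.16
        (a, b), _ = gen_flow_pair((3 * ps, 0.0), noise_sd=0.0, image_px=64,
                                  pixel_size_um=ps, seed=1)
        rolled = np.roll(a, 3, axis=1)
        # compare away from the boundary the roll wraps through
        np.testing.assert_allclose(b[:, 8:], rolled[:, 8:], atol=1e-6)

    def test_dense_field_shape_validation(self):
        with pytest.raises(ValueError):
            gen_flow_pair(np.zeros((4, 4, 3)), image_px=8)


class TestNcCells:
    def test_invalid_ratio(self):
        with pytest.raises(ValueError):
            gen_nc_cells(0.0)

    def test_noiseless_intensities_exact(self):
        stack, samples, gt = gen_nc_cells(2.0, background=50, noise_sd=0, n_cells=3, seed=0)
        sig = stack.plane(0)
        for s in samples:
            nuc = s.nuclear_roi.mean_intensity(sig)
            cyts = [r.mean_intensity(sig) for r in s.cytoplasm_rois]
            assert nuc == pytest.approx(50 + 2.0 * 100)
            assert cyts == pytest.approx([150, 150])

    def test_dapi_channel_marks_nuclei_only(self):
        stack, samples, _ = gen_nc_cells(1.5, n_cells=2, seed=0)
        dapi = stack.plane(1)
        for s in samples:
            assert s.nuclear_roi.mean_intensity(dapi) > 0
            for r in s.cytoplasm_rois:
                assert r.mean_intensity(dapi) == 0.0


class TestNuclei:
    def test_hexagonal_nearest_neighbor_spacing(self):
        _, cents, _ = gen_nuclei("hexagonal", spacing_um=10, region_um=80, seed=0)
        # interior point: nearest neighbor at exactly the lattice spacing
        interior = cents[
            (cents[:, 0] > 15) & (cents[:, 0] < 65) & (cents[:, 1] > 15) & (cents[:, 1] < 65)
        ]
        d = np.linalg.norm(cents[None, :, :] - interior[:, None, :], axis=2)
        d[d == 0] = np.inf
        assert np.allclose(d.min(axis=1), 10.0, atol=1e-9)

    def test_poisson_count_within_error(self):
        counts = []
        for seed in range(20):
            _, cents, _ = gen_nuclei("poisson", density_per_um2=0.01, region_um=100, seed=seed)
            counts.append(len(cents))
        lam = 0.01 * 100**2  # = 100 expected
        # mean of 20 Poisson(100) draws: SE = sqrt(100/20) ≈ 2.2
        assert abs(np.mean(counts) - lam) < 4 * np.sqrt(lam / 20)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            gen_nuclei("grid")


class TestSpheroidSeries:
    def test_static_relative_area_is_one(self):
        series, gt = gen_spheroid_series(growth_per_day=0.0, n_lobes=0, n_timepoints=4, seed=0)
        assert gt.params["relative_area"] == [1.0, 1.0, 1.0, 1.0]
        areas = [s["mask"].sum() for s in series]
        assert len(set(areas)) == 1

    def test_radius_doubling_quadruples_area(self):
        series, gt = gen_spheroid_series(
            radius_um=60, growth_per_day=1.0, n_timepoints=2, image_um=400, seed=0
        )
        assert gt.params["relative_area"][1] == pytest.approx(4.0)
        ratio = series[1]["mask"].sum() / series[0]["mask"].sum()
        assert ratio == pytest.approx(4.0, rel=0.02)


class TestForceCurve:
    def test_hertz_closed_form_constant(self):
        """F/δ^{3/2} is the constant (4/3)·E/(1−ν²)·√R on a noiseless curve."""
        curve, gt = gen_force_curve(1000.0, noise_sd=0.0, seed=0)
        k = curve.spring_constant_N_per_m
        contact = gt.params["contact_z_nm"]
        post = curve.z_nm > contact
        delta_nm = (curve.z_nm[post] - contact) - curve.force_nN[post] / k
        f_n = curve.force_nN[post] * 1e-9
        d_m = delta_nm * 1e-9
        good = d_m > 1e-8
        ratio = f_n[good] / d_m[good] ** 1.5
        expected = (4.0 / 3.0) * (1000.0 / (1 - 0.25)) * np.sqrt(5e-6)
        np.testing.assert_allclose(ratio, expected, rtol=1e-9)

    def test_single_point_unit_audit(self):
        # E=1000 Pa, ν=0.5, R=5 µm, δ=1000 nm -> F = 3.9752 nN by hand
        f = hertz_force_nN(1000.0, 1000.0, 5.0, 0.5)
        assert f == pytest.approx((4 / 3) * (1000 / 0.75) * np.sqrt(5e-6) * 1e-9 * 1e9)
        assert f == pytest.approx(3.9752, abs=1e-3)

    def test_z_strictly_monotone(self):
        curve, _ = gen_force_curve(200.0, noise_sd=0.0, seed=0)
        assert np.all(np.diff(curve.z_nm) > 0)


class TestJunctionImage:
    def test_profile_closed_form(self):
        img, _, gt = gen_junction_image(peak_amplitude=80, peak_width_um=0.5, background=20)
        row = img[0]
        x_um = np.arange(img.shape[1]) * gt.params["pixel_size_um"]
        expected = 20 + 80 * np.exp(-((x_um - gt.params["ridge_x_um"]) ** 2) / (2 * 0.5**2))
        np.testing.assert_allclose(row, expected, rtol=1e-12)

    def test_fwhm_identity(self):
        _, _, gt = gen_junction_image(peak_width_um=0.7)
        assert gt.params["fwhm_um"] == pytest.approx(2.3548 * 0.7, abs=1e-3)


class TestOrientationFieldGenerator:
    def test_infinite_kappa_constant_field(self):
        fld, _ = gen_orientation_field(np.inf, mean_angle=1.1, shape=(6, 6), seed=0)
        assert np.allclose(fld.angles, 1.1)

    def test_ground_truth_json_round_trip(self, tmp_path):
        _, gt = gen_orientation_field(2.0, shape=(4, 4), seed=3)
        p = tmp_path / "gt.json"
        gt.to_json(p)
        import json

        data = json.loads(p.read_text())
        assert data["generator"] == "gen_orientation_field"
        assert data["seed"] == 3
        assert data["params"]["expected_order"] == pytest.approx(
            float(special.i1(2.0) / special.i0(2.0))
        )
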