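import numpy as np
import pytest

from spheroquant import aft, synth
from spheroquant.aft import OrientationField, compute_orientation_field, order_parameter, radial_alignment


def stripes(angle_rad, size=128, period=8):
    """Sinusoidal stripe pattern whose ridges run along ``angle_rad``."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    # intensity varies along the normal to the stripe direction
    phase = -np.sin(angle_rad) * yy + np.cos(angle_rad) * xx
    # careful: ridges along angle means variation along the perpendicular
    perp = xx * np.sin(angle_rad) - yy * np.cos(angle_rad)
    return 100.0 * (1.0 + np.sin(2 * np.pi * perp / period))


def axial_diff(a, b):
    """Smallest angular difference between two axial angles (mod π)."""
    d = (a - b) % np.pi
    return np.minimum(d, np.pi - d)


def make_field(angles, valid=None, window_px=25, overlap=0.5):
    angles = np.asarray(angles, dtype=float)
    ny, nx = angles.shape
    step = int(round(window_px * (1 - overlap)))
    xs = window_px / 2 + step * np.arange(nx)
    ys = window_px / 2 + step * np.arange(ny)
    cx, cy = np.meshgrid(xs, ys)
    if valid is None:
        valid = np.ones_like(angles, dtype=bool)
    return OrientationField(angles, cx, cy, window_px, overlap, valid)


class TestOrientationField:
    @pytest.mark.parametrize("angle", [0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4])
    def test_stripe_orientation_recovered(self, angle):
        field = compute_orientation_field(stripes(angle), window_px=25, overlap=0.5)
        err = axial_diff(field.angles[field.valid], angle)
        assert np.median(err) < 0.02

    def test_image_smaller_than_window(self):
        with pytest.raises(ValueError):
            compute_orientation_field(np.zeros((10, 10)), window_px=25)

    def test_blank_image_all_invalid(self):
        field = compute_orientation_field(np.zeros((64, 64)), window_px=25)
        assert not field.valid.any()

    def test_generator_ground_truth_correlation(self):
        """Window angles track the circular mean of fiber segments per window."""
        img, gt = synth.gen_fiber_field(8.0, mean_angle=0.5, seed=3)
        field = compute_orientation_field(img)
        segs = gt.params["segments"]  # (x, y, theta)
        half = field.window_px / 2
        meas, truth = [], []
        for i in range(field.shape[0]):
            for j in range(field.shape[1]):
                if not field.valid[i, j]:
                    continue
                cx, cy = field.centers_x[i, j], field.centers_y[i, j]
                inside = (np.abs(segs[:, 0] - cx) < half) & (np.abs(segs[:, 1] - cy) < half)
                if inside.sum() < 1:
                    continue
                th = segs[inside, 2]
                circ_mean = 0.5 * np.arctan2(np.sin(2 * th).mean(), np.cos(2 * th).mean())
                meas.append(field.angles[i, j])
                truth.append(circ_mean % np.pi)
        meas, truth = np.array(meas), np.array(truth)
        # axial circular correlation: alignment of doubled-angle unit vectors
        corr = np.mean(np.cos(2 * (meas - truth)))
        assert corr > 0.9

    def test_rotation_equivariance(self):
        """Rotating the image 90° shifts every angle by π/2 and preserves S."""
        img, _ = synth.gen_fiber_field(4.0, mean_angle=0.4, image_px=256, n_fibers=250, seed=5)
        f0 = compute_orientation_field(img)
        f90 = compute_orientation_field(np.rot90(img))
        s0 = order_parameter(f0).S_summary
        s90 = order_parameter(f90).S_summary
        assert s90 == pytest.approx(s0, abs=0.05)
        a0 = np.sort(f0.angles[f0.valid])
        a90 = np.sort((f90.angles[f90.valid] + np.pi / 2) % np.pi)
        # compare angle distributions after the 90° shift
        n = min(len(a0), len(a90))
        q0 = np.quantile(a0, np.linspace(0.1, 0.9, 9))
        q90 = np.quantile(a90, np.linspace(0.1, 0.9, 9))
        assert np.median(axial_diff(q0, q90)) < 0.05


class TestOrderParameter:
    def test_uniform_angles_give_unity(self):
        field = make_field(np.full((8, 8), 0.7))
        res = order_parameter(field)
        assert res.S_summary == pytest.approx(1.0)
        assert np.nanmin(res.S_map) == pytest.approx(1.0)

    def test_iid_uniform_mean_zero(self):
        """E[cos 2θ_ij] = 0 for i.i.d. uniform axial angles."""
        vals = []
        for seed in range(200):
            fld, _ = synth.gen_orientation_field(0.0, shape=(10, 10), seed=seed)
            vals.append(order_parameter(fld).S_summary)
        assert abs(np.mean(vals)) < 0.02

    def test_checkerboard_brute_force_oracle(self):
        """Hand-enumerated S over the 24 neighbors of each window."""
        angles = np.zeros((6, 6))
        angles[(np.indices((6, 6)).sum(axis=0) % 2) == 1] = np.pi / 2
        field = make_field(angles)
        res = order_parameter(field, neighborhood=5)
        # independent brute force with explicit python loops
        for i in range(6):
            for j in range(6):
                if 2 <= i <= 3 and 2 <= j <= 3:
                    vals = []
                    for di in range(-2, 3):
                        for dj in range(-2, 3):
                            if di == 0 and dj == 0:
                                continue
                            vals.append(
                                np.cos(2 * (angles[i, j] - angles[i + di, j + dj]))
                            )
                    assert res.S_map[i, j] == pytest.approx(np.mean(vals))
                else:
                    assert np.isnan(res.S_map[i, j])

    def test_invalid_member_excludes_neighborhood(self):
        valid = np.ones((5, 5), dtype=bool)
        valid[0, 0] = False
        field = make_field(np.zeros((5, 5)), valid=valid)
        res = order_parameter(field, neighborhood=5)
        assert res.n_defined == 0 and np.isnan(res.S_summary)

    def test_too_small_grid_returns_empty(self):
        field = make_field(np.zeros((3, 3)))
        res = order_parameter(field, neighborhood=5)
        assert res.n_defined == 0 and np.isnan(res.S_summary)

    def test_even_neighborhood_rejected(self):
        field = make_field(np.zeros((6, 6)))
        with pytest.raises(ValueError):
            order_parameter(field, neighborhood=4)

    def test_monotone_in_concentration(self):
        """Median S strictly increases with angular concentration κ."""
        medians = []
        for kappa in (0.0, 1.0, 2.0, 4.0, 8.0):
            img, _ = synth.gen_fiber_field(kappa, mean_angle=0.3, seed=11)
            field = compute_orientation_field(img)
            medians.append(order_parameter(field).S_summary)
        assert all(b > a for a, b in zip(medians, medians[1:]))


class TestRadialAlignment:
    @staticmethod
    def _radial_field(tangential=False, n=12):
        window, step = 25, 12
        xs = window / 2 + step * np.arange(n)
        cx, cy = np.meshgrid(xs, xs)
        center = (xs.mean(), xs.mean())
        ang = np.arctan2(cy - center[1], cx - center[0]) % np.pi
        if tangential:
            ang = (ang + np.pi / 2) % np.pi
        return (
            OrientationField(ang, cx, cy, window, 0.5, np.ones_like(ang, dtype=bool)),
            center,
        )

    def test_spokes_are_radial(self):
        field, center = self._radial_field(tangential=False)
        sectors = radial_alignment(field, center)
        assert np.all(sectors > 0.95)

    def test_rings_are_tangential(self):
        field, center = self._radial_field(tangential=True)
        sectors = radial_alignment(field, center)
        assert np.all(sectors < -0.95)

    def test_uniform_random_sectors_near_zero(self):
        acc = []
        for seed in range(100):
            fld, _ = synth.gen_orientation_field(0.0, shape=(12, 12), seed=1000 + seed)
            acc.append(radial_alignment(fld, (80.0, 80.0), n_sectors=4))
        means = np.nanmean(np.array(acc), axis=0)
        assert np.all(np.abs(means) < 0.05)

    def test_empty_sector_flagged_missing(self):
        field = make_field(np.zeros((4, 4)))
        # center far to the left: all windows lie in sectors near 0
        sectors = radial_alignment(field, (-1000.0, field.centers_y.mean()), n_sectors=8)
        assert np.isnan(sectors).sum() >= 4
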