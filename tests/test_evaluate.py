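import numpy as np
import pytest

from irai import (
    DoseVolume,
    dvh,
    dvh_rmse,
    gamma_index,
    isodose_contour,
    line_profile,
    region_mean_amplitude,
    ssim,
)
from irai.grids import VolumeGrid
from irai.recon import ReconVolume


def volume_on_grid(values, spacing=4e-3):
    values = np.asarray(values, float)
    grid = VolumeGrid(
        extent=tuple(s * spacing for s in values.shape),
        spacing=(spacing,) * 3,
        origin=(0.0, 0.0, 0.01),
    )
    return DoseVolume(dose=values, grid=grid)


class TestDVH:
    def test_uniform_volume_is_step_function(self):
        curve = dvh(np.full((4, 4, 4), 2.0), n_bins=11)
        assert np.all(curve.volume_fraction == 100.0)  # all bins <= max are covered
        assert curve.dose_bins[-1] == pytest.approx(2.0)

    def test_linear_ramp_closed_form(self):
        # N equally likely values 0..Dmax: fraction >= d is (1 - d/Dmax)
        n = 1001
        dmax = 5.0
        vals = np.linspace(0.0, dmax, n)
        curve = dvh(vals.reshape(7, 11, 13), n_bins=101)
        expected = (1.0 - curve.dose_bins / dmax) * 100.0
        # discrete >= makes each bin's count ceil-like; tolerance one voxel
        assert np.allclose(curve.volume_fraction, expected, atol=100.0 / n + 1e-9)

    def test_monotone_non_increasing(self, rng):
        curve = dvh(rng.uniform(0, 3, (9, 9, 9)))
        assert np.all(np.diff(curve.volume_fraction) <= 1e-12)
        assert curve.volume_fraction[0] == 100.0

    def test_empty_volume_rejected(self):
        with pytest.raises(ValueError):
            dvh(np.array([]))


class TestDVHRMSE:
    def test_identical_curves_zero(self, rng):
        c = dvh(rng.uniform(0, 1, (6, 6, 6)))
        assert dvh_rmse(c, c) == 0.0

    def test_constant_offset_recovers_delta(self):
        c1 = dvh(np.linspace(0, 1, 1000).reshape(10, 10, 10))
        c2 = type(c1)(dose_bins=c1.dose_bins,
                      volume_fraction=np.clip(c1.volume_fraction - 7.0, 0, 100))
        # clip only affects the tail; restrict to interior by construction
        inner = type(c1)(dose_bins=c1.dose_bins[:90],
                         volume_fraction=c1.volume_fraction[:90])
        shifted = type(c1)(dose_bins=c1.dose_bins[:90],
                           volume_fraction=c1.volume_fraction[:90] - 7.0)
        assert dvh_rmse(inner, shifted) == pytest.approx(7.0)

    def test_matches_direct_formula(self, rng):
        a = dvh(rng.uniform(0, 2, (8, 8, 8)))
        b = dvh(rng.uniform(0, 2, (8, 8, 8)))
        fb = np.interp(a.dose_bins, b.dose_bins, b.volume_fraction)
        expected = np.sqrt(np.mean((a.volume_fraction - fb) ** 2))
        with pytest.warns(UserWarning):
            got = dvh_rmse(a, b)
        assert got == pytest.approx(expected)


def brute_force_gamma(ref, ev, spacing, dd_abs, dta, radius_factor=3.0, sub=3):
    """Independent exhaustive gamma search with its own trilinear sampler."""

    def trilinear(vol, x):
        x = np.clip(x, 0, np.array(vol.shape) - 1.0)
        i = np.floor(x).astype(int)
        i = np.minimum(i, np.array(vol.shape) - 2)
        f = x - i
        out = 0.0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = ((1 - f[0]) if dx == 0 else f[0]) * \
                        ((1 - f[1]) if dy == 0 else f[1]) * \
                        ((1 - f[2]) if dz == 0 else f[2])
                    out += w * vol[i[0] + dx, i[1] + dy, i[2] + dz]
        return out

    step = dta / sub
    n = int(np.floor(radius_factor * dta / step))
    offs = []
    for ox in range(-n, n + 1):
        for oy in range(-n, n + 1):
            for oz in range(-n, n + 1):
                off = np.array([ox, oy, oz]) * step
                if np.dot(off, off) <= (radius_factor * dta) ** 2 + 1e-12:
                    offs.append(off)
    gamma = np.empty(ref.shape)
    for idx in np.ndindex(ref.shape):
        best = np.inf
        for off in offs:
            pos = np.array(idx, float) + off / spacing
            if np.any(pos < 0) or np.any(pos > np.array(ref.shape) - 1):
                continue
            val = trilinear(ev, pos)
            g2 = (val - ref[idx]) ** 2 / dd_abs**2 + np.dot(off, off) / dta**2
            best = min(best, g2)
        gamma[idx] = np.sqrt(best)
    return gamma


class TestGamma:
    def test_identical_volumes_all_pass(self, rng):
        v = volume_on_grid(rng.uniform(0, 1, (6, 6, 6)))
        res = gamma_index(v, v)
        assert res.pass_rate == 100.0
        assert np.allclose(res.gamma_map, 0.0)

    def test_uniform_offset_at_dd_boundary(self):
        ref = volume_on_grid(np.full((5, 5, 5), 1.0))
        ev = volume_on_grid(np.full((5, 5, 5), 1.05))
        res = gamma_index(ref, ev, dd_percent=5.0, dta_mm=5.0)
        # displacement cannot reduce the dose term in a uniform field
        assert np.allclose(res.gamma_map, 1.0, atol=1e-9)
        assert res.pass_rate == 100.0

    def test_matches_brute_force_oracle(self, rng):
        ref_vals = rng.uniform(0, 1, (4, 4, 4))
        ev_vals = np.clip(ref_vals + rng.normal(0, 0.1, ref_vals.shape), 0, None)
        ref = volume_on_grid(ref_vals)
        ev = volume_on_grid(ev_vals)
        res = gamma_index(ref, ev, dd_percent=5.0, dta_mm=5.0,
                          low_dose_threshold=0.0)
        oracle = brute_force_gamma(ref_vals, ev_vals,
                                   np.array(ref.grid.spacing),
                                   0.05 * ref_vals.max(), 5e-3)
        assert np.allclose(res.gamma_map, oracle, rtol=1e-9, atol=1e-9)

    def test_invariant_under_joint_global_scale(self, rng):
        a = rng.uniform(0, 1, (5, 5, 5))
        b = np.clip(a + rng.normal(0, 0.05, a.shape), 0, None)
        r1 = gamma_index(volume_on_grid(a), volume_on_grid(b))
        r2 = gamma_index(volume_on_grid(3 * a), volume_on_grid(3 * b))
        assert r1.pass_rate == pytest.approx(r2.pass_rate)
        assert np.allclose(r1.gamma_map, r2.gamma_map, atol=1e-9)

    def test_spacing_coarser_than_dta_rejected(self, rng):
        v = volume_on_grid(rng.uniform(0, 1, (4, 4, 4)), spacing=8e-3)
        with pytest.raises(ValueError, match="spacing"):
            gamma_index(v, v, dta_mm=5.0)


class TestSSIM:
    def test_identical_images(self, rng):
        a = rng.uniform(0, 1, (16, 16))
        assert ssim(a, a) == pytest.approx(1.0)

    def test_constant_offset_lowers_luminance_term(self, rng):
        a = rng.uniform(0, 1, (32, 32))
        b = a + 0.3
        s = ssim(a, b, data_range=1.3)
        mu_a, mu_b = a.mean(), b.mean()
        c1 = (0.01 * 1.3) ** 2
        lum = (2 * mu_a * mu_b + c1) / (mu_a**2 + mu_b**2 + c1)
        assert s < 1.0
        assert s <= lum + 0.05

    def test_single_window_matches_direct_formula(self):
        # uniform-covariance SSIM over one full window
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 1, (5, 5))
        b = rng.uniform(0, 1, (5, 5))
        from skimage.metrics import structural_similarity

        got = structural_similarity(a, b, win_size=5, data_range=1.0,
                                    gaussian_weights=False)
        mu_a, mu_b = a.mean(), b.mean()
        va, vb = a.var(ddof=1), b.var(ddof=1)
        cov = ((a - mu_a) * (b - mu_b)).sum() / (a.size - 1)
        c1, c2 = 0.01**2, 0.03**2
        direct = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
            (mu_a**2 + mu_b**2 + c1) * (va + vb + c2))
        assert got == pytest.approx(direct, rel=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ssim(np.zeros((4, 4)), np.zeros((5, 5)))


class TestIsodose:
    def test_disc_boundary_recovered(self):
        yy, xx = np.mgrid[:64, :64]
        img = ((xx - 32) ** 2 + (yy - 32) ** 2 <= 20**2).astype(float)
        contour = isodose_contour(img, 0.8)
        assert contour.polylines
        pts = np.vstack(contour.polylines)
        r = np.hypot(pts[:, 0] - 32, pts[:, 1] - 32)
        assert np.all(np.abs(r - 20) <= 1.0)

    def test_nested_levels(self):
        yy, xx = np.mgrid[:64, :64]
        img = np.exp(-((xx - 32) ** 2 + (yy - 32) ** 2) / (2 * 8.0**2))
        r8 = np.vstack(isodose_contour(img, 0.8).polylines)
        r9 = np.vstack(isodose_contour(img, 0.9).polylines)
        rad8 = np.hypot(r8[:, 0] - 32, r8[:, 1] - 32).mean()
        rad9 = np.hypot(r9[:, 0] - 32, r9[:, 1] - 32).mean()
        assert rad9 < rad8

    def test_gaussian_spot_radius_closed_form(self):
        sigma = 8.0
        yy, xx = np.mgrid[:96, :96]
        img = np.exp(-((xx - 48) ** 2 + (yy - 48) ** 2) / (2 * sigma**2))
        pts = np.vstack(isodose_contour(img, 0.8).polylines)
        r = np.hypot(pts[:, 0] - 48, pts[:, 1] - 48)
        expected = sigma * np.sqrt(2 * np.log(1 / 0.8))
        assert r.mean() == pytest.approx(expected, rel=0.02)

    def test_bad_level_rejected(self):
        with pytest.raises(ValueError):
            isodose_contour(np.ones((8, 8)), 1.2)


class TestRegionsAndProfiles:
    def test_region_mean_of_uniform_volume(self):
        v = volume_on_grid(np.ones((4, 4, 4)))
        mask = np.zeros((4, 4, 4), bool)
        mask[1:3, 1:3, 1:3] = True
        assert region_mean_amplitude(v, mask) == 1.0
        assert region_mean_amplitude(volume_on_grid(np.zeros((4, 4, 4))), mask) == 0.0

    def test_empty_mask_rejected(self):
        v = volume_on_grid(np.ones((4, 4, 4)))
        with pytest.raises(ValueError):
            region_mean_amplitude(v, np.zeros((4, 4, 4), bool))

    def test_flat_profile_of_uniform_volume(self):
        v = volume_on_grid(np.ones((5, 5, 5)))
        coords, vals = line_profile(v, 2, np.array([0.01, 0.01, 0.02]))
        assert np.allclose(vals, 1.0)
        assert coords.size == 5

    def test_profile_point_outside_rejected(self):
        v = volume_on_grid(np.ones((5, 5, 5)))
        with pytest.raises(ValueError):
            line_profile(v, 2, np.array([1.0, 0.0, 0.0]))
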