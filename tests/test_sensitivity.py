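import numpy as np
import pytest

from irai import (
    SweepPlan,
    correction_factors,
    densify_map,
    focused_field,
    lattice_positions,
    simulate_sensitivity_map,
    sweep_events,
    virtual_point_source_map,
)
from irai.array_model import ElementResponse, TransducerSpec, build_array, envelope_sigma
from irai.grids import VolumeGrid
from irai.sensitivity import (
    SensitivityMap,
    angles_from_direction,
    direction_from_angles,
)


class TestSweepEvents:
    def test_full_sweep_event_count(self):
        # half-open 0-180 degree grid at 0.5 degrees: 360 x 360 events
        plan = SweepPlan()
        assert plan.n_events == 129600
        ev = sweep_events(plan)
        assert ev.shape == (129600, 2)
        assert ev[:, 0].max() < 180.0 and ev[:, 1].max() < 180.0

    def test_ninety_degree_step_gives_four_events(self):
        ev = sweep_events(SweepPlan(step=90.0))
        assert ev.shape[0] == 4

    @pytest.mark.parametrize("step", [0.5, 1.0, 2.0, 4.5, 10.0])
    def test_single_axis_count_is_range_over_step(self, step):
        plan = SweepPlan(step=step)
        assert plan.n_azimuth == int(round(180.0 / step))

    def test_invalid_plans_rejected(self):
        with pytest.raises(ValueError):
            SweepPlan(step=-1.0)
        with pytest.raises(ValueError):
            SweepPlan(step=7.0)  # does not divide 180

    def test_direction_angle_round_trip(self):
        az, el = 72.5, 113.0
        d = direction_from_angles(az, el)
        a2, e2 = angles_from_direction(d)
        assert a2 == pytest.approx(az) and e2 == pytest.approx(el)
        assert np.linalg.norm(d) == pytest.approx(1.0)


class TestFocusedField:
    def test_single_element_spherical_spreading(self, medium):
        spec = TransducerSpec(n_elements_x=1, n_elements_y=1)
        el = build_array(spec)
        vol = VolumeGrid(extent=(1e-3, 1e-3, 0.2), spacing=(1e-3, 1e-3, 0.05),
                         origin=(-5e-4, -5e-4, 0.025))
        f = focused_field(el, spec, (90.0, 90.0), medium, vol)
        prof = f[0, 0, :]
        z = vol.axis_coords(2)
        # on-axis amplitude halves from z to 2z
        assert prof[0] / prof[2] == pytest.approx(z[2] / z[0], rel=1e-6)

    def test_broadside_symmetry(self, small_spec, small_elements, medium):
        vol = VolumeGrid(extent=(0.06, 0.06, 0.02), spacing=(0.01, 0.01, 0.02),
                         origin=(-0.03, -0.03, 0.05))
        f = focused_field(small_elements, small_spec, (90.0, 90.0), medium, vol)
        assert np.allclose(f, f[::-1, :, :], rtol=1e-9)
        assert np.allclose(f, f[:, ::-1, :], rtol=1e-9)

    def test_matches_hand_summed_superposition(self, medium, response):
        # 2x2 array, one voxel: four-term delayed-pulse sum done by hand
        spec = TransducerSpec(n_elements_x=2, n_elements_y=2)
        el = build_array(spec)
        p = np.array([0.013, -0.007, 0.09])
        vol = VolumeGrid(extent=(1e-3,) * 3, spacing=(1e-3,) * 3, origin=tuple(p - 5e-4))
        az, el_ang = 80.0, 100.0
        got = focused_field(el, spec, (az, el_ang), medium, vol, time_search="focal")[0, 0, 0]

        c = medium.sound_speed
        omega = 2 * np.pi * spec.center_frequency
        sig = envelope_sigma(spec)
        lam = c / spec.center_frequency
        d_hat = direction_from_angles(az, el_ang)
        focal = np.linalg.norm(p) * d_hat
        acc = 0.0 + 0.0j
        for e in el.positions:
            if np.hypot(p[0] - e[0], p[1] - e[1]) > p[2] / 2.4:
                continue  # outside the F = 1.2 receive aperture
            r_ev = np.linalg.norm(p - e)
            r_ep = np.linalg.norm(focal - e)
            arg = np.pi * spec.element_size / lam
            d = np.sinc(arg * (p - e)[0] / r_ev / np.pi) * np.sinc(
                arg * (p - e)[1] / r_ev / np.pi
            )
            delta = (r_ev - r_ep) / c
            acc += (d / r_ev) * np.exp(-(delta**2) / (2 * sig**2)) * np.exp(
                -1j * omega * delta
            )
        assert got == pytest.approx(abs(acc), rel=1e-9)

    def test_dense_time_search_dominates_focal(self, small_spec, small_elements, medium, coarse_volume):
        dense = focused_field(small_elements, small_spec, (70.0, 90.0), medium,
                              coarse_volume, time_search="dense")
        focal = focused_field(small_elements, small_spec, (70.0, 90.0), medium,
                              coarse_volume, time_search="focal")
        assert np.all(dense >= focal - 1e-12)


class TestSimulateSensitivityMap:
    def test_single_event_equals_its_field(self, small_spec, small_elements, medium, coarse_volume):
        plan = SweepPlan(azimuth_range=(90.0, 135.0), elevation_range=(90.0, 135.0), step=45.0)
        assert plan.n_events == 1
        m = simulate_sensitivity_map(small_elements, small_spec, plan, medium,
                                     coarse_volume, algorithm="exhaustive")
        f = focused_field(small_elements, small_spec, (90.0, 90.0), medium,
                          coarse_volume, time_search="focal")
        assert np.allclose(m.values, f / f.max())

    def test_more_events_never_decrease_any_voxel(self, small_spec, small_elements, medium, coarse_volume):
        coarse = simulate_sensitivity_map(
            small_elements, small_spec, SweepPlan(step=45.0), medium, coarse_volume,
            algorithm="exhaustive", normalize=False)
        fine = simulate_sensitivity_map(
            small_elements, small_spec, SweepPlan(step=22.5), medium, coarse_volume,
            algorithm="exhaustive", normalize=False)
        assert np.all(fine.values >= coarse.values - 1e-12)

    def test_azimuth_elevation_swap_symmetry(self, small_spec, small_elements, medium):
        vol = VolumeGrid(extent=(0.06, 0.06, 0.04), spacing=(0.02, 0.02, 0.02),
                         origin=(-0.03, -0.03, 0.04))
        m = simulate_sensitivity_map(small_elements, small_spec, SweepPlan(step=30.0),
                                     medium, vol, algorithm="exhaustive")
        assert np.allclose(m.values, np.transpose(m.values, (1, 0, 2)), rtol=1e-7)

    def test_pruned_matches_exhaustive_below_beamwidth(self, small_spec, small_elements, medium):
        # 8x8 array beamwidth ~ lambda/aperture ~ 8 deg; 4-deg steps are safe
        vol = VolumeGrid(extent=(0.04, 0.04, 0.04), spacing=(0.02, 0.02, 0.02),
                         origin=(-0.02, -0.02, 0.06))
        plan = SweepPlan(azimuth_range=(60.0, 120.0), elevation_range=(60.0, 120.0), step=4.0)
        ex = simulate_sensitivity_map(small_elements, small_spec, plan, medium, vol,
                                      algorithm="exhaustive")
        pr = simulate_sensitivity_map(small_elements, small_spec, plan, medium, vol,
                                      algorithm="pruned", neighborhood=2)
        assert np.allclose(ex.values, pr.values, rtol=2e-3, atol=2e-3)

    def test_normalized_map_has_unit_max(self, small_spec, small_elements, medium, coarse_volume):
        m = simulate_sensitivity_map(small_elements, small_spec, SweepPlan(step=45.0),
                                     medium, coarse_volume, algorithm="exhaustive")
        assert m.values.max() == pytest.approx(1.0)
        assert np.all(m.values >= 0)

    def test_empty_plan_rejected(self, small_spec, small_elements, medium, coarse_volume):
        with pytest.raises(ValueError):
            SweepPlan(azimuth_range=(90.0, 90.0), step=1.0)


class TestVirtualPointSourceMap:
    def test_lattice_position_arithmetic(self):
        # 15x15x25 cm at 2.5 cm steps: 7 x 7 x 11 = 539 positions
        pos = lattice_positions((0.15, 0.15, 0.25), 0.025)
        assert pos.shape == (539, 3)

    def test_noiseless_map_tracks_sweep_map(self, small_spec, small_elements, medium):
        pos = lattice_positions((0.04, 0.04, 0.04), 0.02, z0=0.05)
        shape = (3, 3, 3)
        virt = virtual_point_source_map(
            small_elements, small_spec, medium, pos, shape,
            sampling_rate=5e6, recon_halfwidth=0.012, recon_spacing=4e-3)
        lat = virt.grid
        swept = simulate_sensitivity_map(
            small_elements, small_spec, SweepPlan(step=2.0), medium, lat,
            algorithm="pruned")
        # both normalized; point-source protocol should track the sweep map
        assert np.allclose(virt.values, swept.values, atol=0.15)
        corr = np.corrcoef(virt.values.ravel(), swept.values.ravel())[0, 1]
        assert corr > 0.9

    def test_averaging_drives_map_toward_noiseless_value(
        self, small_spec, small_elements, medium
    ):
        # averaging n acquisitions suppresses the noise contribution ~1/sqrt(n)
        pos = np.array([[0.0, 0.0, 0.06]])

        def run(noise, n_avg, seed):
            m = virtual_point_source_map(
                small_elements, small_spec, medium, pos, (1, 1, 1),
                noise_std=noise, n_averages=n_avg, seed=seed,
                sampling_rate=5e6, recon_halfwidth=0.01, recon_spacing=5e-3,
                normalize=False)
            return m.values.ravel()[0]

        clean = run(0.0, 1, 0)
        dev1 = np.mean([abs(run(1e-4, 1, s) - clean) for s in range(10)])
        dev100 = np.mean([abs(run(1e-4, 100, s + 50) - clean) for s in range(10)])
        assert dev100 < dev1 / 3.0
        assert abs(run(1e-4, 100, 7) - clean) / clean < 0.05

    def test_invalid_averages_rejected(self, small_spec, small_elements, medium):
        with pytest.raises(ValueError):
            virtual_point_source_map(small_elements, small_spec, medium,
                                     np.array([[0, 0, 0.05]]), (1, 1, 1), n_averages=0)


class TestDensify:
    @staticmethod
    def _sparse(values):
        grid = VolumeGrid(extent=(0.04, 0.04, 0.04), spacing=(0.02, 0.02, 0.02),
                          origin=(-0.02, -0.02, 0.02))
        return SensitivityMap(values, grid, normalized=True)

    def test_constant_map_stays_constant(self):
        sp = self._sparse(np.full((2, 2, 2), 0.7))
        target = VolumeGrid(extent=(0.04, 0.04, 0.04), spacing=(0.005,) * 3,
                            origin=(-0.02, -0.02, 0.02))
        dense = densify_map(sp, target)
        assert np.allclose(dense.values, 0.7)

    def test_lattice_points_preserved(self):
        vals = np.arange(8, dtype=float).reshape(2, 2, 2) / 7.0
        sp = self._sparse(vals)
        dense = densify_map(sp, sp.grid)
        assert np.allclose(dense.values, vals)

    def test_linear_midpoint(self):
        vals = np.zeros((2, 2, 2))
        vals[0] = 0.4
        vals[1] = 0.8
        sp = self._sparse(vals)
        mid = VolumeGrid(extent=(0.001,) * 3, spacing=(0.001,) * 3,
                         origin=(-0.0005, -0.0005, 0.0295))
        dense = densify_map(sp, mid)
        assert dense.values[0, 0, 0] == pytest.approx(0.6)

    def test_too_few_lattice_points_rejected(self):
        grid = VolumeGrid(extent=(0.02, 0.04, 0.04), spacing=(0.02,) * 3,
                          origin=(-0.01, -0.02, 0.02))
        sp = SensitivityMap(np.ones((1, 2, 2)), grid)
        with pytest.raises(ValueError):
            densify_map(sp, grid)


class TestCorrectionFactors:
    @staticmethod
    def _map(values, normalized=True):
        grid = VolumeGrid(extent=(0.01, 0.01, 0.03), spacing=(0.01,) * 3,
                          origin=(-0.005, -0.005, 0.0))
        return SensitivityMap(np.asarray(values, float).reshape(1, 1, 3), grid,
                              normalized=normalized)

    def test_reciprocal_values(self):
        cv = correction_factors(self._map([1.0, 0.5, 0.25]), floor_epsilon=0.05)
        assert np.allclose(cv.factors.ravel(), [1.0, 2.0, 4.0])

    def test_floor_caps_zero_sensitivity(self):
        cv = correction_factors(self._map([1.0, 0.0, 0.02]), floor_epsilon=0.05)
        assert np.allclose(cv.factors.ravel(), [1.0, 20.0, 20.0])
        assert cv.n_capped == 2

    def test_factors_bounded_by_floor(self, rng):
        vals = rng.uniform(0, 1, 3)
        vals[0] = 1.0
        cv = correction_factors(self._map(vals), floor_epsilon=0.1)
        assert np.all(cv.factors >= 1.0 - 1e-12)
        assert np.all(cv.factors <= 10.0 + 1e-12)

    def test_unnormalized_map_rejected(self):
        with pytest.raises(ValueError, match="normaliz"):
            correction_factors(self._map([2.0, 1.0, 0.5], normalized=False))

    def test_bad_epsilon_rejected(self):
        with pytest.raises(ValueError):
            correction_factors(self._map([1.0, 0.5, 0.5]), floor_epsilon=1.5)
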