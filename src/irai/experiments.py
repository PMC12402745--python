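"""End-to-end experiment driver.

``run_experiment`` reproduces the three phantom studies in silico: generate
the planned dose, forward-model the radioacoustic channel data, reconstruct
by delay-and-sum, compensate with reciprocal-sensitivity factors, and
quantify the pre- versus post-compensation agreement.  Everything is
deterministic given the config seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .array_model import build_array
from .evaluate import dvh, dvh_rmse, gamma_index, region_mean_amplitude, ssim
from .forward import acquire, initial_pressure, propagate
from .io import RunConfig, save_volume
from .phantoms import (
    BeamSpec,
    CShapeSpec,
    beam_phantom_grid,
    beam_study_layouts,
    c_shape_dose,
    cshape_grid,
    square_beam_dose,
)
from .recon import compensate, das_reconstruct
from .sensitivity import (
    CorrectionVolume,
    correction_factors,
    densify_map,
    lattice_positions,
    simulate_sensitivity_map,
    virtual_point_source_map,
)

__all__ = ["run_experiment", "build_correction"]

log = logging.getLogger(__name__)

STUDIES = ("depth", "lateral", "size", "cshape")


def build_correction(config: RunConfig, grid) -> CorrectionVolume:
    """Correction-factor volume for a study grid from the configured source."""
    elements = build_array(config.transducer)
    if config.compensation_source == "simulated":
        smap = simulate_sensitivity_map(
            elements,
            config.transducer,
            config.sweep,
            config.medium,
            grid,
            response=config.response,
            f_number=config.f_number,
        )
    else:
        extent = tuple(e - 2 * s for e, s in zip(grid.extent, grid.spacing))
        step = max(extent) / 5.0
        z0 = grid.origin[2] + grid.spacing[2]
        pos = lattice_positions((extent[0], extent[1], extent[2] - step), step, z0=z0)
        shape = tuple(
            int(round(e / step)) + 1
            for e in (extent[0], extent[1], extent[2] - step)
        )
        sparse = virtual_point_source_map(
            elements,
            config.transducer,
            config.medium,
            pos,
            shape,
            noise_std=config.noise_std,
            n_averages=config.n_averages,
            seed=config.seed,
            sampling_rate=config.sampling_rate,
            response=config.response,
            pulse=config.pulse,
            f_number=config.f_number,
        )
        smap = densify_map(sparse, grid).normalize()
    return correction_factors(smap, config.floor_epsilon)


def _linear_slope(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.polyfit(x, y, 1)[0])


def _beam_report(
    config: RunConfig,
    beams: list[BeamSpec],
    grid,
    correction: CorrectionVolume,
    seeds: list[int],
) -> dict:
    elements = build_array(config.transducer)
    pre_means, post_means = [], []
    profile_slopes = []
    for beam, seed in zip(beams, seeds):
        dose = square_beam_dose(beam, grid)
        p0 = initial_pressure(dose, config.medium)
        channels = propagate(
            p0,
            grid,
            elements,
            config.transducer,
            config.medium,
            pulse=config.pulse,
            sampling_rate=config.sampling_rate,
            response=config.response,
        )
        channels = acquire(
            channels, config.noise_std, n_averages=config.n_averages, seed=seed
        )
        # quantification only needs the reconstruction inside the beam
        # column, so beamform just that sub-block of the phantom grid
        mask = dose.dose >= 0.5 * dose.max_dose
        nz = np.argwhere(mask)
        lo, hi = nz.min(axis=0), nz.max(axis=0) + 1
        sub = grid.subgrid(tuple(lo), tuple(hi))
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        recon = das_reconstruct(channels, elements, sub, config.medium,
                                f_number=config.f_number)
        corr_sub = CorrectionVolume(
            factors=correction.factors[sl], grid=sub,
            floor_epsilon=correction.floor_epsilon,
        )
        post = compensate(recon, corr_sub)
        sub_mask = mask[sl]
        pre_means.append(region_mean_amplitude(recon, sub_mask))
        post_means.append(region_mean_amplitude(post, sub_mask))
        profile_slopes.append(
            _in_beam_profile_slopes(beam, sub, recon.amplitude, post.amplitude)
        )
    pre = np.asarray(pre_means)
    post = np.asarray(post_means)
    # per-position amplitudes quoted relative to the family mean, so
    # "approaching 1" is an unbiased statement for every member
    return {
        "targets": [list(b.target_position) for b in beams],
        "field_sizes": [b.field_size for b in beams],
        "pre_means": (pre / pre.mean()).tolist(),
        "post_means": (post / post.mean()).tolist(),
        "cov_pre": float(pre.std() / pre.mean()),
        "cov_post": float(post.std() / post.mean()),
        "profile_slopes": profile_slopes,
    }


def _in_beam_profile_slopes(beam, grid, pre_amp, post_amp):
    """Linear slope (1/m) of the mean-normalized depth profile through the
    beam center, restricted to voxels strictly inside the beam column.

    None when the column spans fewer than 4 depth voxels (slope ill-posed).
    """
    from .evaluate import line_profile
    from .forward import DoseVolume

    x0, _, z0 = beam.target_position
    z = grid.axis_coords(2)
    inside = np.abs(z - z0) <= beam.field_size / 2.0 - grid.spacing[2] / 2.0
    if inside.sum() < 4:
        return None
    out = {}
    for name, amp in (("pre", pre_amp), ("post", post_amp)):
        vol = DoseVolume(dose=amp, grid=grid)
        coords, vals = line_profile(vol, 2, np.array([x0, 0.0, z0]))
        vals = vals[inside]
        out[name] = _linear_slope(coords[inside], vals / vals.mean())
    return out


def run_experiment(
    config: RunConfig,
    study: str,
    outdir=None,
    correction: CorrectionVolume | None = None,
    save_volumes: bool = False,
) -> dict:
    """Run one study end to end and return (and optionally write) a report.

    ``study`` is one of ``depth`` / ``lateral`` / ``size`` (square-beam
    families: per-position pre/post region-mean amplitudes, their
    coefficient of variation, and for the depth family the linear slope of
    amplitude versus depth) or ``cshape`` (DVH-RMSE, gamma pass rate and
    SSIM against the plan, before and after compensation).
    """
    if study not in STUDIES:
        raise ValueError(f"unknown study {study!r}; choose from {STUDIES}")
    rng = np.random.default_rng(config.seed)
    grid = (
        cshape_grid(config.grid_spacing)
        if study == "cshape"
        else beam_phantom_grid(config.grid_spacing)
    )
    if correction is None:
        correction = build_correction(config, grid)

    report: dict = {
        "study": study,
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "grid": grid.to_dict(),
        "n_capped_correction_voxels": correction.n_capped,
    }
    elements = build_array(config.transducer)

    if study in ("depth", "lateral", "size"):
        beams = beam_study_layouts()[study]
        seeds = [int(rng.integers(0, 2**31 - 1)) for _ in beams]
        res = _beam_report(config, beams, grid, correction, seeds)
        if study == "depth":
            z = np.array([t[2] for t in res["targets"]])
            res["slope_pre"] = _linear_slope(z, np.array(res["pre_means"]))
            res["slope_post"] = _linear_slope(z, np.array(res["post_means"]))
        report[study] = res
    else:
        spec = CShapeSpec()
        dose = c_shape_dose(spec, grid)
        p0 = initial_pressure(dose, config.medium)
        channels = propagate(
            p0,
            grid,
            elements,
            config.transducer,
            config.medium,
            pulse=config.pulse,
            sampling_rate=config.sampling_rate,
            response=config.response,
        )
        channels = acquire(
            channels,
            config.noise_std,
            n_averages=config.n_averages,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        recon = das_reconstruct(channels, elements, grid, config.medium,
                                f_number=config.f_number)
        post = compensate(recon, correction)

        plan_n = dose.dose / dose.dose.max()
        dvh_plan = dvh(plan_n, config.dvh_bins)
        g_kwargs = dict(
            dd_percent=config.dd_percent,
            dta_mm=config.dta_mm,
            low_dose_threshold=config.low_dose_threshold,
        )
        emask = plan_n >= config.low_dose_threshold / 100.0

        def _against_plan(vol_n):
            g = gamma_index(
                _on_grid(plan_n, grid), _on_grid(vol_n, grid), **g_kwargs
            )
            return {
                "dvh_rmse": dvh_rmse(dvh_plan, dvh(vol_n, config.dvh_bins)),
                "gamma_pass_rate": g.pass_rate,
                "ssim": ssim(plan_n, vol_n),
            }

        def _scaled(vol, how):
            # iRAI is relative dosimetry: the absolute scale of a
            # reconstruction is arbitrary.  "max" divides by the volume
            # maximum; "matched" applies the least-squares scale factor over
            # the evaluated (above-threshold) region.
            if how == "max":
                return vol / vol.max()
            s = float((vol[emask] * plan_n[emask]).sum() / (vol[emask] ** 2).sum())
            return vol * s

        report["cshape"] = {
            "plan_max_dose_gy": dose.max_dose,
            "pre": _against_plan(_scaled(recon.amplitude, "max")),
            "post": _against_plan(_scaled(post.amplitude, "max")),
            "pre_matched": _against_plan(_scaled(recon.amplitude, "matched")),
            "post_matched": _against_plan(_scaled(post.amplitude, "matched")),
        }
        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            _export_isodose_csv(
                outdir, grid, plan_n, recon.amplitude, post.amplitude, level=0.8
            )
        if save_volumes and outdir is not None:
            save_volume(outdir / "plan.nii", dose.dose, grid)
            save_volume(
                outdir / "recon_pre.nii", recon.amplitude, grid, {"compensated": False}
            )
            save_volume(
                outdir / "recon_post.nii", post.amplitude, grid, {"compensated": True}
            )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / f"report_{study}.json").write_text(
            json.dumps(report, indent=2, sort_keys=True)
        )
    return report


def _export_isodose_csv(outdir, grid, plan_n, pre_amp, post_amp, level=0.8):
    """Write 80%-isodose polylines of the axial mid-plane as CSV."""
    from .evaluate import isodose_contour

    kz = grid.shape[2] // 2
    for name, vol in (("plan", plan_n), ("pre", pre_amp), ("post", post_amp)):
        contour = isodose_contour(vol[:, :, kz] / vol[:, :, kz].max(), level)
        lines = ["polyline,x_m,y_m"]
        for i, poly in enumerate(contour.polylines):
            for px, py in poly:
                x = grid.origin[0] + (px + 0.5) * grid.spacing[0]
                y = grid.origin[1] + (py + 0.5) * grid.spacing[1]
                lines.append(f"{i},{x:.6f},{y:.6f}")
        (Path(outdir) / f"isodose80_{name}.csv").write_text("\n".join(lines) + "\n")


def _on_grid(values, grid):
    """Attach a grid to bare values for grid-checked metrics."""
    from .forward import DoseVolume

    return DoseVolume(dose=np.maximum(values, 0.0), grid=grid)
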