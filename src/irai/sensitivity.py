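"""Volumetric detection-sensitivity mapping and correction factors.

The detection sensitivity of a matrix array is characterized two ways:

* :func:`simulate_sensitivity_map` — a dynamic-focusing sweep: the array is
  steered through a dense grid of (azimuth, elevation) angles covering the
  forward hemisphere; for each focusing event the coherent, band-limited
  array response is evaluated throughout the volume with the focal law
  tracking range along the steered ray, and the voxel-wise maximum over all
  events forms the map.
* :func:`virtual_point_source_map` — a virtual reproduction of the
  point-source measurement protocol: a point acoustic source is simulated on
  a coarse lattice of positions, channel data are formed (optionally with
  averaged noise), each acquisition is reconstructed, and the image maximum
  represents the sensitivity at that position.

Receive sensitivity is obtained from the transmit-field picture by acoustic
reciprocity.  Correction-factor volumes are the regularized reciprocals of
the normalized map.

Angular convention: azimuth and elevation each sweep the half-open interval
[0, 180) degrees so that a 0.5-degree step yields exactly 360 x 360 events.
An angle pair maps to a steering direction through the tangent
parametrization ``d ~ (tan(az - 90), tan(el - 90), 1)``, which covers the
whole forward hemisphere without pole singularities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .array_model import (
    DEFAULT_F_NUMBER,
    ElementGrid,
    ElementResponse,
    TransducerSpec,
    aperture_mask,
    envelope_sigma,
)
from .forward import AcousticMedium, ChannelData, ExcitationPulse, acquire, propagate
from .grids import VolumeGrid

__all__ = [
    "SweepPlan",
    "SensitivityMap",
    "CorrectionVolume",
    "sweep_events",
    "direction_from_angles",
    "angles_from_direction",
    "focused_field",
    "simulate_sensitivity_map",
    "lattice_positions",
    "virtual_point_source_map",
    "densify_map",
    "correction_factors",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SweepPlan:
    """Angular sweep grid: half-open [start, stop) per axis, step in degrees."""

    azimuth_range: tuple[float, float] = (0.0, 180.0)
    elevation_range: tuple[float, float] = (0.0, 180.0)
    step: float = 0.5

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        for lo, hi in (self.azimuth_range, self.elevation_range):
            span = hi - lo
            if span <= 0:
                raise ValueError("angular range must be non-empty")
            n = span / self.step
            if abs(n - round(n)) > 1e-9:
                raise ValueError("step must divide the angular range")

    @property
    def n_azimuth(self) -> int:
        return int(round((self.azimuth_range[1] - self.azimuth_range[0]) / self.step))

    @property
    def n_elevation(self) -> int:
        return int(
            round((self.elevation_range[1] - self.elevation_range[0]) / self.step)
        )

    @property
    def n_events(self) -> int:
        return self.n_azimuth * self.n_elevation

    def azimuth_values(self) -> np.ndarray:
        return self.azimuth_range[0] + self.step * np.arange(self.n_azimuth)

    def elevation_values(self) -> np.ndarray:
        return self.elevation_range[0] + self.step * np.arange(self.n_elevation)

    def to_dict(self) -> dict:
        return {
            "azimuth_range": list(self.azimuth_range),
            "elevation_range": list(self.elevation_range),
            "step": self.step,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SweepPlan":
        return cls(
            azimuth_range=tuple(d["azimuth_range"]),
            elevation_range=tuple(d["elevation_range"]),
            step=d["step"],
        )


def sweep_events(plan: SweepPlan) -> np.ndarray:
    """Row-major (azimuth outer, elevation inner) enumeration of the sweep.

    Returns an ``(n_events, 2)`` array of (azimuth, elevation) degrees.
    The default plan reproduces the 360 x 360 = 129600 focusing events of a
    half-open 0-180 degree sweep at 0.5-degree steps.
    """
    az = plan.azimuth_values()
    el = plan.elevation_values()
    A, E = np.meshgrid(az, el, indexing="ij")
    return np.stack([A.ravel(), E.ravel()], axis=1)


_MAX_TILT = np.deg2rad(90.0) - 1e-9


def direction_from_angles(azimuth_deg, elevation_deg) -> np.ndarray:
    """Unit steering direction(s) for sweep angle pair(s) in degrees."""
    tx = np.tan(np.clip(np.deg2rad(np.asarray(azimuth_deg, float) - 90.0), -_MAX_TILT, _MAX_TILT))
    ty = np.tan(np.clip(np.deg2rad(np.asarray(elevation_deg, float) - 90.0), -_MAX_TILT, _MAX_TILT))
    d = np.stack([tx, ty, np.ones_like(tx)], axis=-1)
    return d / np.linalg.norm(d, axis=-1, keepdims=True)


def angles_from_direction(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sweep angles (degrees) whose steered ray passes through each point."""
    p = np.asarray(points, float)
    az = 90.0 + np.rad2deg(np.arctan2(p[..., 0], p[..., 2]))
    el = 90.0 + np.rad2deg(np.arctan2(p[..., 1], p[..., 2]))
    return az, el


@dataclass
class SensitivityMap:
    """Scalar detection-sensitivity field on a grid (arbitrary units)."""

    values: np.ndarray
    grid: VolumeGrid
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")
        if np.any(self.values < 0):
            raise ValueError("sensitivity values must be non-negative")

    def normalize(self) -> "SensitivityMap":
        m = float(self.values.max())
        if m <= 0:
            raise ValueError("cannot normalize an all-zero map")
        return SensitivityMap(self.values / m, self.grid, normalized=True)


@dataclass
class CorrectionVolume:
    """Voxel-wise compensation factors 1 / max(sensitivity, floor_epsilon)."""

    factors: np.ndarray
    grid: VolumeGrid
    floor_epsilon: float
    n_capped: int = 0

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if self.factors.shape != self.grid.shape:
            raise ValueError("factors shape does not match grid")


def _element_amplitudes(
    points: np.ndarray,
    epos: np.ndarray,
    spec: TransducerSpec,
    medium: AcousticMedium,
    response: ElementResponse,
    f_number: float | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per point x element: geometric distance and amplitude D/r.

    Elements outside the constant-F-number receive aperture of a point get
    amplitude 0.  Points coinciding with an element get amplitude 0
    (distance inf); the caller repairs them from neighbors.
    """
    d = points[:, None, :] - epos[None, :, :]
    r = np.sqrt(np.einsum("peq,peq->pe", d, d))
    bad = r < 1e-9
    if np.any(bad):
        r = np.where(bad, np.inf, r)
    dire = response(d[:, :, 0], d[:, :, 1], d[:, :, 2], r, spec, medium.sound_speed)
    amp = dire / r
    if f_number is not None:
        amp = np.where(aperture_mask(points, epos, f_number), amp, 0.0)
    return r, amp


def focused_field(
    elements: ElementGrid,
    spec: TransducerSpec,
    focus_direction: tuple[float, float],
    medium: AcousticMedium,
    volume: VolumeGrid,
    response: ElementResponse | None = None,
    time_search: str = "dense",
    f_number: float | None = DEFAULT_F_NUMBER,
) -> np.ndarray:
    """Peak envelope amplitude of one focusing event, per voxel.

    The array is steered along ``focus_direction = (azimuth, elevation)`` in
    degrees with a dynamic focal law and a constant-F-number expanding
    aperture: for each voxel the focal delays are
    those of the point at the voxel's range along the steered ray, so delays
    align exactly for voxels on the ray.  The voxel value is the temporal
    peak of the envelope of the coherent element sum, with each element
    weighted by its angular response over distance and the band-limited
    pulse envelope accounting for residual delay misalignment.

    ``time_search="dense"`` scans candidate envelope times across the delay
    spread; ``"focal"`` evaluates at the focal time only (the peak location
    for well-aligned voxels), which is what the sweep simulation uses.
    """
    if response is None:
        response = ElementResponse()
    points = volume.voxel_centers()
    if points.shape[0] == 0:
        raise ValueError("empty volume")
    epos = elements.positions
    c = medium.sound_speed
    omega = 2.0 * np.pi * spec.center_frequency
    sig_t = envelope_sigma(spec)
    d_hat = direction_from_angles(*focus_direction)

    r_v = np.linalg.norm(points, axis=1)
    focal = r_v[:, None] * d_hat[None, :]
    r_ev, amp = _element_amplitudes(points, epos, spec, medium, response, f_number)
    r_ep = np.linalg.norm(focal[:, None, :] - epos[None, :, :], axis=2)
    delta = (r_ev - r_ep) / c

    had_bad = ~np.isfinite(r_ev)
    if time_search == "focal":
        val = np.abs(
            np.sum(
                amp * np.exp(-(delta**2) / (2 * sig_t**2)) * np.exp(-1j * omega * delta),
                axis=1,
            )
        )
    elif time_search == "dense":
        dmin = np.where(np.isfinite(delta), delta, 0.0).min()
        dmax = np.where(np.isfinite(delta), delta, 0.0).max()
        ts = np.arange(dmin, dmax + sig_t / 4.0, sig_t / 4.0)
        ts = np.append(ts, 0.0)
        val = np.zeros(points.shape[0])
        z = amp * np.exp(-1j * omega * delta)
        for t in ts:
            g = np.exp(-((t - delta) ** 2) / (2 * sig_t**2))
            val = np.maximum(val, np.abs(np.sum(z * g, axis=1)))
    else:
        raise ValueError(f"unknown time_search mode: {time_search!r}")

    field = val.reshape(volume.shape)
    if np.any(had_bad):
        n_bad_vox = int(np.any(had_bad, axis=1).sum())
        warnings.warn(
            f"{n_bad_vox} voxels coincide with element positions; "
            "filled from nearest valid neighbor",
            stacklevel=2,
        )
        field = _fill_from_neighbors(field, np.any(had_bad, axis=1).reshape(volume.shape))
    return field


def _fill_from_neighbors(field: np.ndarray, bad: np.ndarray) -> np.ndarray:
    from scipy.ndimage import distance_transform_edt

    if not np.any(bad):
        return field
    idx = distance_transform_edt(bad, return_distances=False, return_indices=True)
    return field[tuple(idx)]


def simulate_sensitivity_map(
    elements: ElementGrid,
    spec: TransducerSpec,
    plan: SweepPlan,
    medium: AcousticMedium,
    volume: VolumeGrid,
    response: ElementResponse | None = None,
    algorithm: str = "auto",
    neighborhood: int = 2,
    normalize: bool = True,
    chunk_voxels: int = 4096,
    f_number: float | None = DEFAULT_F_NUMBER,
) -> SensitivityMap:
    """Voxel-wise maximum of the focused field over all sweep events.

    ``algorithm="exhaustive"`` evaluates every event over the whole volume
    (cost: events x voxels x elements — only for small problems).
    ``algorithm="pruned"`` exploits that the focused response decays away
    from the steered ray: for each voxel only the events steering within
    ``neighborhood`` grid steps of the voxel's own direction are evaluated,
    which contains the per-voxel argmax for any sweep step below the array
    beamwidth times the neighborhood size.  ``"auto"`` picks pruned for
    problems above ~2e8 element-voxel-event products.

    The returned map is normalized to a maximum of 1 unless ``normalize``
    is False.
    """
    if response is None:
        response = ElementResponse()
    if plan.n_events < 1:
        raise ValueError("sweep plan has no events")
    if volume.n_voxels == 0:
        raise ValueError("empty volume")
    if algorithm == "auto":
        work = float(plan.n_events) * volume.n_voxels * elements.n_elements
        algorithm = "exhaustive" if work <= 2e8 else "pruned"
    if algorithm == "exhaustive":
        best = np.zeros(volume.shape)
        for az, el in sweep_events(plan):
            f = focused_field(
                elements, spec, (az, el), medium, volume, response,
                time_search="focal", f_number=f_number,
            )
            np.maximum(best, f, out=best)
        out = SensitivityMap(best, volume)
        return out.normalize() if normalize else out
    if algorithm != "pruned":
        raise ValueError(f"unknown algorithm: {algorithm!r}")

    points = volume.voxel_centers()
    epos = elements.positions
    c = medium.sound_speed
    omega = 2.0 * np.pi * spec.center_frequency
    sig_t = envelope_sigma(spec)
    az_vals = plan.azimuth_values()
    el_vals = plan.elevation_values()
    az_v, el_v = angles_from_direction(points)
    ia = np.clip(
        np.round((az_v - az_vals[0]) / plan.step).astype(int), 0, az_vals.size - 1
    )
    ie = np.clip(
        np.round((el_v - el_vals[0]) / plan.step).astype(int), 0, el_vals.size - 1
    )
    offsets = range(-neighborhood, neighborhood + 1)
    best = np.zeros(points.shape[0], dtype=np.float32)
    for a in range(0, points.shape[0], chunk_voxels):
        b = min(a + chunk_voxels, points.shape[0])
        pts = points[a:b].astype(np.float32)
        r_ev, amp = _element_amplitudes(
            pts.astype(float), epos, spec, medium, response, f_number
        )
        amp = amp.astype(np.float32)
        r_ev = r_ev.astype(np.float32)
        r_v = np.linalg.norm(pts, axis=1)
        blk = np.zeros(b - a, dtype=np.float32)
        for di in offsets:
            ja = np.clip(ia[a:b] + di, 0, az_vals.size - 1)
            for dj in offsets:
                je = np.clip(ie[a:b] + dj, 0, el_vals.size - 1)
                d_hat = direction_from_angles(az_vals[ja], el_vals[je]).astype(
                    np.float32
                )
                focal = r_v[:, None] * d_hat
                diff = focal[:, None, :] - epos[None, :, :].astype(np.float32)
                r_ep = np.sqrt(np.einsum("peq,peq->pe", diff, diff))
                delta = (r_ev - r_ep) / c
                g = np.exp(-(delta**2) / (2 * sig_t**2))
                ph = omega * delta
                re = np.sum(amp * g * np.cos(ph), axis=1)
                im = np.sum(amp * g * np.sin(ph), axis=1)
                np.maximum(blk, np.sqrt(re**2 + im**2), out=blk)
        best[a:b] = blk
    field = best.astype(float).reshape(volume.shape)
    bad = ~np.isfinite(field)
    if np.any(bad):
        field = _fill_from_neighbors(np.where(bad, 0.0, field), bad)
    out = SensitivityMap(field, volume)
    return out.normalize() if normalize else out


def lattice_positions(
    extent: tuple[float, float, float],
    step: float,
    z0: float = 0.0,
) -> np.ndarray:
    """Measurement lattice of a point-source protocol.

    Inclusive grid: laterally centered spanning ``extent[0] x extent[1]``,
    depth from ``z0`` to ``z0 + extent[2]``, all at spacing ``step``.  A
    15 x 15 x 25 cm space at 2.5 cm steps gives 7 x 7 x 11 = 539 positions.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    nx = int(round(extent[0] / step)) + 1
    ny = int(round(extent[1] / step)) + 1
    nz = int(round(extent[2] / step)) + 1
    xs = (np.arange(nx) - (nx - 1) / 2.0) * step
    ys = (np.arange(ny) - (ny - 1) / 2.0) * step
    zs = z0 + np.arange(nz) * step
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)


def virtual_point_source_map(
    elements: ElementGrid,
    spec: TransducerSpec,
    medium: AcousticMedium,
    source_positions: np.ndarray,
    lattice_shape: tuple[int, int, int],
    noise_std: float = 0.0,
    n_averages: int = 1,
    seed: int | None = None,
    sampling_rate: float = 5e6,
    recon_halfwidth: float = 0.02,
    recon_spacing: float = 5e-3,
    response: ElementResponse | None = None,
    pulse: ExcitationPulse | None = None,
    normalize: bool = True,
    f_number: float | None = DEFAULT_F_NUMBER,
) -> SensitivityMap:
    """Sensitivity sampled by simulated point sources (measurement twin).

    For each lattice position a unit point source is forward-modeled, the
    channel data acquired (optionally with white noise averaged
    ``n_averages`` times), reconstructed by delay-and-sum over a small box
    around the source, and the image maximum recorded as the sensitivity at
    that position.  The result lives on the (coarse) source lattice, in
    lattice-index order, normalized over all positions.
    """
    from .recon import das_reconstruct  # local import; recon depends on us

    if n_averages < 1:
        raise ValueError("n_averages must be >= 1")
    pos = np.asarray(source_positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise ValueError("source_positions must be (n, 3)")
    if int(np.prod(lattice_shape)) != pos.shape[0]:
        raise ValueError("lattice_shape does not match the number of positions")
    if np.any(pos[:, 2] <= 0):
        raise ValueError("source positions must lie in front of the array")
    if response is None:
        response = ElementResponse()
    rng = np.random.default_rng(seed)
    vals = np.empty(pos.shape[0])
    for i, p in enumerate(pos):
        src_grid = VolumeGrid(
            extent=(1e-3, 1e-3, 1e-3),
            spacing=(1e-3, 1e-3, 1e-3),
            origin=(p[0] - 5e-4, p[1] - 5e-4, p[2] - 5e-4),
        )
        channels = propagate(
            np.ones((1, 1, 1)),
            src_grid,
            elements,
            spec,
            medium,
            pulse=pulse,
            sampling_rate=sampling_rate,
            response=response,
        )
        channels = acquire(
            channels,
            noise_std,
            n_averages=n_averages,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        # odd voxel count with one center exactly on the source, so the
        # image maximum can be read at the true point response
        nvox = 2 * int(np.ceil(recon_halfwidth / recon_spacing)) + 1
        half = nvox * recon_spacing / 2.0
        zlo = max(p[2] - half, 1e-6)
        win = VolumeGrid(
            extent=(nvox * recon_spacing,) * 3,
            spacing=(recon_spacing,) * 3,
            origin=(p[0] - half, p[1] - half, zlo),
        )
        img = das_reconstruct(channels, elements, win, medium, f_number=f_number)
        vals[i] = float(img.amplitude.max())

    step = np.array(
        [
            (pos[:, a].max() - pos[:, a].min()) / max(lattice_shape[a] - 1, 1)
            if lattice_shape[a] > 1
            else 1e-3
            for a in range(3)
        ]
    )
    lat_grid = VolumeGrid(
        extent=tuple(step[a] * lattice_shape[a] for a in range(3)),
        spacing=tuple(step),
        origin=tuple(pos[:, a].min() - step[a] / 2 for a in range(3)),
    )
    out = SensitivityMap(vals.reshape(lattice_shape), lat_grid)
    return out.normalize() if normalize else out


def densify_map(sparse: SensitivityMap, target: VolumeGrid) -> SensitivityMap:
    """Trilinear interpolation of a lattice map onto a voxel grid.

    Query points outside the lattice hull are clamped to the nearest lattice
    coordinate (constant extrapolation).  Requires at least two lattice
    points per axis.
    """
    from scipy.interpolate import RegularGridInterpolator

    if any(n < 2 for n in sparse.grid.shape):
        raise ValueError("sparse lattice needs at least 2 points per axis")
    coords = [sparse.grid.axis_coords(a) for a in range(3)]
    interp = RegularGridInterpolator(coords, sparse.values, method="linear")
    q = target.voxel_centers()
    for a in range(3):
        q[:, a] = np.clip(q[:, a], coords[a][0], coords[a][-1])
    vals = interp(q).reshape(target.shape)
    return SensitivityMap(vals, target, normalized=sparse.normalized)


def correction_factors(
    smap: SensitivityMap, floor_epsilon: float = 0.05
) -> CorrectionVolume:
    """Reciprocal-sensitivity compensation factors, floored at epsilon.

    The reciprocal of a normalized sensitivity map diverges where the map
    approaches zero; values below ``floor_epsilon`` are clamped so factors
    stay within [1, 1/epsilon], and the number of capped voxels is logged.
    """
    if not smap.normalized:
        raise ValueError("normalize the sensitivity map before taking reciprocals")
    if not 0 < floor_epsilon < 1:
        raise ValueError("floor_epsilon must be in (0, 1)")
    capped = int(np.count_nonzero(smap.values < floor_epsilon))
    if capped:
        log.info(
            "correction_factors: %d voxels below floor epsilon %.3g were capped",
            capped,
            floor_epsilon,
        )
    factors = 1.0 / np.maximum(smap.values, floor_epsilon)
    return CorrectionVolume(
        factors=factors, grid=smap.grid, floor_epsilon=floor_epsilon, n_capped=capped
    )
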