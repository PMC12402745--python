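"""Quantitative agreement between reconstructed volumes and planned dose.

Implements the standard radiotherapy QA toolbox used to score the
reconstructions: cumulative dose-volume histograms (DVH) and their RMSE,
the global gamma index (dose-difference / distance-to-agreement), SSIM,
isodose contours, region-mean amplitudes and line profiles.

Conventions
-----------
* DVH: volume fraction (%) of voxels with value >= each of ``n_bins``
  equally spaced levels from 0 to the volume maximum.
* Gamma: global normalization to the reference maximum; voxels below a
  low-dose threshold (% of the reference maximum) are excluded from the
  pass rate; the displacement search covers a sphere of radius
  ``search_radius_factor * dta`` sampled at ``dta / subsample_factor`` per
  axis, with the evaluated volume interpolated trilinearly at sub-voxel
  positions.
* DVH-RMSE is quoted in percentage points of volume fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.measure import find_contours
from skimage.metrics import structural_similarity

from .forward import DoseVolume
from .grids import VolumeGrid
from .recon import ReconVolume

__all__ = [
    "DVHCurve",
    "GammaResult",
    "IsodoseContour",
    "dvh",
    "dvh_rmse",
    "gamma_index",
    "ssim",
    "isodose_contour",
    "region_mean_amplitude",
    "line_profile",
]


def _values_of(vol) -> np.ndarray:
    if isinstance(vol, DoseVolume):
        return vol.dose
    if isinstance(vol, ReconVolume):
        return vol.amplitude
    return np.asarray(vol, dtype=float)


def _grid_of(vol) -> VolumeGrid | None:
    return getattr(vol, "grid", None)


@dataclass
class DVHCurve:
    """Cumulative (complementary) dose-volume histogram."""

    dose_bins: np.ndarray
    volume_fraction: np.ndarray  # percent of voxels with value >= bin

    def __post_init__(self) -> None:
        self.dose_bins = np.asarray(self.dose_bins, dtype=float)
        self.volume_fraction = np.asarray(self.volume_fraction, dtype=float)
        if self.dose_bins.shape != self.volume_fraction.shape:
            raise ValueError("bins and fractions must have equal length")
        if np.any(np.diff(self.volume_fraction) > 1e-9):
            raise ValueError("volume fraction must be non-increasing")


def dvh(volume, n_bins: int = 101) -> DVHCurve:
    """Complementary cumulative histogram on [0, max] with ``n_bins`` levels."""
    vals = _values_of(volume).ravel()
    if vals.size == 0:
        raise ValueError("empty volume")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    vmax = float(vals.max())
    bins = np.linspace(0.0, vmax if vmax > 0 else 1.0, n_bins)
    # fraction of voxels >= level; sorted search is O(n log n) once
    s = np.sort(vals)
    frac = 100.0 * (s.size - np.searchsorted(s, bins, side="left")) / s.size
    return DVHCurve(dose_bins=bins, volume_fraction=frac)


def dvh_rmse(a: DVHCurve, b: DVHCurve) -> float:
    """RMS difference of volume fractions (percentage points) over common bins.

    If the two curves are not on identical bins, ``b`` is resampled onto
    ``a``'s bins with a warning.
    """
    fb = b.volume_fraction
    if a.dose_bins.shape != b.dose_bins.shape or not np.allclose(
        a.dose_bins, b.dose_bins
    ):
        warnings.warn("DVH bins differ; resampling second curve", stacklevel=2)
        fb = np.interp(a.dose_bins, b.dose_bins, b.volume_fraction)
    return float(np.sqrt(np.mean((a.volume_fraction - fb) ** 2)))


@dataclass
class GammaResult:
    """Gamma map and pass rate of a DD/DTA comparison."""

    gamma_map: np.ndarray
    pass_rate: float  # percent of evaluated voxels with gamma <= 1
    dd_percent: float
    dta_mm: float
    low_dose_threshold: float
    n_evaluated: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.pass_rate <= 100.0:
            raise ValueError("pass_rate must be a percentage")


def _displacement_offsets(
    spacing: np.ndarray, dta: float, search_radius_factor: float, subsample_factor: int
) -> np.ndarray:
    """Physical displacement candidates, sorted by radius (origin first)."""
    step = dta / subsample_factor
    radius = search_radius_factor * dta
    n = int(np.floor(radius / step))
    ax = step * np.arange(-n, n + 1)
    OX, OY, OZ = np.meshgrid(ax, ax, ax, indexing="ij")
    offs = np.stack([OX.ravel(), OY.ravel(), OZ.ravel()], axis=1)
    r2 = np.einsum("ij,ij->i", offs, offs)
    keep = r2 <= radius**2 + 1e-12
    offs, r2 = offs[keep], r2[keep]
    order = np.argsort(r2, kind="stable")
    return offs[order]


def gamma_index(
    reference,
    evaluated,
    dd_percent: float = 5.0,
    dta_mm: float = 5.0,
    low_dose_threshold: float = 10.0,
    search_radius_factor: float = 3.0,
    subsample_factor: int = 3,
) -> GammaResult:
    """Global 3D gamma index between two volumes on the same physical grid.

    Per reference voxel::

        gamma = min over displacements r of
                sqrt( (D_eval(x+r) - D_ref(x))^2 / (dd * Dmax_ref)^2
                      + |r|^2 / dta^2 )

    Displacements are enumerated coarsest-first so the search can stop once
    the distance term alone exceeds the current worst gamma.  The pass rate
    counts voxels with gamma <= 1 among those with reference dose at or
    above ``low_dose_threshold`` percent of the reference maximum (0 keeps
    every voxel).
    """
    ref = _values_of(reference)
    ev = _values_of(evaluated)
    if ref.shape != ev.shape:
        raise ValueError("reference and evaluated volumes must share a grid")
    g_ref, g_ev = _grid_of(reference), _grid_of(evaluated)
    if g_ref is not None and g_ev is not None:
        if not (
            np.allclose(g_ref.spacing, g_ev.spacing)
            and np.allclose(g_ref.origin, g_ev.origin)
        ):
            raise ValueError("reference and evaluated grids do not match")
    spacing = np.asarray(g_ref.spacing if g_ref is not None else (1e-3, 1e-3, 1e-3))
    if dd_percent <= 0 or dta_mm <= 0:
        raise ValueError("dd_percent and dta_mm must be positive")
    dta = dta_mm * 1e-3
    if np.max(spacing) > dta:
        raise ValueError(
            "grid spacing exceeds the DTA criterion; resample the volumes first"
        )
    dmax = float(ref.max())
    if dmax <= 0:
        raise ValueError("reference volume is empty")
    dd_abs = dd_percent / 100.0 * dmax

    offsets = _displacement_offsets(spacing, dta, search_radius_factor, subsample_factor)
    base = np.indices(ref.shape, dtype=float)
    flat_idx = base.reshape(3, -1)
    gamma2 = np.full(ref.size, np.inf)
    ref_flat = ref.ravel()
    active = np.arange(ref.size)
    for off in offsets:
        dist2 = float(np.sum(off**2)) / dta**2
        worst = gamma2[active].max() if active.size else 0.0
        if dist2 >= worst:
            break
        sel = active[gamma2[active] > dist2]
        if sel.size == 0:
            continue
        coords = flat_idx[:, sel] + (off / spacing)[:, None]
        inside = np.all(
            (coords >= 0) & (coords <= (np.array(ref.shape) - 1)[:, None]), axis=0
        )
        if not np.any(inside):
            continue
        sel = sel[inside]
        vals = map_coordinates(ev, coords[:, inside], order=1, mode="nearest")
        g2 = (vals - ref_flat[sel]) ** 2 / dd_abs**2 + dist2
        improved = g2 < gamma2[sel]
        gamma2[sel[improved]] = g2[improved]
        active = active[gamma2[active] > dist2]
    gamma_map = np.sqrt(gamma2).reshape(ref.shape)

    if low_dose_threshold > 0:
        mask = ref >= low_dose_threshold / 100.0 * dmax
    else:
        mask = np.ones_like(ref, dtype=bool)
    n_eval = int(mask.sum())
    if n_eval == 0:
        raise ValueError("no voxels above the low-dose threshold")
    # tiny epsilon so exact-boundary cases (gamma == 1) are not lost to rounding
    pass_rate = 100.0 * float(np.count_nonzero(gamma_map[mask] <= 1.0 + 1e-9)) / n_eval
    return GammaResult(
        gamma_map=gamma_map,
        pass_rate=pass_rate,
        dd_percent=dd_percent,
        dta_mm=dta_mm,
        low_dose_threshold=low_dose_threshold,
        n_evaluated=n_eval,
    )


def ssim(
    a,
    b,
    mode: str = "slices",
    sigma: float = 1.5,
    data_range: float | None = None,
) -> float:
    """Mean structural similarity with a Gaussian window.

    ``mode="slices"`` averages 2D SSIM over matched axial (x-y) planes;
    ``mode="volume"`` computes a single volumetric SSIM.  Inputs should be
    normalized to a common dynamic range; by default the range is the joint
    max of both volumes.
    """
    va, vb = _values_of(a), _values_of(b)
    if va.shape != vb.shape:
        raise ValueError("shapes do not match")
    if data_range is None:
        data_range = float(max(va.max(), vb.max()) - min(va.min(), vb.min()))
        if data_range <= 0:
            return 1.0
    kwargs = dict(gaussian_weights=True, sigma=sigma, use_sample_covariance=False,
                  data_range=data_range)
    if va.ndim == 2 or mode == "volume":
        return float(structural_similarity(va, vb, **kwargs))
    if mode != "slices":
        raise ValueError("mode must be 'slices' or 'volume'")
    vals = [
        structural_similarity(va[:, :, k], vb[:, :, k], **kwargs)
        for k in range(va.shape[2])
    ]
    return float(np.mean(vals))


@dataclass
class IsodoseContour:
    """Marching-squares contours of one isodose level in a planar slice."""

    level: float  # fraction of the image maximum
    polylines: list = field(default_factory=list)  # each (n, 2) in pixel coords


def isodose_contour(plane_image: np.ndarray, level_fraction: float) -> IsodoseContour:
    """Contours at ``level_fraction`` of the image maximum (e.g. 0.8)."""
    img = np.asarray(plane_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("plane_image must be 2D")
    if not 0 < level_fraction < 1:
        raise ValueError("level_fraction must be in (0, 1)")
    level = level_fraction * float(img.max())
    if img.max() <= 0 or level >= img.max():
        warnings.warn("isodose level at or above the image maximum", stacklevel=2)
        return IsodoseContour(level=level_fraction, polylines=[])
    lines = find_contours(img, level)
    return IsodoseContour(level=level_fraction, polylines=lines)


def region_mean_amplitude(volume, mask: np.ndarray) -> float:
    """Mean amplitude over a region mask (e.g. the planned dose region)."""
    vals = _values_of(volume)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vals.shape:
        raise ValueError("mask shape does not match volume")
    if not np.any(mask):
        raise ValueError("empty mask")
    return float(vals[mask].mean())


def line_profile(
    volume, axis: int, through_point: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """1D profile along a grid axis through a physical point.

    Returns ``(coords_m, values)``: physical coordinates (m) of the sampled
    voxel centers along ``axis`` and the amplitudes there.
    """
    vals = _values_of(volume)
    grid = _grid_of(volume)
    if grid is None:
        raise ValueError("volume must carry a grid")
    if not grid.contains(np.asarray(through_point)):
        raise ValueError("point lies outside the volume")
    idx = list(grid.index_of(np.asarray(through_point)))
    sl = [slice(None) if a == axis else idx[a] for a in range(3)]
    return grid.axis_coords(axis), vals[tuple(sl)]
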