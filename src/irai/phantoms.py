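"""Synthetic dose volumes for the beam and treatment-plan studies.

The beam study mirrors a LINAC irradiating a homogeneous soft-tissue phantom
(a 17 x 17 x 20 cm box of solidified vegetable oil) with vertically directed
square x-ray beams while a matrix array on one side (the z = 0 face) records
the radioacoustic signals.  "Vertical" is the elevation axis y: a beam is a
rectangular column of dose, square in the x-z cross-section, traversing the
phantom along y.

Three layout families probe the detection-sensitivity variation:

* depth:   1 x 1 cm beams on the central axis at z = 5, 7, ..., 17 cm;
* lateral: 1 x 1 cm beams at z = 11 cm, x = -6 ... +6 cm in 2 cm steps;
* size:    1-5 cm beams centered at z = 11 cm.

The treatment-plan study uses a C-shaped target (annular sector sparing a
central "spine") with a maximum dose of 21.6 Gy.  The clinical plan's
exact geometry is not available; the default dimensions here (outer radius
5 cm, inner radius 2.5 cm, 90-degree gap, 5 cm height, 3 mm Gaussian edge)
are a synthetic stand-in reproducing the topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .forward import DoseVolume
from .grids import VolumeGrid

__all__ = [
    "BeamSpec",
    "CShapeSpec",
    "square_beam_dose",
    "beam_study_layouts",
    "c_shape_dose",
    "beam_phantom_grid",
    "cshape_grid",
]

#: 2.26 Gy delivered per measurement in the beam study.
DEFAULT_BEAM_DOSE_GY = 2.26

#: Maximum dose of the C-shaped plan, Gy.
CSHAPE_MAX_DOSE_GY = 21.6


def beam_phantom_grid(spacing: float = 5e-3) -> VolumeGrid:
    """Voxel grid of the 17 x 17 x 20 cm beam-study phantom box."""
    return VolumeGrid(extent=(0.17, 0.17, 0.20), spacing=(spacing,) * 3)


def cshape_grid(spacing: float = 5e-3, center_depth: float = 0.11) -> VolumeGrid:
    """15 x 15 x 15 cm evaluation volume centered at the plan depth."""
    return VolumeGrid(
        extent=(0.15, 0.15, 0.15),
        spacing=(spacing,) * 3,
        origin=(-0.075, -0.075, center_depth - 0.075),
    )


@dataclass(frozen=True)
class BeamSpec:
    """A square x-ray beam traversing the phantom along the vertical (y) axis.

    field_size : side of the square cross-section in the x-z plane, m
    target_position : beam-axis location (x, y-ignored, z), m
    dose_gy : plateau dose inside the column, Gy
    depth_dose_model : "uniform" or "exponential" (attenuation mu_eff along
        the beam direction, entering from +y)
    """

    field_size: float
    target_position: tuple[float, float, float]
    dose_gy: float = DEFAULT_BEAM_DOSE_GY
    depth_dose_model: str = "uniform"
    mu_eff: float = 0.0
    edge_softness: float = 0.0
    entry_axis: str = "y"

    def __post_init__(self) -> None:
        if self.field_size <= 0:
            raise ValueError("field_size must be positive")
        if self.dose_gy <= 0:
            raise ValueError("dose_gy must be positive")
        if self.depth_dose_model not in ("uniform", "exponential"):
            raise ValueError("depth_dose_model must be 'uniform' or 'exponential'")
        if self.depth_dose_model == "exponential" and self.mu_eff <= 0:
            raise ValueError("exponential model needs mu_eff > 0")
        if self.entry_axis != "y":
            raise ValueError("only vertical (y) beams are supported")

    def to_dict(self) -> dict:
        return {
            "field_size": self.field_size,
            "target_position": list(self.target_position),
            "dose_gy": self.dose_gy,
            "depth_dose_model": self.depth_dose_model,
            "mu_eff": self.mu_eff,
            "edge_softness": self.edge_softness,
            "entry_axis": self.entry_axis,
        }


def square_beam_dose(spec: BeamSpec, volume: VolumeGrid) -> DoseVolume:
    """Voxelize a square beam column onto a grid.

    Dose is nonzero only where the voxel center lies inside the square
    column; along the beam (y) it is constant for the uniform model or
    ``exp(-mu_eff * path)`` from the +y entry face for the exponential one.
    Optionally the hard column is smoothed by a Gaussian of physical width
    ``edge_softness`` (dose renormalized to the plateau).
    """
    x0, _, z0 = spec.target_position
    half = spec.field_size / 2.0
    lo = np.asarray(volume.origin)
    hi = lo + np.asarray(volume.extent)
    if not (lo[0] <= x0 - half and x0 + half <= hi[0] and lo[2] <= z0 - half and z0 + half <= hi[2]):
        raise ValueError("beam column does not fit inside the grid")
    x = volume.axis_coords(0)
    y = volume.axis_coords(1)
    z = volume.axis_coords(2)
    # half-open [lo, hi) column so beam edges falling exactly on voxel
    # boundaries still select a well-defined voxel set
    tol = 1e-9
    in_x = (x >= x0 - half - tol) & (x < x0 + half - tol)
    in_z = (z >= z0 - half - tol) & (z < z0 + half - tol)
    if spec.depth_dose_model == "uniform":
        along = np.ones_like(y)
    else:
        along = np.exp(-spec.mu_eff * (hi[1] - y))
    dose = (
        in_x[:, None, None] * along[None, :, None] * in_z[None, None, :]
    ) * spec.dose_gy
    if spec.edge_softness > 0:
        sig = [spec.edge_softness / s for s in volume.spacing]
        dose = gaussian_filter(dose, sigma=sig)
        if dose.max() > 0:
            dose *= spec.dose_gy / dose.max()
    return DoseVolume(dose=dose, grid=volume)


def beam_study_layouts(
    dose_gy: float = DEFAULT_BEAM_DOSE_GY,
) -> dict[str, list[BeamSpec]]:
    """The three beam-study families.

    depth: seven 1 x 1 cm beams at z = 5-17 cm (2 cm steps) on the central
    axis; lateral: seven 1 x 1 cm beams at z = 11 cm spaced 2 cm apart in x;
    size: 1, 2, 3, 4 and 5 cm beams at z = 11 cm.
    """
    depth = [
        BeamSpec(field_size=0.01, target_position=(0.0, 0.0, z), dose_gy=dose_gy)
        for z in np.arange(0.05, 0.171, 0.02)
    ]
    lateral = [
        BeamSpec(field_size=0.01, target_position=(x, 0.0, 0.11), dose_gy=dose_gy)
        for x in np.arange(-0.06, 0.061, 0.02)
    ]
    size = [
        BeamSpec(field_size=s, target_position=(0.0, 0.0, 0.11), dose_gy=dose_gy)
        for s in (0.01, 0.02, 0.03, 0.04, 0.05)
    ]
    return {"depth": depth, "lateral": lateral, "size": size}


@dataclass(frozen=True)
class CShapeSpec:
    """C-shaped (annular-sector) prism target.

    The annulus lies in the x-y plane with the prism axis along depth z;
    the gap sector of full width ``2 * gap_half_angle`` is bisected by the
    +y direction, so the dose is mirror-symmetric in x.
    """

    outer_radius: float = 0.05
    inner_radius: float = 0.025
    gap_half_angle: float = np.pi / 4.0
    height: float = 0.05
    max_dose: float = CSHAPE_MAX_DOSE_GY
    edge_softness: float = 3e-3
    center: tuple[float, float, float] = (0.0, 0.0, 0.11)

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius < self.outer_radius:
            raise ValueError("need 0 < inner_radius < outer_radius")
        if not 0 < self.gap_half_angle < np.pi:
            raise ValueError("gap_half_angle must be in (0, pi)")
        if self.height <= 0 or self.max_dose <= 0:
            raise ValueError("height and max_dose must be positive")

    def to_dict(self) -> dict:
        return {
            "outer_radius": self.outer_radius,
            "inner_radius": self.inner_radius,
            "gap_half_angle": self.gap_half_angle,
            "height": self.height,
            "max_dose": self.max_dose,
            "edge_softness": self.edge_softness,
            "center": list(self.center),
        }


def c_shape_dose(spec: CShapeSpec, volume: VolumeGrid) -> DoseVolume:
    """Voxelize the C-shaped plan: annular sector prism at ``max_dose``.

    The gap sector (angles within ``gap_half_angle`` of +y) and the inner
    core are zero; edges are smoothed by a Gaussian of width
    ``edge_softness`` and the volume rescaled so its maximum equals
    ``max_dose`` exactly.
    """
    cx, cy, cz = spec.center
    lo = np.asarray(volume.origin)
    hi = lo + np.asarray(volume.extent)
    if not (
        lo[0] <= cx - spec.outer_radius
        and cx + spec.outer_radius <= hi[0]
        and lo[1] <= cy - spec.outer_radius
        and cy + spec.outer_radius <= hi[1]
        and lo[2] <= cz - spec.height / 2
        and cz + spec.height / 2 <= hi[2]
    ):
        raise ValueError("C-shape does not fit inside the grid")
    x = volume.axis_coords(0) - cx
    y = volume.axis_coords(1) - cy
    z = volume.axis_coords(2) - cz
    X, Y = np.meshgrid(x, y, indexing="ij")
    rho = np.hypot(X, Y)
    # angle measured from the gap bisector (+y)
    phi = np.abs(np.arctan2(X, Y))
    # small tolerance so voxels exactly on the sector boundary classify
    # identically under the x -> -x mirror
    eps = 1e-9
    in_annulus = (rho >= spec.inner_radius - eps) & (rho <= spec.outer_radius + eps)
    in_c = in_annulus & (phi >= spec.gap_half_angle - eps)
    in_z = np.abs(z) <= spec.height / 2.0
    dose = (in_c[:, :, None] & in_z[None, None, :]).astype(float)
    if spec.edge_softness > 0:
        sig = [spec.edge_softness / s for s in volume.spacing]
        dose = gaussian_filter(dose, sigma=sig)
    if dose.max() <= 0:
        raise ValueError("C-shape mask is empty on this grid")
    dose *= spec.max_dose / dose.max()
    return DoseVolume(dose=dose, grid=volume)
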