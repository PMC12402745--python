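"""Physical voxel grids.

All volumes in this package live on a :class:`VolumeGrid`: a regular,
axis-aligned lattice of voxel *centers* in the transducer coordinate frame
(x = azimuth, y = elevation, z = depth into the medium, origin at the center
of the array face).  ``origin`` is the physical position of the low corner of
the volume; voxel centers sit half a spacing inside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeGrid"]


@dataclass(frozen=True)
class VolumeGrid:
    """Regular voxel grid in meters.

    Parameters
    ----------
    extent:
        Physical side lengths ``(Lx, Ly, Lz)`` in meters.
    spacing:
        Voxel side lengths ``(dx, dy, dz)`` in meters.
    origin:
        Physical coordinate of the low corner of the volume.  The default
        centers the volume laterally on the array axis with its front face
        at the array plane ``z = 0``.
    """

    extent: tuple[float, float, float]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        extent = tuple(float(v) for v in self.extent)
        spacing = tuple(float(v) for v in self.spacing)
        if len(extent) != 3 or len(spacing) != 3:
            raise ValueError("extent and spacing must be length-3")
        if any(v <= 0 for v in extent) or any(v <= 0 for v in spacing):
            raise ValueError("extent and spacing must be positive")
        origin = self.origin
        if origin is None:
            origin = (-extent[0] / 2.0, -extent[1] / 2.0, 0.0)
        origin = tuple(float(v) for v in origin)
        if origin[2] < 0:
            raise ValueError("volume must lie in front of the array (z >= 0)")
        object.__setattr__(self, "extent", extent)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        """Voxel counts per axis (extent/spacing, rounded)."""
        return tuple(
            int(round(e / s)) for e, s in zip(self.extent, self.spacing)
        )

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis."""
        n = self.shape[axis]
        d = self.spacing[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * d

    def voxel_centers(self) -> np.ndarray:
        """All voxel centers as an ``(n_voxels, 3)`` array (C order)."""
        x, y, z = (self.axis_coords(a) for a in range(3))
        X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def index_of(self, point: np.ndarray) -> tuple[int, int, int]:
        """Voxel index containing a physical point (clipped to the grid)."""
        p = np.asarray(point, dtype=float)
        idx = np.floor((p - np.asarray(self.origin)) / np.asarray(self.spacing))
        return tuple(
            int(np.clip(idx[a], 0, self.shape[a] - 1)) for a in range(3)
        )

    def contains(self, point: np.ndarray) -> bool:
        p = np.asarray(point, dtype=float)
        lo = np.asarray(self.origin)
        hi = lo + np.asarray(self.extent)
        return bool(np.all(p >= lo) and np.all(p <= hi))

    def subgrid(self, lo: tuple[int, int, int], hi: tuple[int, int, int]) -> "VolumeGrid":
        """Axis-aligned sub-block [lo, hi) in voxel indices, sharing voxel
        centers with the parent grid."""
        for a in range(3):
            if not 0 <= lo[a] < hi[a] <= self.shape[a]:
                raise ValueError("subgrid bounds outside the parent grid")
        return VolumeGrid(
            extent=tuple((hi[a] - lo[a]) * self.spacing[a] for a in range(3)),
            spacing=self.spacing,
            origin=tuple(self.origin[a] + lo[a] * self.spacing[a] for a in range(3)),
        )

    def to_dict(self) -> dict:
        return {
            "extent": list(self.extent),
            "spacing": list(self.spacing),
            "origin": list(self.origin),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VolumeGrid":
        return cls(
            extent=tuple(d["extent"]),
            spacing=tuple(d["spacing"]),
            origin=tuple(d["origin"]) if d.get("origin") is not None else None,
        )
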