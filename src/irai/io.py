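"""File I/O and run configuration.

Volumes are written as NIfTI (spacing/origin in the affine, meters scaled to
millimeters per NIfTI convention) with a JSON sidecar carrying flags such as
``compensated`` or ``normalized``.  Channel data live in HDF5 containers
with ``traces``, ``sampling_rate``, ``t0``, ``element_positions`` and
``seed`` datasets.  Run configuration is YAML.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .array_model import DEFAULT_F_NUMBER, ElementResponse, TransducerSpec
from .forward import AcousticMedium, ChannelData, ExcitationPulse
from .grids import VolumeGrid
from .sensitivity import SweepPlan

__all__ = [
    "save_volume",
    "load_volume",
    "save_channels",
    "load_channels",
    "RunConfig",
    "save_config",
    "load_config",
]

_M_TO_MM = 1e3


def save_volume(path, values: np.ndarray, grid: VolumeGrid, meta: dict | None = None) -> Path:
    """Write a scalar volume as NIfTI (+ JSON sidecar for flags)."""
    path = Path(path)
    affine = np.diag([*(s * _M_TO_MM for s in grid.spacing), 1.0])
    affine[:3, 3] = [
        (o + s / 2.0) * _M_TO_MM for o, s in zip(grid.origin, grid.spacing)
    ]
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine)
    nib.save(img, str(path))
    sidecar = {"grid": grid.to_dict(), **(meta or {})}
    path.with_suffix("").with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True)
    )
    return path


def load_volume(path) -> tuple[np.ndarray, VolumeGrid, dict]:
    """Read a NIfTI volume saved by :func:`save_volume`."""
    path = Path(path)
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=float)
    side = path.with_suffix("").with_suffix(".json")
    if side.exists():
        meta = json.loads(side.read_text())
        grid = VolumeGrid.from_dict(meta.pop("grid"))
    else:
        aff = img.affine
        spacing = tuple(float(aff[a, a]) / _M_TO_MM for a in range(3))
        origin = tuple(
            float(aff[a, 3]) / _M_TO_MM - spacing[a] / 2.0 for a in range(3)
        )
        grid = VolumeGrid(
            extent=tuple(spacing[a] * values.shape[a] for a in range(3)),
            spacing=spacing,
            origin=origin,
        )
        meta = {}
    return values, grid, meta


def save_channels(path, channels: ChannelData, element_positions: np.ndarray) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=channels.traces)
        f.create_dataset("sampling_rate", data=channels.sampling_rate)
        f.create_dataset("t0", data=channels.t0)
        f.create_dataset("element_positions", data=element_positions)
        f.create_dataset(
            "seed", data=-1 if channels.seed is None else int(channels.seed)
        )
    return path


def load_channels(path) -> tuple[ChannelData, np.ndarray]:
    with h5py.File(path, "r") as f:
        seed = int(f["seed"][()])
        ch = ChannelData(
            traces=f["traces"][()],
            sampling_rate=float(f["sampling_rate"][()]),
            t0=float(f["t0"][()]),
            seed=None if seed < 0 else seed,
        )
        pos = f["element_positions"][()]
    return ch, pos


@dataclass
class RunConfig:
    """Everything needed to run an end-to-end study reproducibly."""

    transducer: TransducerSpec = dc_field(default_factory=TransducerSpec)
    medium: AcousticMedium = dc_field(default_factory=AcousticMedium)
    pulse: ExcitationPulse = dc_field(default_factory=ExcitationPulse)
    response: ElementResponse = dc_field(default_factory=ElementResponse)
    sweep: SweepPlan = dc_field(default_factory=SweepPlan)
    grid_spacing: float = 5e-3
    f_number: float | None = DEFAULT_F_NUMBER
    sampling_rate: float = 5e6
    noise_std: float = 0.0
    n_averages: int = 1
    seed: int = 0
    compensation_source: str = "simulated"  # or "virtual"
    floor_epsilon: float = 0.05
    dd_percent: float = 5.0
    dta_mm: float = 5.0
    low_dose_threshold: float = 10.0
    dvh_bins: int = 101

    def __post_init__(self) -> None:
        if self.compensation_source not in ("simulated", "virtual"):
            raise ValueError("compensation_source must be 'simulated' or 'virtual'")
        if self.n_averages < 1:
            raise ValueError("n_averages must be >= 1")

    def to_dict(self) -> dict:
        return {
            "transducer": self.transducer.to_dict(),
            "medium": self.medium.to_dict(),
            "pulse": self.pulse.to_dict(),
            "response": self.response.to_dict(),
            "sweep": self.sweep.to_dict(),
            "grid_spacing": self.grid_spacing,
            "f_number": self.f_number,
            "sampling_rate": self.sampling_rate,
            "noise_std": self.noise_std,
            "n_averages": self.n_averages,
            "seed": self.seed,
            "compensation_source": self.compensation_source,
            "floor_epsilon": self.floor_epsilon,
            "dd_percent": self.dd_percent,
            "dta_mm": self.dta_mm,
            "low_dose_threshold": self.low_dose_threshold,
            "dvh_bins": self.dvh_bins,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        return cls(
            transducer=TransducerSpec.from_dict(d.pop("transducer", {})),
            medium=AcousticMedium.from_dict(d.pop("medium", {})),
            pulse=ExcitationPulse.from_dict(d.pop("pulse", {})),
            response=ElementResponse.from_dict(d.pop("response", {})),
            sweep=SweepPlan.from_dict(d.pop("sweep", SweepPlan().to_dict())),
            **d,
        )


def save_config(path, config: RunConfig) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return path


def load_config(path) -> RunConfig:
    with open(path) as f:
        return RunConfig.from_dict(yaml.safe_load(f))
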