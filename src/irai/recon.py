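"""3D delay-and-sum reconstruction with envelope detection and
voxel-wise sensitivity compensation.

The default beamformer is complex (analytic-signal) delay-and-sum: each RF
trace is converted to its analytic signal, sampled at the geometric
time-of-flight of every voxel with linear inter-sample interpolation, summed
across elements, and the magnitude of the complex sum taken as the voxel
amplitude.  Enveloping before summation is phase-robust; an RF-then-envelope
variant (real sum, envelope along depth) is available for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .array_model import DEFAULT_F_NUMBER, ElementGrid, aperture_mask
from .forward import AcousticMedium, ChannelData
from .grids import VolumeGrid
from .sensitivity import CorrectionVolume

__all__ = ["ReconVolume", "das_reconstruct", "envelope", "compensate"]

log = logging.getLogger(__name__)


@dataclass
class ReconVolume:
    """Envelope-detected reconstruction amplitude (a.u.) on a grid."""

    amplitude: np.ndarray
    grid: VolumeGrid
    compensated: bool = False
    normalization: str = "none"

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.amplitude.shape != self.grid.shape:
            raise ValueError("amplitude shape does not match grid")
        if np.any(self.amplitude < 0):
            raise ValueError("envelope amplitude must be non-negative")

    def normalize(self) -> "ReconVolume":
        m = float(self.amplitude.max())
        if m <= 0:
            raise ValueError("cannot normalize an all-zero volume")
        return ReconVolume(
            self.amplitude / m, self.grid, self.compensated, normalization="max"
        )


def envelope(trace: np.ndarray) -> np.ndarray:
    """Amplitude envelope: magnitude of the analytic signal."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    return np.abs(hilbert(trace))


def das_reconstruct(
    channels: ChannelData,
    elements: ElementGrid,
    volume: VolumeGrid,
    medium: AcousticMedium,
    apodization: str = "none",
    mode: str = "complex",
    chunk_voxels: int = 2048,
    f_number: float | None = DEFAULT_F_NUMBER,
) -> ReconVolume:
    """Delay-and-sum beamforming of channel data onto a voxel grid.

    Per voxel, traces are sampled at ``t = r / c`` (element-to-voxel
    time-of-flight) with linear interpolation and summed across the
    receive aperture with uniform weights.  The aperture expands with depth
    at constant F-number (elements within ``z / (2 f_number)`` of the
    voxel's lateral projection); ``f_number=None`` uses every element.
    Delays falling outside the recorded traces contribute zero; the number
    of fully out-of-range voxels is logged.
    """
    if channels.n_elements != elements.n_elements:
        raise ValueError(
            f"channel count {channels.n_elements} does not match element "
            f"count {elements.n_elements}"
        )
    if apodization not in ("none", "uniform"):
        raise ValueError("apodization must be 'none' or 'uniform'")
    if mode not in ("complex", "rf"):
        raise ValueError("mode must be 'complex' or 'rf'")

    if mode == "complex":
        data = hilbert(channels.traces, axis=1)
    else:
        data = channels.traces
    ne, nt = data.shape
    fs = channels.sampling_rate
    epos = elements.positions
    points = volume.voxel_centers()
    c = medium.sound_speed
    eidx = np.arange(ne)[None, :]

    out = np.empty(points.shape[0], dtype=complex if mode == "complex" else float)
    n_zeroed = 0
    for a in range(0, points.shape[0], chunk_voxels):
        b = min(a + chunk_voxels, points.shape[0])
        d = points[a:b, None, :] - epos[None, :, :]
        r = np.sqrt(np.einsum("peq,peq->pe", d, d))
        s = (r / c - channels.t0) * fs
        i0 = np.floor(s).astype(int)
        frac = s - i0
        valid = (i0 >= 0) & (i0 < nt - 1)
        i0c = np.clip(i0, 0, nt - 2)
        vals = data[eidx, i0c] * (1.0 - frac) + data[eidx, i0c + 1] * frac
        vals = np.where(valid, vals, 0.0)
        if f_number is not None:
            vals = np.where(aperture_mask(points[a:b], epos, f_number), vals, 0.0)
        n_zeroed += int(np.count_nonzero(~valid.any(axis=1)))
        out[a:b] = vals.sum(axis=1)
    if n_zeroed:
        log.info("das_reconstruct: %d voxels had all delays out of range", n_zeroed)

    if mode == "complex":
        amp = np.abs(out).reshape(volume.shape)
    else:
        rf = out.reshape(volume.shape)
        amp = np.abs(hilbert(rf, axis=2))
    return ReconVolume(amplitude=amp, grid=volume)


def compensate(volume: ReconVolume, correction: CorrectionVolume) -> ReconVolume:
    """Voxel-wise multiplication by reciprocal-sensitivity factors."""
    if volume.compensated:
        raise ValueError("volume is already compensated")
    if volume.grid.shape != correction.grid.shape or not np.allclose(
        volume.grid.origin, correction.grid.origin
    ) or not np.allclose(volume.grid.spacing, correction.grid.spacing):
        raise ValueError("volume and correction grids do not match")
    return ReconVolume(
        amplitude=volume.amplitude * correction.factors,
        grid=volume.grid,
        compensated=True,
        normalization=volume.normalization,
    )
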