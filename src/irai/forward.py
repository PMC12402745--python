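"""Linear radioacoustic forward model.

Converts a dose volume into per-element RF channel data for a planar matrix
array in a homogeneous, lossless medium.  The chain is the standard
linear-systems treatment of thermoacoustic generation:

1. dose -> initial pressure, ``p0 = Gamma * rho * D`` (Gy = J/kg, so
   ``rho * D`` is a volumetric absorbed-energy density and Gamma the
   Grueneisen efficiency);
2. each voxel radiates as a point source, contributing
   ``p0 * V_voxel / (4 pi r)`` delayed by ``r / c`` at each element;
3. the finite x-ray pulse violates stress confinement, so the delta-excitation
   response is convolved with the time derivative of the pulse envelope;
4. the element's band-limited receive response and angular sensitivity are
   applied.

Superposition of retarded point sources is exact for a homogeneous medium up
to voxel discretization, so no wave solver is needed at this scale.  All
waveforms are referenced so that a point source at range r produces an
envelope peak at exactly ``t = r / c`` (the excitation and receive responses
are applied zero-phase / centered).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .array_model import (
    ElementGrid,
    ElementResponse,
    TransducerSpec,
    receive_impulse,
)
from .grids import VolumeGrid

__all__ = [
    "AcousticMedium",
    "ExcitationPulse",
    "ChannelData",
    "DoseVolume",
    "initial_pressure",
    "propagate",
    "acquire",
    "effective_averages",
]


@dataclass(frozen=True)
class AcousticMedium:
    """Homogeneous acoustic medium.

    Defaults are the solidified-vegetable-oil phantom: c = 1445 m/s,
    rho = 920 kg/m^3.  The Grueneisen parameter is not reported for the
    phantom; 0.9 is a representative value for oil-based media.
    """

    sound_speed: float = 1445.0
    density: float = 920.0
    grueneisen: float = 0.9

    def __post_init__(self) -> None:
        if self.sound_speed <= 0 or self.density <= 0 or self.grueneisen <= 0:
            raise ValueError("medium parameters must be positive")

    def to_dict(self) -> dict:
        return {
            "sound_speed": self.sound_speed,
            "density": self.density,
            "grueneisen": self.grueneisen,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcousticMedium":
        return cls(**d)


@dataclass(frozen=True)
class ExcitationPulse:
    """X-ray excitation pulse: 4 us duration at a 330 Hz repetition rate.

    ``shape`` names the envelope on [0, duration]: "hann" (default, smooth
    beam ramp-up/down) or "rect".  Only a single pulse period is simulated;
    the repetition rate is bookkeeping for averaging arithmetic.
    """

    duration: float = 4e-6
    repetition_rate: float = 330.0
    shape: str = "hann"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.repetition_rate <= 0 or 1.0 / self.repetition_rate <= self.duration:
            raise ValueError("pulse period must exceed the pulse duration")
        if self.shape not in ("hann", "rect"):
            raise ValueError(f"unknown pulse shape: {self.shape!r}")

    def envelope(self, sampling_rate: float) -> np.ndarray:
        """Sampled envelope on [0, duration]."""
        n = max(int(round(self.duration * sampling_rate)) + 1, 3)
        t = np.linspace(0.0, self.duration, n)
        if self.shape == "hann":
            return 0.5 - 0.5 * np.cos(2.0 * np.pi * t / self.duration)
        return np.ones_like(t)

    def to_dict(self) -> dict:
        return {
            "duration": self.duration,
            "repetition_rate": self.repetition_rate,
            "shape": self.shape,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExcitationPulse":
        return cls(**d)


@dataclass
class ChannelData:
    """Per-element RF traces (element x time) with sampling metadata."""

    traces: np.ndarray
    sampling_rate: float
    t0: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise ValueError("traces must be 2D (element x time)")
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("traces must be finite")

    @property
    def n_elements(self) -> int:
        return self.traces.shape[0]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate


@dataclass
class DoseVolume:
    """Voxelized dose (Gy) on a physical grid."""

    dose: np.ndarray
    grid: VolumeGrid

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != self.grid.shape:
            raise ValueError(
                f"dose shape {self.dose.shape} does not match grid {self.grid.shape}"
            )
        if np.any(self.dose < 0):
            raise ValueError("dose must be non-negative")

    @property
    def max_dose(self) -> float:
        return float(self.dose.max())


def initial_pressure(dose: DoseVolume, medium: AcousticMedium) -> np.ndarray:
    """Initial pressure p0 = Gamma * rho * D (Pa) per voxel."""
    return medium.grueneisen * medium.density * dose.dose


def _system_wavelet(
    spec: TransducerSpec,
    pulse: ExcitationPulse,
    sampling_rate: float,
    apply_bandwidth: bool,
) -> tuple[np.ndarray, int]:
    """Centered excitation-times-receive wavelet and its center index.

    conv(d/dt pulse envelope, receive impulse response), both centered so the
    envelope of the result peaks at index ``center``.
    """
    env = pulse.envelope(sampling_rate)
    denv = np.gradient(env, 1.0 / sampling_rate)
    c_env = (env.size - 1) / 2.0
    if apply_bandwidth:
        ir = receive_impulse(spec, sampling_rate)
        w = np.convolve(denv, ir.samples)
        center = c_env + (ir.samples.size - 1) / 2.0
    else:
        w = denv
        center = c_env
    return w, int(round(center))


def propagate(
    p0: np.ndarray,
    dose_grid: VolumeGrid,
    elements: ElementGrid,
    spec: TransducerSpec,
    medium: AcousticMedium,
    pulse: ExcitationPulse | None = None,
    sampling_rate: float = 20e6,
    response: ElementResponse | None = None,
    apply_bandwidth: bool = True,
    time_pad: float = 2e-5,
) -> ChannelData:
    """Forward-model channel data from an initial-pressure volume.

    Each element trace is the retarded-potential superposition over all
    non-zero source voxels, synthesized exactly in the frequency domain (no
    delay quantization).  Voxel spacing coarser than a quarter wavelength at
    the center frequency triggers a discretization warning; a source voxel
    coinciding with an element is excluded with a warning.
    """
    if pulse is None:
        pulse = ExcitationPulse()
    if response is None:
        response = ElementResponse()
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != dose_grid.shape:
        raise ValueError("p0 shape does not match grid")
    lam = spec.wavelength(medium.sound_speed)
    if max(dose_grid.spacing) > lam / 4.0:
        warnings.warn(
            "voxel spacing exceeds lambda/4 at the center frequency; "
            "point-source discretization may be coarse",
            stacklevel=2,
        )

    centers = dose_grid.voxel_centers()
    vals = p0.ravel()
    nz = vals != 0
    src = centers[nz]
    amp0 = vals[nz] * float(np.prod(dose_grid.spacing))
    epos = elements.positions
    c = medium.sound_speed

    if src.size == 0:
        nt = int(round((time_pad + pulse.duration) * sampling_rate))
        return ChannelData(
            traces=np.zeros((elements.n_elements, max(nt, 16))),
            sampling_rate=sampling_rate,
        )
    if np.any(src[:, 2] <= 0):
        raise ValueError("all source voxels must lie in front of the array (z > 0)")

    # trace length from the grid bounds (not the active voxels) so that
    # superposed sub-volumes produce identically shaped traces
    lo = np.asarray(dose_grid.origin)
    hi = lo + np.asarray(dose_grid.extent)
    far = np.max(np.abs(np.stack([lo, hi])), axis=0)
    rmax = np.linalg.norm(far) + np.max(np.linalg.norm(epos[:, :2], axis=1))
    wavelet, w_center = _system_wavelet(spec, pulse, sampling_rate, apply_bandwidth)
    nt = int(np.ceil((rmax / c + time_pad) * sampling_rate)) + wavelet.size
    from scipy.fft import next_fast_len, rfft, irfft, rfftfreq

    nt = next_fast_len(nt)
    # zero-phase wavelet spectrum: center sample wrapped to index 0
    wbuf = np.zeros(nt)
    idx = (np.arange(wavelet.size) - w_center) % nt
    np.add.at(wbuf, idx, wavelet)
    WF = rfft(wbuf)
    freqs = rfftfreq(nt, 1.0 / sampling_rate)

    ne = epos.shape[0]
    traces_F = np.zeros((ne, freqs.size), dtype=complex)
    chunk = 512
    excluded = 0
    for a in range(0, src.shape[0], chunk):
        b = min(a + chunk, src.shape[0])
        d = src[a:b, None, :] - epos[None, :, :]  # (s, e, 3)
        r = np.linalg.norm(d, axis=2)
        bad = r < 1e-9
        if np.any(bad):
            excluded += int(bad.sum())
            r = np.where(bad, np.inf, r)
        dire = response(d[:, :, 0], d[:, :, 1], d[:, :, 2], r, spec, medium.sound_speed)
        amp = amp0[a:b, None] * dire / (4.0 * np.pi * r)
        tau = r / c
        # accumulate sum_s amp * exp(-2i pi f tau) per element; frequencies
        # are uniform, so the phasor advances by a constant complex factor
        # per bin (one multiply instead of one exp)
        df = freqs[1] - freqs[0] if freqs.size > 1 else 0.0
        phasor = amp.astype(complex)  # f = 0 term
        step = np.exp(-2j * np.pi * df * tau)
        for k in range(freqs.size):
            traces_F[:, k] += phasor.sum(axis=0)
            phasor *= step
    if excluded:
        warnings.warn(
            f"{excluded} source-voxel/element pairs coincided (r=0) and were excluded",
            stacklevel=2,
        )
    traces = irfft(traces_F * WF[None, :], nt)
    return ChannelData(traces=traces, sampling_rate=float(sampling_rate))


def effective_averages(n_pulses: int, multiplexer_ratio: int = 4) -> int:
    """Full-array acquisitions obtained from ``n_pulses`` excitation pulses
    through an N-to-1 channel multiplexer (1000 pulses at 4:1 -> 250)."""
    if n_pulses < 1 or multiplexer_ratio < 1:
        raise ValueError("n_pulses and multiplexer_ratio must be >= 1")
    return n_pulses // multiplexer_ratio


def acquire(
    channels: ChannelData,
    noise_std: float,
    n_averages: int | None = None,
    seed: int | None = None,
    n_pulses: int | None = None,
    multiplexer_ratio: int = 4,
) -> ChannelData:
    """Simulate averaged acquisition with additive white channel noise.

    Independent zero-mean Gaussian noise of standard deviation ``noise_std``
    is added per repetition and the mean over ``n_averages`` repetitions is
    returned; the mean of n i.i.d. noise draws is sampled directly as a
    single draw of standard deviation ``noise_std / sqrt(n)``, which is
    distributionally identical.  When configured from pulse counts the
    effective number of averages is ``n_pulses // multiplexer_ratio``.
    """
    if noise_std < 0:
        raise ValueError("noise_std must be non-negative")
    if n_averages is None:
        if n_pulses is None:
            raise ValueError("provide n_averages or n_pulses")
        n_averages = effective_averages(n_pulses, multiplexer_ratio)
    if n_averages < 1:
        raise ValueError("n_averages must be >= 1")
    if noise_std == 0:
        return ChannelData(
            traces=channels.traces.copy(),
            sampling_rate=channels.sampling_rate,
            t0=channels.t0,
            seed=seed,
        )
    rng = np.random.default_rng(seed)
    noise = rng.normal(
        0.0, noise_std / np.sqrt(n_averages), size=channels.traces.shape
    )
    return ChannelData(
        traces=channels.traces + noise,
        sampling_rate=channels.sampling_rate,
        t0=channels.t0,
        seed=seed,
    )
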