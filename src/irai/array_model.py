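"""2D matrix-array transducer model.

Geometry, receive spectrum and angular response of a planar matrix array of
square elements.  The array lies in the plane ``z = 0`` with its normal along
+z (into the medium); x is azimuth and y elevation.

The element angular response is the classical far-field model for a square
element in a rigid baffle: the separable sinc ``sin(x)/x`` with
``x = pi * (a/lambda) * sin(theta)``, exposed as
:func:`element_directivity` and as the default :class:`ElementResponse`
(soft-baffle and Gaussian variants are available).

Beamforming aperture.  A flat matrix array has no geometric focus, yet the
instrument's detection sensitivity peaks near 15 cm depth.  That behavior
is characteristic of expanding-aperture (constant-F-number) receive
beamforming: only elements within a cone of half-width ``z / (2 F)`` around
a voxel's lateral projection contribute coherently, so the effective
aperture grows with depth until the physical array is exhausted — the
"focal zone".  :data:`DEFAULT_F_NUMBER` = 1.2 places that transition at the
reported ~15 cm and is used consistently by the sensitivity sweep and the
delay-and-sum reconstruction; ``f_number=None`` selects the full aperture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import gaussian as _gaussian_window

__all__ = [
    "TransducerSpec",
    "ElementGrid",
    "ImpulseResponse",
    "ElementResponse",
    "build_array",
    "receive_impulse",
    "element_directivity",
    "envelope_sigma",
    "aperture_mask",
    "DEFAULT_F_NUMBER",
]

#: -6 dB width of a Gaussian equals 2*sqrt(2*ln 2) sigma.
_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: Receive F-number of the expanding-aperture beamformer; calibrated so the
#: coherent response of the 32 x 32 array peaks at the ~15 cm focal zone.
DEFAULT_F_NUMBER = 1.2


@dataclass(frozen=True)
class TransducerSpec:
    """Technical specification of a 2D matrix array.

    center_frequency : Hz
    fractional_bandwidth : -6 dB fractional bandwidth (0.5 means 50%)
    n_elements_x, n_elements_y : element counts per lattice axis
    element_size : side of the square element, m
    kerf : gap between elements, m
    """

    center_frequency: float = 0.35e6
    fractional_bandwidth: float = 0.5
    n_elements_x: int = 32
    n_elements_y: int = 32
    element_size: float = 3.45e-3
    kerf: float = 0.2e-3

    def __post_init__(self) -> None:
        if self.center_frequency <= 0:
            raise ValueError("center_frequency must be positive")
        if not 0 < self.fractional_bandwidth < 2:
            raise ValueError("fractional_bandwidth must be in (0, 2)")
        if self.n_elements_x < 1 or self.n_elements_y < 1:
            raise ValueError("element counts must be >= 1")
        if self.element_size <= 0 or self.kerf < 0:
            raise ValueError("element_size must be positive, kerf non-negative")

    @property
    def pitch(self) -> float:
        """Center-to-center element spacing: element_size + kerf."""
        return self.element_size + self.kerf

    @property
    def n_elements(self) -> int:
        return self.n_elements_x * self.n_elements_y

    @property
    def aperture(self) -> tuple[float, float]:
        """Physical aperture extent per axis: (n-1)*pitch + element_size."""
        return (
            (self.n_elements_x - 1) * self.pitch + self.element_size,
            (self.n_elements_y - 1) * self.pitch + self.element_size,
        )

    def wavelength(self, sound_speed: float) -> float:
        return sound_speed / self.center_frequency

    def to_dict(self) -> dict:
        return {
            "center_frequency": self.center_frequency,
            "fractional_bandwidth": self.fractional_bandwidth,
            "n_elements_x": self.n_elements_x,
            "n_elements_y": self.n_elements_y,
            "element_size": self.element_size,
            "kerf": self.kerf,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransducerSpec":
        return cls(**d)


@dataclass(frozen=True)
class ElementGrid:
    """Element center positions of a planar array.

    ``positions`` is an ``(n, 3)`` array in meters with all z = 0, centered
    on the origin; ``normal`` points into the medium (+z).
    """

    positions: np.ndarray
    normal: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (n, 3)")
        if not np.allclose(pos[:, 2], 0.0):
            raise ValueError("all elements must lie in the plane z = 0")
        object.__setattr__(self, "positions", pos)

    @property
    def n_elements(self) -> int:
        return self.positions.shape[0]


def build_array(spec: TransducerSpec) -> ElementGrid:
    """Lay out the element lattice of a matrix array.

    Returns element centers on a regular ``n_x x n_y`` lattice of the spec's
    pitch, centered at the origin in the plane z = 0.  Row-major (x fastest
    varying last axis... element index = ix * n_y + iy).
    """
    p = spec.pitch
    xs = (np.arange(spec.n_elements_x) - (spec.n_elements_x - 1) / 2.0) * p
    ys = (np.arange(spec.n_elements_y) - (spec.n_elements_y - 1) / 2.0) * p
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pos = np.stack([X.ravel(), Y.ravel(), np.zeros(X.size)], axis=1)
    return ElementGrid(positions=pos)


@dataclass(frozen=True)
class ImpulseResponse:
    """Band-limited receive waveform: pressure samples at ``sampling_rate``.

    The waveform is zero-phase: its envelope peaks at the center sample, and
    ``t0`` gives the (negative) time of the first sample relative to that
    peak so that convolutions introduce no group delay.
    """

    samples: np.ndarray
    sampling_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, float))

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sampling_rate


def envelope_sigma(spec: TransducerSpec) -> float:
    """Temporal standard deviation (s) of the Gaussian envelope implied by
    the spec's -6 dB fractional bandwidth.

    A Gaussian-enveloped tone has a Gaussian amplitude spectrum; the -6 dB
    full spectral width ``bw * f0`` maps to ``sigma_f = bw*f0 / (2*sqrt(2 ln 2))``
    and ``sigma_t = 1 / (2 pi sigma_f)``.
    """
    sigma_f = spec.fractional_bandwidth * spec.center_frequency / _FWHM_TO_SIGMA
    return 1.0 / (2.0 * np.pi * sigma_f)


def receive_impulse(spec: TransducerSpec, sampling_rate: float) -> ImpulseResponse:
    """Gaussian-windowed tone burst modeling the element receive response.

    Unit peak amplitude; spectral magnitude peaks at the center frequency and
    the -6 dB fractional bandwidth equals the spec's.

    Raises
    ------
    ValueError
        If ``sampling_rate < 10 x center_frequency`` (too close to aliasing
        for the later envelope and delay interpolation steps).
    """
    if sampling_rate < 10.0 * spec.center_frequency:
        raise ValueError(
            "sampling_rate must be at least 10x the center frequency "
            f"({10 * spec.center_frequency:.3g} Hz)"
        )
    sigma_t = envelope_sigma(spec)
    half = int(np.ceil(4.0 * sigma_t * sampling_rate))
    n = 2 * half + 1
    t = (np.arange(n) - half) / sampling_rate
    env = _gaussian_window(n, sigma_t * sampling_rate)
    samples = env * np.cos(2.0 * np.pi * spec.center_frequency * t)
    return ImpulseResponse(
        samples=samples, sampling_rate=float(sampling_rate), t0=-half / sampling_rate
    )


def element_directivity(
    spec: TransducerSpec,
    angle_from_normal: float | np.ndarray,
    frequency: float,
    sound_speed: float,
) -> float | np.ndarray:
    """Far-field rigid-baffle directivity of a square element.

    ``sin(x)/x`` with ``x = pi * (element_size/lambda) * sin(theta)``;
    returns 1 at normal incidence.  For the 0.35 MHz / 3.45 mm element the
    element is smaller than a wavelength, so the response has no null at any
    real angle.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    theta = np.asarray(angle_from_normal, dtype=float)
    if np.any(theta < 0) or np.any(theta >= np.pi / 2):
        raise ValueError("angle_from_normal must lie in [0, pi/2)")
    lam = sound_speed / frequency
    x = np.pi * (spec.element_size / lam) * np.sin(theta)
    out = np.sinc(x / np.pi)  # np.sinc is sin(pi u)/(pi u)
    return float(out) if np.isscalar(angle_from_normal) else out


@dataclass(frozen=True)
class ElementResponse:
    """Angular amplitude response used inside field sums.

    kind:
      ``"sinc"``      rigid-baffle separable sinc in the two lateral angles
                      (default — the classical far-field square-element
                      model),
      ``"sinc-soft"`` sinc times cos(theta) obliquity (soft baffle),
      ``"gaussian"``  exp(-theta^2 / 2 sigma^2) in the polar angle.
    """

    kind: str = "sinc"
    sigma_deg: float = 15.0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "sinc", "sinc-soft"):
            raise ValueError(f"unknown element response kind: {self.kind!r}")
        if self.sigma_deg <= 0:
            raise ValueError("sigma_deg must be positive")

    def __call__(
        self,
        dx: np.ndarray,
        dy: np.ndarray,
        dz: np.ndarray,
        r: np.ndarray,
        spec: TransducerSpec,
        sound_speed: float,
    ) -> np.ndarray:
        """Amplitude factor for propagation vectors (dx, dy, dz) of length r."""
        ct = np.clip(dz / r, -1.0, 1.0)
        if self.kind == "gaussian":
            theta = np.arccos(ct)
            s = np.deg2rad(self.sigma_deg)
            return np.exp(-(theta**2) / (2.0 * s * s))
        lam = spec.wavelength(sound_speed)
        a = np.pi * spec.element_size / lam
        d = np.sinc(a * (dx / r) / np.pi) * np.sinc(a * (dy / r) / np.pi)
        if self.kind == "sinc-soft":
            d = d * ct
        return d

    def to_dict(self) -> dict:
        return {"kind": self.kind, "sigma_deg": self.sigma_deg}

    @classmethod
    def from_dict(cls, d: dict) -> "ElementResponse":
        return cls(**d)


def aperture_mask(
    points: np.ndarray,
    element_positions: np.ndarray,
    f_number: float | None,
) -> np.ndarray:
    """Boolean (points x elements) receive-aperture selection.

    Constant-F-number rule: an element contributes to a point at depth z if
    its lateral distance from the point's projection onto the array plane
    is at most ``z / (2 * f_number)``.  ``f_number=None`` keeps every
    element (full aperture).
    """
    if f_number is None:
        return np.ones((points.shape[0], element_positions.shape[0]), dtype=bool)
    if f_number <= 0:
        raise ValueError("f_number must be positive (or None for full aperture)")
    lat = np.hypot(
        points[:, None, 0] - element_positions[None, :, 0],
        points[:, None, 1] - element_positions[None, :, 1],
    )
    return lat <= points[:, None, 2] / (2.0 * f_number)
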