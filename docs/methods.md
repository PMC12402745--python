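# Methods

`irai` is a synthetic twin of a sensitivity-compensated quantitative
ionizing-radiation acoustic imaging (iRAI) pipeline: it characterizes the
volumetric detection sensitivity of a 2D matrix-array transducer, forward
models the acoustic signals generated by pulsed x-ray dose deposition in a
homogeneous phantom, reconstructs volumetric images by delay-and-sum (DAS)
with envelope detection, compensates them voxel-wise by the reciprocal of
the normalized sensitivity, and quantifies agreement with the planned dose
(DVH, DVH-RMSE, 3D global gamma, SSIM, isodose contours, region means,
profiles).

## Instrument model

**Array.** A planar 32 × 32 lattice of 3.45 mm square elements with 0.2 mm
kerf (pitch 3.65 mm, aperture 116.6 mm per side) in the plane z = 0, normal
+z. Coordinates: x = azimuth, y = elevation, z = depth.

**Receive spectrum.** Gaussian-enveloped cosine at 0.35 MHz; the −6 dB
fractional bandwidth of the amplitude spectrum is 50%, which fixes the
temporal envelope sigma at 2.14 µs. The waveform is applied zero-phase so
no stage introduces group delay: a point source at range r produces an
envelope peak at exactly t = r/c.

**Element directivity.** Far-field rigid-baffle separable sinc,
`sin(x)/x` with `x = π (a/λ) sin θ` per lateral angle. At 0.35 MHz in the
phantom (λ = 4.13 mm) the 3.45 mm element is sub-wavelength, so the
response has no null. Soft-baffle (× cos θ) and Gaussian variants are
selectable.

**Receive aperture (F-number).** A flat matrix array has no geometric
focus, yet the instrument this package models detects most sensitively
near 15 cm depth. That behavior is characteristic of expanding-aperture
(constant-F-number) receive beamforming: a voxel at depth z is beamformed
from the elements within `z / (2F)` of its lateral projection, so the
effective aperture grows with depth until the physical array is exhausted —
producing a "focal zone" at `z ≈ F × aperture`. The default `F = 1.2` is
calibrated to place the on-axis peak of the coherent response at ~15 cm;
`f_number=None` selects the full aperture. The same aperture rule is used
by the sensitivity sweep, the virtual point-source protocol and DAS, which
is what makes reciprocal-sensitivity compensation self-consistent (the DAS
point response tracks the sweep map to a constant factor; verified to
0.3% in tests). With the full aperture instead, the lateral point-spread
function (PSF) grows ~linearly with depth and extended sources gain
amplitude with depth beyond what point sensitivity explains, so
compensation cannot equalize the beam studies; this, and the focal-zone
depth, motivated the default.

## Sensitivity characterization

**Dynamic-focusing sweep.** Azimuth and elevation each sweep the half-open
interval [0°, 180°) (so a 0.5° step gives exactly 360 × 360 = 129 600
events). An angle pair maps to a steering direction via the tangent
parametrization `d ∝ (tan(az−90°), tan(el−90°), 1)`, which covers the
forward hemisphere without pole singularities. Each event applies a
dynamic focal law along its ray; a voxel's value is the temporal peak of
the envelope of the coherent element sum, with the band-limited envelope
penalizing residual delay misalignment. The map is the voxel-wise maximum
over events, normalized to 1. Receive sensitivity is obtained from this
transmit-style focused-field picture by acoustic reciprocity.

Exhaustive evaluation of events × voxels × elements is quadratic overkill:
the focused response decays away from the steered ray, so the production
algorithm evaluates, per voxel, only events steering within a small
angular neighborhood (±2 grid steps) of the voxel's own direction.
Pruned and exhaustive agree on coarse configurations whenever the step is
below the array beamwidth (tested); at steps well above the beamwidth the
voxel-wise max becomes dominated by incidental phase alignment with far
events — an artifact of coarse sweeps, not of the pruning.

**Virtual point-source protocol.** A unit point source is simulated on a
lattice of positions (the physical protocol's 15 × 15 × 25 cm space at
2.5 cm steps gives 7 × 7 × 11 = 539 positions), channel data are formed
(optionally with white noise averaged over n acquisitions; 1000 pulses
through the 4:1 multiplexer correspond to n = 250), each acquisition is
reconstructed over a small box whose central voxel coincides with the
source, and the image maximum is the sensitivity there. Sparse maps are
densified by trilinear interpolation with edge clamping.

**Correction factors.** `1 / max(s, ε)` with ε = 0.05 by default: the
reciprocal of a normalized map is unbounded where sensitivity vanishes
(near the array face, extreme lateral corners), and unbounded factors only
amplify clutter. Capped voxel counts are logged and reported.

## Forward model

Dose D (Gy) converts to initial pressure `p0 = Γ ρ D` (Gy = J/kg, so ρD is
volumetric absorbed energy density); Γ defaults to 0.9, a representative
Grüneisen value for oil-based media (the phantom: solidified vegetable
oil, ρ = 920 kg/m³, c = 1445 m/s). Each voxel radiates as a point source,
`p0 · V / (4π r)` delayed by `r/c`, weighted by element directivity; the
4 µs x-ray pulse violates stress confinement, so the delta response is
convolved with the time derivative of the pulse envelope (Hann by
default) and with the element receive response. Traces are synthesized
exactly in the frequency domain (no delay quantization), using a
recursive phasor over the uniform frequency grid. Superposition of
retarded point sources is exact for a homogeneous lossless medium, so no
wave solver is required; heterogeneity, attenuation and shear are out of
scope. Voxel spacing coarser than λ/4 triggers a warning — the 5 mm study
grids accept this discretization deliberately (sources are dose voxels,
not scatterers; the study quantities are region statistics).

Acquisition averaging adds the distributional equivalent of per-repetition
white noise: the mean of n i.i.d. draws is sampled directly at σ/√n.

## Reconstruction and compensation

Complex (analytic-signal) DAS: traces → analytic signals, sampled at
`t = r/c` with linear inter-sample interpolation, summed over the
F-number aperture, amplitude = magnitude (envelope before summation; an
RF-then-envelope mode exists for comparison). Out-of-range delays
contribute zero and are counted. Compensation is voxel-wise
multiplication by the correction volume on a matching grid; double
compensation is refused.

## Studies and quantification

Beam studies on the 17 × 17 × 20 cm phantom box (5 mm voxels): square
columns of uniform dose (2.26 Gy) traversing the phantom along the
vertical (y) axis — seven depths (5–17 cm), seven lateral positions at
11 cm (2 cm apart), five field sizes (1–5 cm) at 11 cm. Region means are
taken over the dose mask (≥50% of the beam dose) and quoted relative to
the family mean, so "all amplitudes approaching 1" is an unbiased
statement for every member (max-normalization would structurally bias the
minimum low; coefficients of variation and slope ratios are
normalization-invariant). The C-shaped plan (outer radius 5 cm, inner
2.5 cm, 90° gap, 5 cm height, 3 mm Gaussian edge, 21.6 Gy maximum — a
synthetic stand-in; the clinical plan's geometry is not published) is
evaluated on a 15³ cm volume against the planned dose by DVH-RMSE
(percentage points of volume fraction, 101 bins), 3D global gamma
(5%/5 mm, global normalization to the reference maximum, 10% low-dose
threshold, search radius 3 × DTA at DTA/3 steps, trilinear sub-voxel
interpolation, exhaustive search retained as a test oracle), slice-wise
Gaussian-window SSIM, and 80% isodose contours (marching squares,
exported as CSV polylines).

Because iRAI is relative dosimetry, the scale of a reconstruction is
arbitrary; the C-shape report carries both conventions — division by the
volume maximum, and the least-squares scale factor over the evaluated
(above-threshold) region ("matched"), which removes the influence of
isolated out-of-target maxima.

Reconstruction for the beam families is restricted to the beam-column
sub-block of the grid (region means and in-beam profiles need nothing
else); the C-shape study reconstructs the full volume.

## Problem sizes and determinism

Default study resolution is 5 mm voxels with a 0.5° sweep (the pruned
sweep's cost is independent of step); the sensitivity-map DVH check runs
at 5 mm / 2°. Full-paper resolution is a config change away. Every
stochastic stage takes an explicit seed, per-beam seeds derive from the
run seed, and a repeated run writes a byte-identical JSON report.

## What the synthetic twin does and does not show

The generator emulates: the array geometry and spectrum of the instrument,
homogeneous-phantom radioacoustic generation with the finite pulse, the
beam-study layouts, a C-shaped plan topology, and noise averaging. It does
not emulate: heterogeneous tissue, acoustic attenuation, transducer
element-to-element gain spread (the instrument's observed low-sensitivity
edge elements), LINAC beam transport (no percentage-depth-dose by
default), film dosimetry, or the clinical treatment-planning system's dose
gradients.

Consequences worth stating plainly:

* **Sensitivity-map DVH.** The measured instrument reportedly has ~80% of
  the 15 × 15 × 25 cm volume above half its maximum sensitivity. Every
  coherent-sum surrogate explored here (any directivity or aperture rule
  consistent with the printed geometry and frequency) yields 30–68%,
  because 1/r depth decay plus any angular response leaves a substantial
  near-face and far-corner fraction below half maximum. The default model
  computes 29.9% at the reduced resolution. The discrepancy is reported,
  not tuned away; models scoring closer to 80% on this single number are
  exactly those that contradict the reported 15 cm focal zone and the
  rising depth trend.
* **Within-beam depth profiles of large beams.** The radioacoustic wavelet
  is zero-mean, so uniform interiors cancel and sharp beam boundaries
  dominate ("boundary buildup"). For ≥3 cm synthetic beams this specular
  structure swamps the sensitivity trend inside the beam, and compensation
  reveals rather than flattens it. The depth- and lateral-family
  equalization (the core claim) is reproduced; the within-beam profile
  flattening of large uniform sharp-edged columns is not.
* **C-shape global metrics.** For the uniform sharp-edged synthetic C, the
  in-target reconstruction variation is interference-dominated rather than
  sensitivity-dominated, and reciprocal factors amplify out-of-target
  clutter; the measured pre→post improvements in gamma pass rate and
  DVH-RMSE are therefore not reproduced by this twin. Both pre/post values
  under both scalings are computed and reported for inspection.

## Numerical choices

Gamma uses an epsilon of 1e-9 on the γ ≤ 1 pass test so exact boundary
cases are not lost to rounding; the displacement search enumerates
candidates coarsest-first and stops when the distance term alone exceeds
the worst remaining γ. DVH uses `≥` (complementary cumulative) on equally
spaced bins from 0 to the maximum. Voxels coinciding with element
positions are excluded from field sums with a warning and refilled from
the nearest valid neighbor. Degenerate inputs (empty volumes, empty masks,
unnormalized maps, double compensation, grid mismatches) raise
`ValueError` with instructive messages.
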