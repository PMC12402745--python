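# irai

Sensitivity-compensated quantitative ionizing-radiation acoustic imaging
(iRAI), end to end and fully synthetic.

iRAI images the pressure waves generated when pulsed x-ray beams deposit
dose in tissue: a passive ultrasound array records the radioacoustic
signals and delay-and-sum (DAS) beamforming maps them back to the dose
distribution in 3D, in real time and in vivo. The catch for *quantitative*
dose mapping is that a matrix-array transducer does not hear every voxel
equally well — its detection sensitivity varies strongly over the imaging
volume — so uncorrected reconstructions misrepresent dose by position.
This package implements the whole correction pipeline for a 0.35 MHz
32 × 32 matrix array and a homogeneous soft-tissue phantom:

1. **Sensitivity mapping** (`irai.sensitivity`) — simulate the volumetric
   detection-sensitivity map S(**r**) by a dynamic-focusing angular sweep
   with voxel-wise max projection, or by a virtual point-source
   measurement protocol; derive correction factors `1 / max(S, ε)`.
2. **Forward model** (`irai.forward`) — dose → initial pressure
   `p₀ = Γ ρ D`, then retarded-potential superposition of voxel sources
   convolved with the 4 µs x-ray pulse derivative and the element's
   band-limited receive response, to per-element RF channel data.
3. **Reconstruction** (`irai.recon`) — complex (analytic-signal) 3D DAS
   with envelope detection and constant-F-number expanding receive
   aperture; voxel-wise compensation by the reciprocal-sensitivity volume.
4. **Phantoms** (`irai.phantoms`) — square-beam study layouts (depth,
   lateral, field-size families) and a C-shaped treatment-plan target
   (21.6 Gy maximum).
5. **Evaluation** (`irai.evaluate`) — DVH and DVH-RMSE, 3D global gamma
   index (5%/5 mm dose-difference / distance-to-agreement), SSIM, 80%
   isodose contours, region-mean amplitudes and line profiles.
6. **Driver + CLI** (`irai.experiments`, `irai.cli`) — reproducible
   end-to-end studies with JSON reports; `irai phantom / sensitivity-sim /
   sensitivity-virtual / forward-sim / reconstruct / compensate /
   evaluate / run`.

The central quantity is the gamma index between a reference dose
distribution `D_r` and an evaluated one `D_e`:

    γ(r) = min over displacements Δ of
           sqrt( (D_e(r+Δ) − D_r(r))² / (0.05·D_max)²  +  |Δ|² / (5 mm)² )

with a voxel passing when γ ≤ 1, and the cumulative dose-volume histogram
DVH(d) = % of volume receiving ≥ d.

## Worked example

Run the depth study — seven identical 1 × 1 cm beams at 5–17 cm from the
array — at coarse desk settings, and compare the beam-region amplitudes
before and after sensitivity compensation:

```python
import numpy as np
from irai import RunConfig, SweepPlan
from irai.experiments import run_experiment

config = RunConfig(grid_spacing=0.01, sweep=SweepPlan(step=2.0), seed=1)
report = run_experiment(config, "depth")["depth"]
print("pre :", np.round(report["pre_means"], 3))
print("post:", np.round(report["post_means"], 3))
print(f"CoV  {report['cov_pre']:.3f} -> {report['cov_post']:.3f}")
print(f"slope {report['slope_pre']:.2f} -> {report['slope_post']:.2f}  (1/m)")
```

Output:

```
pre : [0.468 0.667 0.871 1.033 1.206 1.373 1.382]
post: [0.899 1.086 1.074 0.975 0.975 0.987 1.003]
CoV  0.325 -> 0.059
slope 8.01 -> 0.02  (1/m)
```

Reading it: before compensation the apparent amplitude of *identical*
beams rises almost 3× with depth (the array's sensitivity peaks near its
15 cm focal zone), a slope of 8 per meter. After voxel-wise multiplication
by the reciprocal-sensitivity factors, every position reads within ~10% of
1 and the depth trend is gone — which is the point of quantitative iRAI:
equal dose should read equal, wherever it lands.

The same driver runs the lateral and field-size families and the C-shaped
plan study (`study="lateral" | "size" | "cshape"`); the C-shape report
contains DVH-RMSE, gamma pass rate and SSIM against the plan, before and
after compensation, under two scaling conventions, plus exported 80%
isodose contours.

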