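# raffmap

Quantitative myocardial relaxometry with **RAFF2** — Relaxation Along a
Fictitious Field in the 2nd rotating frame — for researchers developing or
evaluating rotating-frame preparation sequences at clinical field strengths.
The package covers the whole desk-side workflow: RAFF2 pulse synthesis,
Bloch simulation of the five-contrast preparation sequence under B0/B1
imperfections, digital phantoms, voxel-wise T<sub>RAFF2</sub> map fitting
with residual-based SD maps, and the repeatability / precision /
myocardial-segment statistics used to characterize such a mapping method.

## The method

A RAFF2 preparation pulse is an amplitude- and frequency-modulated RF pulse
driven sub-adiabatically:

```
omega_1(t)      = omega_1max |sin(omega_1max t + phi_0)|      (AM)
Delta_omega(t)  = omega_1max  cos(omega_1max t + phi_0)       (FM)
phi(t)          = integral_0^t Delta_omega(t') dt'            (phase)
```

Because AM and FM form a sine/cosine pair of equal amplitude, the effective
field in the first rotating frame keeps constant magnitude
`omega_1max` while its tilt angle sweeps at rate `omega_1max`; in the
doubly rotating frame the effective-plus-fictitious field is stationary
with magnitude `sqrt(2) * omega_1max`.  Magnetization precessing about that
stationary field relaxes with the characteristic time T<sub>RAFF2</sub>,
which is selectively sensitive to slow molecular motions — a candidate
non-contrast marker of myocardial infarction.  The default single-pulse
duration is `sqrt(2)/f1max` (two full revolutions about the
doubly-rotating-frame field): 2.26 ms at `f1max` = 625 Hz.

The mapping sequence acquires five single-shot images: one without
preparation, three after spoiled RAFF2 trains of 8/16/24 pulses
(total preparation times 22.98/46.66/70.34 ms with 0.7 ms spoilers), and
one after a saturation pre-pulse (an infinitely long preparation).
Per-voxel maps come from the three-parameter magnitude fit

```
S(Tp) = A * exp(-Tp / T_RAFF2) + B
```

where the saturation image enters as `S = B` exactly, and the SD map is the
(bias-corrected) standard error of T<sub>RAFF2</sub> propagated from the
fit residuals.

## Worked example

```python
import numpy as np
from raffmap import (PulseConfig, SequenceProtocol, make_vial_phantom,
                     simulate_series, fit_traff2)

maps = make_vial_phantom(grid_size=96)                # nine-vial phantom
series = simulate_series(maps, SequenceProtocol(), PulseConfig(f1max=625.0),
                         mode="phenomenological", seed=7,
                         noise_sigma=0.005, noise_model="rician")
res = fit_traff2(series)
print(res.summary())
print(res.roi_summary(maps.label_map).to_string(index=False))
```

prints

```
TRAFF2 three-parameter fit
==========================
contrasts (prep ms)   : [ 0.   23.   46.7  70.41   inf]
voxels fitted         : 2637
voxels converged      : 2637
TRAFF2 mean +/- SD    : 321.53 +/- 141.04 ms
median SD-map value   : 11.635 ms
median RMS residual   : 0.002661
 label  n_voxels  traff2_mean_ms  traff2_sd_ms  sd_map_median_ms
     1       293      101.900789      2.342054          2.106426
     2       293      158.151445      4.372176          4.019013
     ...
     9       293      530.863098     38.012989         35.799131
```

The five contrasts use the simulated train totals (the single pulse is
2.2627 ms, so 8/16/24-pulse trains give 23.0/46.7/70.4 ms).  Vial 1
(ground truth 101.7 ms) is recovered to within its SD-map uncertainty;
the longest vials (truth up to 550.8 ms) are increasingly uncertain and
slightly underestimated because the longest preparation (70 ms) samples
only the start of their decay — exactly the behaviour the SD map is meant
to flag.

The same pipeline is available from the shell:

```
raffmap demo --seed 7 --out demo/           # full synthetic pipeline
raffmap sweep --out sweep.csv               # B0/B1 inhomogeneity trends
raffmap fit --images series.nii --preps series.json --out maps/
```

`raffmap demo` writes per-vial repeatability CVs (typically below 1.5% at
the demo noise level), an AHA 16-segment bullseye of a short-axis annulus
phantom, and a 2SD scar mask of its synthetic lesion.

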