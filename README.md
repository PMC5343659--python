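# optotherm

Simulation and analysis of light delivery and tissue heating during
high-irradiance optogenetic photostimulation of the brain.

Optogenetic neuromodulation of deep cortical layers — especially with
red-shifted opsins stimulated through an epidural fiber — requires surface
irradiances of hundreds of mW/mm². Whether such protocols heat the tissue to
dangerous levels, and how deep the light actually reaches, are the central
dosimetry questions for anyone designing stimulation protocols. `optotherm`
is a toolkit for answering them *in silico* and for analyzing the kinds of
measurements used to answer them *in vivo*:

* **Photon transport** — voxelized Monte Carlo simulation of weighted photon
  packets launched from a multimode fiber (0.4 mm core, NA 0.48 by default)
  into homogeneous brain tissue: exponential step sampling with
  μt = μa + μs, Henyey–Greenstein scattering, continuous absorption
  deposition, Russian roulette, and unpolarized Fresnel refraction /
  total internal reflection at a planar brain–air interface.
* **Bioheat** — an explicit finite-difference solver for the Pennes equation
  in deviation form, ρc ∂T/∂t = k∇²T − ρc·ω·T + q, driven by the
  duty-cycle-weighted absorbed optical power, with a convective brain
  surface and perfusion sink.
* **Synthetic measurements** — thermal-camera movies (affine grey levels,
  0.08 °C NETD noise, 3 frames/s), beaker-cooling calibration series,
  light-distribution images, and LFP traces (1/f background plus band
  oscillations over baseline/stim/post phases), all deterministic given a
  seed and carrying their ground truth.
* **Analysis** — camera calibration fits, ΔT maps against a pre-stimulation
  baseline, hottest-spot 1 mm² ROI time courses with 8-s binning, the linear
  thermal-dose model ΔT_max = a·(E·duty) + b, opsin-threshold penetration
  depths by log-linear interpolation, Morlet-wavelet (ω₀ = 6) band power in
  the α/β/γ bands, and small-sample exact Wilcoxon and Friedman tests.

## Worked example

Simulate the strongest standard protocol — 600 mW/mm² continuous-equivalent
irradiance at 638 nm, 5 ms pulses at 40 Hz, 90 s of stimulation — and ask
what the camera would see and how deep the light reaches:

```python
import numpy as np
from optotherm import (FiberSource, StimulationProtocol, propagate,
                       TissueOpticalProperties, TissueThermalProperties, solve)
from optotherm.mc_light import absorbed_power_map
from optotherm.pipeline import coarsen, coarsen_grid
from optotherm.irradiance import IrradianceProfile, scale_to_absolute, threshold_depth

proto = StimulationProtocol(wavelength_nm=638, peak_irradiance_mw_mm2=600,
                            pulse_ms=5, freq_hz=40)
print(f"duty cycle: {proto.duty:.2f}   thermal dose (E x duty): "
      f"{proto.average_irradiance_mw_mm2:.0f} mW/mm^2")

props = TissueOpticalProperties.brain(638)
source = FiberSource()                       # axis 0.5 mm below the surface
fluence = propagate(200_000, source, props, seed=1)
print(f"total-reflection fraction: {fluence.total_reflection_fraction:.3f}")

d, v = fluence.axial_profile(source)
profile = scale_to_absolute(
    IrradianceProfile(d, np.clip(v, 0, None), axis="axial"), 600.0)
print(f"1 mW/mm^2 opsin threshold depth: {threshold_depth(profile, 1.0).depth_mm:.2f} mm")

q = coarsen(absorbed_power_map(fluence, props), 2) * 600.0
grid = coarsen_grid(fluence.grid, 2)
field = solve(q, TissueThermalProperties(), proto, grid,
              store="surface", surface_depth_mm=0.2)
print(f"max surface dT: {field.frames.max():.2f} C   "
      f"(at t = {field.times_s[field.frames.max(axis=(1,2)).argmax()]:.0f} s)")
```

Output:

```
duty cycle: 0.20   thermal dose (E x duty): 120 mW/mm^2
total-reflection fraction: 0.331
1 mW/mm^2 opsin threshold depth: 5.35 mm
max surface dT: 0.83 C   (at t = 90 s)
```

Reading: the protocol delivers a time-averaged 120 mW/mm²; about a third of
all launched packets touch the brain–air interface beyond the critical
angle at least once during their diffuse random walk; red light keeps
opsin-activating irradiance (≥1 mW/mm²) down to ~5 mm along the axis; and
the camera-facing surface warms by under 1 °C, peaking at the end of the
90 s stimulation. Higher-level drivers live in `optotherm.pipeline`
(protocol sweeps with camera-noise rendering and dose-model recovery,
threshold-depth comparisons, LFP null calibration) and behind the
`optotherm` command-line interface (`mc-light`, `bioheat`, `synth`,
`thermo-analyze`, `lfp-power`, `pipeline`).

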