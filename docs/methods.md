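# Methods

This note documents the models implemented in `optotherm`, the defaults
they run with, the numerical choices behind them, and what the synthetic
data do and do not establish about real measurements.

## Photon transport

Light from the fiber is simulated with a standard weighted-packet Monte
Carlo in a homogeneous, semi-infinite tissue block (default 12 × 12 × 6 mm,
0.1 mm voxels). Packets start uniformly on the fiber exit disc with
directions uniform in solid angle inside the emission cone of half-angle
asin(NA/n) ≈ 20.7° about the axis. Free paths are exponential with
μt = μa + μs; at each interaction a fraction μa/μt of the weight is
deposited and the direction is deflected by the Henyey–Greenstein phase
function; packets below weight 10⁻⁴ face Russian roulette with survival
factor 10 (weight bookkeeping is exact: launched = absorbed + escaped +
roulette-net to ~10⁻¹² relative). Fluence is scored by the pathlength
estimator Σw·Δl/V and scaled so the fiber-face fluence equals the source
irradiance; the absorbed-power map is q = μa·Φ.

The plane z = 0 is a smooth brain–air interface. A packet crossing it
beyond the critical angle asin(n_air/n_tissue) ≈ 47.3° is specularly
reflected and counted (once per packet) in the total-internal-reflection
tally; below the critical angle, unpolarized Fresnel reflection is sampled
and transmitted packets escape. All other grid faces terminate packets, the
usual convention for a voxelized transport volume.

A consequence worth stating explicitly: in this geometry — fiber axis
parallel to the interface and only 0.5 mm below it — the per-packet
total-reflection fraction is large, ~33% at the 638 nm defaults and
18–38% across geometry and ±50% property variations. This is forced by
diffusion physics, not by implementation detail: with μa = 0.06/mm and
μs′ = 0.84/mm the diffusion length √(D/μa) ≈ 2.5 mm far exceeds the 0.5 mm
depth, so most packets reach the interface at least once, and roughly half
of diffuse incidence lies beyond the critical angle. Quantities defined on
first-pass or ballistic light would be orders of magnitude smaller; the
package deliberately reports the unambiguous per-packet tally.

Default optical properties are literature-based homogeneous rat-cortex
values, overridable everywhere: 638 nm μa = 0.06/mm, μs = 7.0/mm, g = 0.88,
n = 1.36; 476 nm μa = 0.15/mm, μs = 10.0/mm, g = 0.88. Absorption and
scattering are both higher in the blue, which reproduces the qualitative
ordering that red light penetrates deeper at every tested irradiance.

## Bioheat

Temperature is the deviation ΔT from baseline, governed by the Pennes
equation ρc ∂T/∂t = k∇²T − ρc·ω·T + q_eff. Defaults: k = 0.5 mW/(mm·°C)
(= 0.5 W/(m·K)), ρc = 3.7 mJ/(mm³·°C) (diffusivity 0.135 mm²/s), perfusion
ω = 0.008 s⁻¹, surface convection h = 0.02 mW/(mm²·°C). The discretization
is explicit forward-time central-space; the time step defaults to 0.8× the
stability bound dx²ρc/(6k) and larger steps are refused. The z = 0 face is
convective (Robin, ambient offset folded into the deviation form); far
faces are Dirichlet ΔT = 0, placed ≥6 mm from the source (insulated
variants exist for the conservation tests). Frames are stored every 1/3 s
to match the 3 frames/s thermal camera; a `surface` storage mode keeps only
the per-column mean of the top 100 μm (or one voxel layer, whichever is
thicker) — the slab a surface thermal imager integrates.

During stimulation the optical source is applied duty-averaged
(q_eff = q·duty): pulse periods of 16.7–50 ms are far below the thermal
time constants of the heated region, and an explicit pulsed-gating mode
exists and agrees with the averaged source on end-of-stimulation fields for
spatially smooth sources to within a few percent. The disagreement is real
at single-voxel scale, where the sub-voxel time constant (~50 ms) is
comparable to the pulse period — a reason the pulsed mode exists for
verification but is not the default.

The solver was validated against an insulated-domain energy balance
(final enthalpy = injected energy within 1%) and the transient point-source
Green's function ΔT = P·erfc(r/2√(αt))/(4πkr) (within 5% at r ≥ 5 voxels),
and halving the voxel size changes peak ΔT by <3%.

Simulated tip-vs-surface contrast: the hottest tissue voxel reads only
~15% above the camera-style surface projection by the end of a 90 s
stimulation, because diffusion has largely flattened vertical gradients
over the top millimeter. In vivo the discrepancy is reported closer to
40–70%, driven by mechanisms outside this model (evaporative cooling of
the exposed surface, probe self-heating, layered anatomy).
`tip_correction` therefore keeps the conventional empirical factor 1.5 as
its default rather than a simulated value.

## Synthetic data

The camera model is affine (grey = gain·T + offset) with additive Gaussian
noise of 0.08 °C (the NETD of the emulated imager), 16-bit quantization,
3 frames/s, and 0.05 mm/pixel by default; the absolute surface baseline is
29 °C. Calibration series follow Newtonian beaker cooling
T(t) = ambient + (T0 − ambient)e^(−t/τ). LFP traces are 1/f^β Gaussian
background plus per-band narrowband Gaussian oscillations (bandwidth 20% of
the band center) whose RMS amplitude is piecewise constant over the
30/90/120 s baseline/stim/post phases; amplitude-modulated noise rather
than sinusoids so repeated trials genuinely vary. All generators are
deterministic given (spec, seed).

What passing tests show — and don't. The generators reproduce the *noise
statistics and phase structure* of the measurements, so end-to-end tests
demonstrate that the analysis chain is unbiased and correctly calibrated
against known ground truth at realistic noise levels. They do not contain
vasculature texture, motion, breathing artifacts, layered skull/CSF
anatomy, or physiological thermoregulation, so success here does not
certify the analysis against those real-world structured disturbances.

## Analysis chain

* Calibration: least-squares affine grey→°C fit on the cooling series.
* ΔT maps: per-pixel subtraction of the mean over the 10 s pre-stimulation
  baseline.
* ROI: circular, 1 mm² (radius 0.5642 mm), centered on the maximum of the
  3×3-mean-smoothed time-max projection — raw argmax is unstable at
  0.08 °C NETD; among smoothed ties the pixel with the highest raw value
  wins, then the lowest (row, col). Bins are left-aligned non-overlapping
  8 s windows anchored at stimulation onset (alignment is a package
  convention; nothing in the data fixes it).
* Dose model: OLS with free intercept of max binned ΔT on irradiance × duty,
  fitted on trial means, separately per wavelength. Fitting pooled trials
  or forcing the intercept are defensible alternatives; trial means with a
  free intercept were adopted.
* Frequency comparisons: per-bin exact two-sided Wilcoxon signed-rank tests
  (n = 5 trials makes the asymptotic null invalid), zero differences
  dropped. No multiple-testing correction is applied across bins — results
  are per-bin markers, a documented caveat.
* Threshold depths: first crossing below the opsin threshold, interpolated
  log-linearly between samples (fluence decays quasi-exponentially; linear
  interpolation biases depth upward; log-linear is exact for exponentials).
  A profile that never crosses is flagged undefined with its search limit.
* LFP: Morlet ω₀ = 6, band sampled at 1 Hz steps, squared magnitude
  averaged over 3 s windows every 10 s restarting at each phase onset;
  windows straddling a phase boundary are dropped. Trace means are removed
  first, so power is offset-invariant and scales quadratically with
  amplitude. Friedman tests use average ranks with tie correction; for
  n ≤ 8 subjects the p-value is exact, aggregated by dynamic programming
  over the (k!)ⁿ within-subject rank arrangements (the statistic depends
  only on column rank sums, so full enumeration is never materialized) and
  verified against brute-force enumeration; larger n falls back to the χ²
  approximation. Note the exact test is conservative by discreteness: at
  n = 5, k = 3 the largest attainable size below 0.05 is ≈0.039, so null
  rejection rates settle slightly under the nominal α.

## Problem sizes and seeds

Default experiment sizes are chosen to keep full runs in the minutes range
on one CPU while leaving Monte Carlo and camera noise at realistic levels:
10⁶ packets for interface statistics, 1.5–2×10⁵ packets for fluence maps
feeding the thermal model, a 0.2 mm thermal grid (block-averaged from the
0.1 mm optical grid; refinement changes peak ΔT < 3%), 5 rendered trials
per protocol, and LFP null calibration at 500 Hz sampling (all analysis
bands lie below 100 Hz, so nothing is lost relative to a high-rate
recording). One master seed hashes into per-stage seeds; every artifact
records the seeds that produced it, and reruns are bit-identical.

## Known limitations

Homogeneous single-layer tissue (no skull, dura, CSF, or vasculature);
instantaneous transport (no pulse-shape effects); no temperature-dependent
perfusion feedback; planar interface (no cortical curvature or finite
craniotomy window); camera without vignetting or motion. These are the
main reasons simulated absolute values should be read as order-of-magnitude
guidance for protocol design rather than predictions for a specific
preparation.
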