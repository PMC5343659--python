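"""Synthetic-data generators with known ground truth.

Everything the analysis stages consume can be generated here: grey-level
thermal-camera movies rendered from simulated ΔT surface fields, hot-water
beaker cooling series for camera calibration, surface light-intensity images,
and raw LFP traces with a 1/f background plus band-limited oscillations over
baseline/stimulation/post phases.  Each generator is deterministic given its
spec and seed, and returns the ground truth next to the rendered data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from optotherm.mc_light import FluenceGrid


@dataclass(frozen=True)
class CameraModel:
    """Affine grey-level thermal camera with Gaussian NETD noise.

    ``noise_sd_c`` is the noise-equivalent temperature difference (0.08 °C,
    the sensitivity of the thermal imager being emulated).  ``pixel_pitch_mm``
    defaults to 0.05 mm/pixel so a 1 mm² circular ROI holds ~125 pixels.
    """

    gain: float = 100.0  # grey levels per °C
    offset: float = 1000.0  # grey levels
    noise_sd_c: float = 0.08
    frame_rate_hz: float = 3.0
    pixel_pitch_mm: float = 0.05

    def __post_init__(self) -> None:
        if self.gain == 0:
            raise ValueError("camera gain must be nonzero")
        if self.noise_sd_c < 0:
            raise ValueError("noise SD must be >= 0")

    def to_grey(self, temperature_c: np.ndarray) -> np.ndarray:
        return self.gain * np.asarray(temperature_c) + self.offset

    def to_temperature(self, grey: np.ndarray) -> np.ndarray:
        return (np.asarray(grey, dtype=float) - self.offset) / self.gain


@dataclass
class ThermalMovieRecord:
    """A rendered 16-bit grey movie plus the ground truth that produced it."""

    grey: np.ndarray  # (n_frames, ny, nx) uint16
    times_s: np.ndarray
    camera: CameraModel
    baseline_temp_c: float
    true_dT: np.ndarray  # noiseless ΔT frames, °C
    seed: int


def render_thermal_movie(
    surface_dT: np.ndarray,
    camera: CameraModel,
    baseline_temp_c: float = 29.0,
    times_s: Optional[np.ndarray] = None,
    seed: int = 0,
) -> ThermalMovieRecord:
    """Render a ΔT surface movie (°C) into quantized 16-bit camera counts.

    grey = gain · (baseline + ΔT + N(0, noise_sd)) + offset, rounded to the
    nearest integer and clipped to the 16-bit range.  The default baseline of
    29 °C sits in the 28–31 °C range typical of an exposed cortical surface.
    """
    surface_dT = np.asarray(surface_dT, dtype=float)
    if not np.all(np.isfinite(surface_dT)):
        raise ValueError("movie frames must be finite")
    rng = np.random.default_rng(seed)
    noisy = baseline_temp_c + surface_dT + rng.normal(
        0.0, camera.noise_sd_c, size=surface_dT.shape
    )
    grey = np.clip(np.rint(camera.to_grey(noisy)), 0, 65535).astype(np.uint16)
    if times_s is None:
        times_s = np.arange(surface_dT.shape[0]) / camera.frame_rate_hz
    return ThermalMovieRecord(
        grey=grey,
        times_s=np.asarray(times_s, dtype=float),
        camera=camera,
        baseline_temp_c=baseline_temp_c,
        true_dT=surface_dT,
        seed=seed,
    )


@dataclass
class CalibrationSeries:
    """Simultaneous camera grey levels and thermocouple reference during the
    cooling of a beaker of hot water (Newtonian cooling)."""

    times_s: np.ndarray
    grey_levels: np.ndarray
    reference_temperatures_c: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.times_s)
        if n == 0:
            raise ValueError("calibration series must be non-empty")
        if len(self.grey_levels) != n or len(self.reference_temperatures_c) != n:
            raise ValueError("calibration arrays must have equal length")


def generate_calibration_series(
    camera: CameraModel,
    t0_c: float = 60.0,
    ambient_c: float = 25.0,
    tau_s: float = 300.0,
    duration_s: float = 120.0,
    n_points: int = 120,
    grey_noise_sd: float = 0.5,
    seed: int = 0,
) -> CalibrationSeries:
    """Newtonian cooling reference: T(t) = ambient + (T0 − ambient)·e^(−t/τ),
    imaged through the camera model with additive grey-level noise."""
    if tau_s <= 0:
        raise ValueError("cooling time constant must be > 0")
    if t0_c <= ambient_c:
        raise ValueError("initial temperature must exceed ambient")
    if n_points < 1:
        raise ValueError("need at least one calibration point")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration_s, n_points)
    temp = ambient_c + (t0_c - ambient_c) * np.exp(-t / tau_s)
    grey = camera.to_grey(temp) + rng.normal(0.0, grey_noise_sd, size=n_points)
    return CalibrationSeries(times_s=t, grey_levels=grey, reference_temperatures_c=temp)


#: analysis frequency bands, Hz: α, β, γ
LFP_BANDS = ((6.0, 10.0), (15.0, 40.0), (60.0, 100.0))


@dataclass(frozen=True)
class SyntheticLFPSpec:
    """Recipe for a synthetic LFP trace over baseline/stim/post phases.

    ``band_amplitudes`` maps each oscillation band to its per-phase RMS
    amplitude (baseline, stim, post).  Oscillations are amplitude-modulated
    narrowband Gaussian noise (bandwidth 20% of the band center), not pure
    sinusoids, so repeated trials genuinely vary.  A spec with equal
    amplitudes across phases is a null: phases are statistically
    exchangeable.
    """

    sampling_rate_hz: float = 20000.0
    baseline_s: float = 30.0
    stim_s: float = 90.0
    post_s: float = 120.0
    background_exponent: float = 1.0
    background_rms: float = 1.0
    band_amplitudes: tuple = field(
        default_factory=lambda: tuple(
            (band, (0.5, 0.5, 0.5)) for band in LFP_BANDS
        )
    )

    def __post_init__(self) -> None:
        if min(self.baseline_s, self.stim_s, self.post_s) <= 0:
            raise ValueError("phase durations must be > 0")
        for _, amps in self.band_amplitudes:
            if any(a < 0 for a in amps):
                raise ValueError("band amplitudes must be >= 0")

    @property
    def total_s(self) -> float:
        return self.baseline_s + self.stim_s + self.post_s

    @property
    def phase_boundaries_s(self) -> tuple:
        return (self.baseline_s, self.baseline_s + self.stim_s, self.total_s)

    def null(self) -> "SyntheticLFPSpec":
        """Same spec with phase-constant band amplitudes (exchangeable null)."""
        from dataclasses import replace

        return replace(
            self,
            band_amplitudes=tuple(
                (band, (amps[0], amps[0], amps[0]))
                for band, amps in self.band_amplitudes
            ),
        )


@dataclass
class LFPRecord:
    trace: np.ndarray
    fs_hz: float
    phase_boundaries_s: tuple
    spec: SyntheticLFPSpec
    seed: int

    def phase_of(self, t_s: float) -> str:
        b0, b1, _ = self.phase_boundaries_s
        return "baseline" if t_s < b0 else ("stim" if t_s < b1 else "post")


def _one_over_f_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise with a 1/f^exponent amplitude spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shaping, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _narrowband_noise(
    n: int, fs: float, f_lo: float, f_hi: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS Gaussian noise confined (in frequency) to the band around the
    band center, with a Gaussian envelope of width 20% of the center."""
    center = 0.5 * (f_lo + f_hi)
    bw = 0.2 * center
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.exp(-0.5 * ((freqs - center) / (bw / 2.355)) ** 2)  # FWHM = bw
    x = np.fft.irfft(spec * shaping, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_lfp(spec: SyntheticLFPSpec, seed: int = 0) -> LFPRecord:
    """Synthesize one LFP trial: 1/f^β background plus per-band narrowband
    oscillations whose RMS amplitude is piecewise constant per phase."""
    rng = np.random.default_rng(seed)
    fs = spec.sampling_rate_hz
    n = int(round(spec.total_s * fs))
    trace = spec.background_rms * (
        _one_over_f_noise(n, spec.background_exponent, rng)
        if spec.background_rms > 0
        else np.zeros(n)
    )
    if spec.background_rms <= 0:
        trace = np.zeros(n)
    t = np.arange(n) / fs
    b0, b1, _ = spec.phase_boundaries_s
    phase_idx = np.where(t < b0, 0, np.where(t < b1, 1, 2))
    for (f_lo, f_hi), amps in spec.band_amplitudes:
        if max(amps) <= 0:
            continue
        carrier = _narrowband_noise(n, fs, f_lo, f_hi, rng)
        envelope = np.asarray(amps, dtype=float)[phase_idx]
        trace = trace + envelope * carrier
    return LFPRecord(
        trace=trace,
        fs_hz=fs,
        phase_boundaries_s=spec.phase_boundaries_s,
        spec=spec,
        seed=seed,
    )


def generate_light_image(
    fluence: FluenceGrid,
    plane: str = "surface",
    plane_coord_mm: float = 0.0,
    counts_per_unit: float = 1.0,
    saturation: Optional[float] = None,
    shot_noise: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """Render a fluence slice as a camera intensity image.

    ``plane`` selects the surface map (mean over the top voxel layer, the
    view of a camera looking down the z axis) or an axial slice at constant
    y (``plane="axial"``, the coronal-plane view).  Mapping to counts is
    linear with optional saturation clipping and Poisson shot noise.
    """
    g = fluence.grid
    if plane == "surface":
        img = fluence.values[:, :, 0].T.copy()
    elif plane == "axial":
        lo, hi = g.extent(1)
        if not lo <= plane_coord_mm < hi:
            raise ValueError(f"plane y={plane_coord_mm} outside grid [{lo}, {hi})")
        j = int((plane_coord_mm - g.origin_mm[1]) / g.spacing_mm)
        img = fluence.values[:, j, :].T.copy()
    else:
        raise ValueError("plane must be 'surface' or 'axial'")
    img = img * counts_per_unit
    if shot_noise:
        rng = np.random.default_rng(seed)
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if saturation is not None:
        img = np.clip(img, None, saturation)
    return img
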