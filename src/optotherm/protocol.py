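"""Stimulation protocols and dosimetry arithmetic.

Conventions used throughout the package:

* "irradiance" is the continuous-equivalent (during-pulse) optical power flux
  at the fiber exit face, in mW/mm², as measured with a power meter under
  continuous illumination.  Time-averaged delivery is irradiance × duty cycle.
* lengths in mm, times in s (pulse widths in ms where stated), powers in mW,
  temperatures in °C.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import yaml


class InvalidProtocolError(ValueError):
    """Raised for physically impossible stimulation parameters."""


def duty_cycle(pulse_width_ms: float, frequency_hz: float) -> float:
    """Fraction of time the light source is on.

    Parameters
    ----------
    pulse_width_ms : float
        Width of each light pulse in milliseconds.
    frequency_hz : float
        Pulse repetition frequency in Hz.

    Returns
    -------
    float
        ``pulse_width_ms * frequency_hz / 1000``, in [0, 1].  5 ms pulses at
        20/40/60 Hz give 10/20/30 % duty — the pulsed regimes typical of
        optogenetic stimulation.
    """
    if pulse_width_ms < 0 or frequency_hz < 0:
        raise InvalidProtocolError("pulse width and frequency must be >= 0")
    duty = pulse_width_ms * frequency_hz / 1000.0
    if duty > 1.0 + 1e-12:
        raise InvalidProtocolError(
            f"duty cycle {duty:.3f} > 1: pulse width {pulse_width_ms} ms does "
            f"not fit in the {1000.0 / frequency_hz:.3f} ms period"
        )
    return min(duty, 1.0)


def power_duty_product(peak_irradiance_mw_mm2: float, duty: float) -> float:
    """Time-averaged irradiance: peak (during-pulse) irradiance × duty cycle.

    This product is the predictor of the linear thermal-dose model: protocols
    with equal irradiance × duty (e.g. 400 mW/mm² at 60 Hz and 600 mW/mm² at
    40 Hz with 5 ms pulses, both 120) produce the same maximal heating.
    """
    if peak_irradiance_mw_mm2 < 0 or duty < 0:
        raise InvalidProtocolError("irradiance and duty must be >= 0")
    return peak_irradiance_mw_mm2 * duty


def irradiance_from_power(total_power_mw: float, core_diameter_mm: float) -> float:
    """Convert total optical power at the fiber exit to irradiance.

    Power divided by the fiber cross-section π(d/2)².  10 mW through a 62 μm
    fiber is ≈3312 mW/mm² — the standard conversion used to compare sources
    of different core diameters.
    """
    if core_diameter_mm <= 0:
        raise InvalidProtocolError("core diameter must be > 0")
    if total_power_mw < 0:
        raise InvalidProtocolError("power must be >= 0")
    return total_power_mw / (math.pi * (core_diameter_mm / 2.0) ** 2)


def power_from_irradiance(irradiance_mw_mm2: float, core_diameter_mm: float) -> float:
    """Inverse of :func:`irradiance_from_power`: E · π(d/2)²."""
    if core_diameter_mm <= 0:
        raise InvalidProtocolError("core diameter must be > 0")
    return irradiance_mw_mm2 * math.pi * (core_diameter_mm / 2.0) ** 2


@dataclass(frozen=True)
class StimulationProtocol:
    """A pulsed photostimulation protocol.

    Attributes
    ----------
    wavelength_nm : float
        Stimulation wavelength (476 nm blue or 638 nm red in the reference
        protocols; any positive value is accepted).
    peak_irradiance_mw_mm2 : float
        Continuous-equivalent irradiance at the fiber exit during a pulse.
    pulse_ms, freq_hz : float
        Pulse width (ms) and repetition frequency (Hz); their product must
        not exceed the period (duty ≤ 1).
    baseline_s, stim_s, post_s : float
        Durations of the pre-stimulation baseline, the stimulation phase and
        the post-stimulation recovery recording.
    """

    wavelength_nm: float
    peak_irradiance_mw_mm2: float
    pulse_ms: float
    freq_hz: float
    baseline_s: float = 10.0
    stim_s: float = 90.0
    post_s: float = 120.0

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise InvalidProtocolError("wavelength must be > 0")
        if self.peak_irradiance_mw_mm2 < 0:
            raise InvalidProtocolError("irradiance must be >= 0")
        if min(self.baseline_s, self.stim_s, self.post_s) < 0:
            raise InvalidProtocolError("durations must be >= 0")
        duty_cycle(self.pulse_ms, self.freq_hz)  # validates duty <= 1

    @property
    def duty(self) -> float:
        return duty_cycle(self.pulse_ms, self.freq_hz)

    @property
    def average_irradiance_mw_mm2(self) -> float:
        """Time-averaged irradiance during the stimulation phase."""
        return power_duty_product(self.peak_irradiance_mw_mm2, self.duty)

    @property
    def total_s(self) -> float:
        return self.baseline_s + self.stim_s + self.post_s

    def to_dict(self) -> dict:
        return {
            "wavelength_nm": self.wavelength_nm,
            "irradiance_mw_mm2": self.peak_irradiance_mw_mm2,
            "pulse_ms": self.pulse_ms,
            "freq_hz": self.freq_hz,
            "baseline_s": self.baseline_s,
            "stim_s": self.stim_s,
            "post_s": self.post_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulationProtocol":
        return cls(
            wavelength_nm=float(d["wavelength_nm"]),
            peak_irradiance_mw_mm2=float(d["irradiance_mw_mm2"]),
            pulse_ms=float(d["pulse_ms"]),
            freq_hz=float(d["freq_hz"]),
            baseline_s=float(d.get("baseline_s", 10.0)),
            stim_s=float(d.get("stim_s", 90.0)),
            post_s=float(d.get("post_s", 120.0)),
        )

    def save(self, path: Union[str, Path]) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "StimulationProtocol":
        path = Path(path)
        raw = path.read_text()
        d = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.from_dict(d)


@dataclass(frozen=True)
class FiberSource:
    """Multimode fiber light source inside (or against) the tissue.

    The default geometry matches the lateral-insertion configuration: a
    400 μm core, NA 0.48 fiber whose optical axis runs parallel to the planar
    brain–air interface, 500 μm below it.  ``tip_mm`` is the center of the
    exit face; ``axis`` is the (unit) emission direction.
    """

    core_diameter_mm: float = 0.4
    numerical_aperture: float = 0.48
    tip_mm: tuple = (0.0, 0.0, 0.5)
    axis: tuple = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.core_diameter_mm <= 0:
            raise InvalidProtocolError("core diameter must be > 0")
        if not 0.0 < self.numerical_aperture < 1.6:
            raise InvalidProtocolError("NA must be in (0, 1.6)")
        norm = math.sqrt(sum(c * c for c in self.axis))
        if norm == 0:
            raise InvalidProtocolError("axis must be a nonzero vector")
        if abs(norm - 1.0) > 1e-9:
            object.__setattr__(self, "axis", tuple(c / norm for c in self.axis))

    @property
    def radius_mm(self) -> float:
        return self.core_diameter_mm / 2.0

    @property
    def area_mm2(self) -> float:
        return math.pi * self.radius_mm**2

    @property
    def axis_depth_below_surface_mm(self) -> float:
        """Depth of the optical axis below the z=0 interface."""
        return self.tip_mm[2]

    def cone_half_angle_rad(self, n_medium: float) -> float:
        """Emission cone half-angle asin(NA / n) in the launch medium."""
        if self.numerical_aperture >= n_medium:
            raise InvalidProtocolError(
                f"NA {self.numerical_aperture} >= medium index {n_medium}"
            )
        return math.asin(self.numerical_aperture / n_medium)

    def replace(self, **kw) -> "FiberSource":
        return dataclasses.replace(self, **kw)
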