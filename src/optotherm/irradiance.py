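"""Light-distribution analysis: relative maps, axial/lateral profiles,
absolute scaling, and opsin-threshold depth estimation.

Opsins require roughly 1–5 mW/mm² of local irradiance; given an absolute
irradiance profile along an axis from the fiber tip, the threshold depth is
the first distance at which the profile falls below that level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates


@dataclass
class IrradianceProfile:
    """Irradiance versus distance from the fiber tip along a stated axis.

    ``values`` are in mW/mm² when absolute, or normalized units otherwise.
    """

    distances_mm: np.ndarray
    values: np.ndarray
    axis: str = "axial"  # "axial" | "lateral"
    wavelength_nm: Optional[float] = None
    absolute: bool = False

    def __post_init__(self) -> None:
        self.distances_mm = np.asarray(self.distances_mm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.distances_mm) != len(self.values):
            raise ValueError("distances and values must have equal length")
        if len(self.distances_mm) and (
            self.distances_mm[0] != 0.0 or np.any(np.diff(self.distances_mm) <= 0)
        ):
            raise ValueError("distances must increase strictly from 0")
        if np.any(self.values < 0):
            raise ValueError("irradiance values must be >= 0")


def relative_map(image: np.ndarray, reference_image: np.ndarray) -> np.ndarray:
    """Normalize an intensity image against the brightest reference pixel.

    The reference is typically the highest-irradiance acquisition; the
    reference's own relative map has max exactly 1.
    """
    image = np.asarray(image, dtype=float)
    reference_image = np.asarray(reference_image, dtype=float)
    if image.shape != reference_image.shape:
        raise ValueError("image and reference must have the same shape")
    ref_max = reference_image.max()
    if ref_max <= 0:
        raise ValueError("reference image has no positive values")
    return image / ref_max


def extract_profile(
    image: np.ndarray,
    tip_px: tuple,
    direction: tuple,
    step_px: float = 1.0,
    pixel_pitch_mm: float = 1.0,
    axis: str = "axial",
    wavelength_nm: Optional[float] = None,
) -> IrradianceProfile:
    """Bilinear-interpolated profile from ``tip_px`` along ``direction``.

    ``tip_px`` and ``direction`` are in (row, col) pixel coordinates; samples
    run until the ray leaves the image.  Distances are converted to mm with
    ``pixel_pitch_mm``.
    """
    image = np.asarray(image, dtype=float)
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("direction must be a nonzero vector")
    d = d / norm
    tip = np.asarray(tip_px, dtype=float)
    if not (0 <= tip[0] <= image.shape[0] - 1 and 0 <= tip[1] <= image.shape[1] - 1):
        raise ValueError("tip must lie inside the image")
    ks = []
    k = 0
    while True:
        p = tip + k * step_px * d
        if not (0 <= p[0] <= image.shape[0] - 1 and 0 <= p[1] <= image.shape[1] - 1):
            break
        ks.append(k)
        k += 1
    pts = tip[None, :] + np.asarray(ks, dtype=float)[:, None] * step_px * d[None, :]
    vals = map_coordinates(image, pts.T, order=1)
    dists = np.asarray(ks, dtype=float) * step_px * pixel_pitch_mm
    return IrradianceProfile(
        distances_mm=dists,
        values=np.clip(vals, 0.0, None),
        axis=axis,
        wavelength_nm=wavelength_nm,
        absolute=False,
    )


def scale_to_absolute(
    profile: IrradianceProfile, surface_irradiance_mw_mm2: float
) -> IrradianceProfile:
    """Scale a normalized profile so its distance-0 value equals the applied
    fiber-exit irradiance."""
    if len(profile.values) == 0 or profile.values[0] <= 0:
        raise ValueError("profile value at distance 0 must be > 0")
    factor = surface_irradiance_mw_mm2 / profile.values[0]
    return IrradianceProfile(
        distances_mm=profile.distances_mm.copy(),
        values=profile.values * factor,
        axis=profile.axis,
        wavelength_nm=profile.wavelength_nm,
        absolute=True,
    )


@dataclass(frozen=True)
class ThresholdDepth:
    """First depth at which an absolute profile falls below a threshold.

    ``defined`` is False when the profile never drops below the threshold
    within its range; ``search_limit_mm`` then reports the end of the range.
    """

    depth_mm: float
    defined: bool
    search_limit_mm: float

    def __float__(self) -> float:
        return self.depth_mm if self.defined else math.nan


def threshold_depth(
    profile: IrradianceProfile, threshold_mw_mm2: float
) -> ThresholdDepth:
    """Locate the first crossing below ``threshold_mw_mm2``.

    The crossing is interpolated log-linearly between the bracketing samples
    (fluence decays quasi-exponentially, so linear interpolation would bias
    the depth upward).  A threshold at or above the origin value gives depth
    0; a profile never below the threshold is flagged undefined.
    """
    if threshold_mw_mm2 <= 0:
        raise ValueError("threshold must be > 0")
    v = profile.values
    d = profile.distances_mm
    limit = float(d[-1]) if len(d) else 0.0
    if len(v) == 0:
        return ThresholdDepth(math.nan, False, limit)
    if v[0] <= threshold_mw_mm2:
        return ThresholdDepth(0.0, True, limit)
    below = np.nonzero(v < threshold_mw_mm2)[0]
    if len(below) == 0:
        return ThresholdDepth(math.nan, False, limit)
    i = int(below[0])
    v0, v1 = v[i - 1], v[i]
    d0, d1 = d[i - 1], d[i]
    if v1 <= 0:
        # log interpolation undefined at zero; fall back to the sample
        return ThresholdDepth(float(d1), True, limit)
    frac = (math.log(v0) - math.log(threshold_mw_mm2)) / (math.log(v0) - math.log(v1))
    return ThresholdDepth(float(d0 + frac * (d1 - d0)), True, limit)
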