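"""Thermal-movie analysis: calibration, ΔT maps, hottest-spot ROI time
courses, 8-s binning, the linear thermal-dose model, and paired
nonparametric comparisons between stimulation frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, stats

from optotherm.synth import CalibrationSeries


@dataclass(frozen=True)
class CalibrationFit:
    """Affine grey → °C map fitted on a beaker-cooling reference."""

    slope_c_per_grey: float
    intercept_c: float
    residual_rms_c: float

    def apply(self, grey: np.ndarray) -> np.ndarray:
        return self.slope_c_per_grey * np.asarray(grey, dtype=float) + self.intercept_c


def fit_calibration(series: CalibrationSeries) -> CalibrationFit:
    """Least-squares affine fit temperature = a·grey + b."""
    grey = np.asarray(series.grey_levels, dtype=float)
    temp = np.asarray(series.reference_temperatures_c, dtype=float)
    if len(grey) < 2:
        raise ValueError("need at least two calibration points")
    if np.ptp(grey) == 0:
        raise ValueError("constant grey levels: calibration fit is singular")
    a, b = np.polyfit(grey, temp, 1)
    resid = temp - (a * grey + b)
    return CalibrationFit(
        slope_c_per_grey=float(a),
        intercept_c=float(b),
        residual_rms_c=float(np.sqrt(np.mean(resid**2))),
    )


def delta_maps(
    movie_c: np.ndarray,
    times_s: np.ndarray,
    baseline_window_s: float = 10.0,
) -> np.ndarray:
    """Per-pixel ΔT relative to the mean over the pre-stimulation baseline.

    ``times_s`` are frame times with t = 0 at stimulation onset; frames with
    t < 0 (within the last ``baseline_window_s`` seconds) form the baseline.
    """
    movie_c = np.asarray(movie_c, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    mask = (times_s < 0) & (times_s >= -baseline_window_s)
    if not mask.any():
        raise ValueError("no baseline frames within the baseline window")
    baseline = movie_c[mask].mean(axis=0)
    return movie_c - baseline[None]


def hottest_roi(
    dT_stack: np.ndarray,
    pixel_pitch_mm: float,
    area_mm2: float = 1.0,
) -> np.ndarray:
    """Circular ROI mask around the hottest point of the time-max projection.

    The projection is smoothed with a 3×3 mean before taking the argmax so a
    single noisy pixel (camera NETD ~0.08 °C) cannot anchor the ROI; ties go
    to the lowest (row, col) index.  Radius = √(area/π) (0.5642 mm for 1 mm²);
    a pixel belongs to the ROI when its center lies within the radius.
    """
    dT_stack = np.asarray(dT_stack, dtype=float)
    if dT_stack.size == 0:
        raise ValueError("empty ΔT stack")
    proj = dT_stack.max(axis=0)
    smooth = ndimage.uniform_filter(proj, size=3, mode="nearest")
    # among pixels tied at the smoothed maximum, anchor on the one with the
    # highest raw projection; remaining ties go to the lowest (row, col)
    cand = np.argwhere(smooth >= smooth.max() - 1e-12)
    raw = proj[cand[:, 0], cand[:, 1]]
    order = np.lexsort((cand[:, 1], cand[:, 0], -raw))
    center = tuple(cand[order[0]])
    radius_mm = math.sqrt(area_mm2 / math.pi)
    rr, cc = np.indices(proj.shape)
    dist = pixel_pitch_mm * np.hypot(rr - center[0], cc - center[1])
    mask = dist <= radius_mm
    # warn-by-construction: clipped at the frame edge if the disc overruns it
    return mask


@dataclass
class TemperatureTimeCourse:
    """ROI-averaged ΔT per frame, with non-overlapping 8-s bin means."""

    times_s: np.ndarray
    dT_c: np.ndarray
    binned_times_s: np.ndarray  # bin centers
    binned_dT_c: np.ndarray
    bin_s: float
    trial_id: Optional[str] = None


def roi_timecourse(
    dT_stack: np.ndarray,
    roi_mask: np.ndarray,
    times_s: np.ndarray,
    bin_s: float = 8.0,
    trial_id: Optional[str] = None,
) -> TemperatureTimeCourse:
    """Mean ΔT inside the ROI per frame, then binned into left-aligned,
    non-overlapping ``bin_s``-second windows anchored at t = 0 (stim onset)."""
    if not np.any(roi_mask):
        raise ValueError("empty ROI")
    dT_stack = np.asarray(dT_stack, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    tc = dT_stack[:, roi_mask].mean(axis=1)
    # bin edges on the ..., -8, 0, 8, ... grid so stim onset starts a bin
    first_edge = math.floor(times_s[0] / bin_s) * bin_s
    edges = np.arange(first_edge, times_s[-1] + bin_s, bin_s)
    idx = np.digitize(times_s, edges) - 1
    centers, means = [], []
    for b in range(len(edges)):
        sel = idx == b
        if sel.any():
            centers.append(edges[b] + bin_s / 2)
            means.append(tc[sel].mean())
    return TemperatureTimeCourse(
        times_s=times_s,
        dT_c=tc,
        binned_times_s=np.array(centers),
        binned_dT_c=np.array(means),
        bin_s=bin_s,
        trial_id=trial_id,
    )


def max_delta_t(tc: TemperatureTimeCourse, stim_s: float = 90.0) -> float:
    """Maximal binned ΔT during the stimulation phase (bin centers in
    [0, stim_s))."""
    if len(tc.binned_dT_c) == 0:
        raise ValueError("empty time course")
    sel = (tc.binned_times_s >= 0) & (tc.binned_times_s < stim_s)
    vals = tc.binned_dT_c[sel] if sel.any() else tc.binned_dT_c
    return float(vals.max())


@dataclass
class LinearThermalModel:
    """OLS fit of maximal ΔT against irradiance × duty (the thermal dose).

    ``slope`` is in °C per (mW/mm²·duty); the fit predicts the maximum
    temperature increase for any protocol from its power × duty-cycle
    product.
    """

    slope: float
    intercept: float
    r_squared: float
    x: np.ndarray
    y: np.ndarray
    wavelength_nm: Optional[float] = None

    def predict(self, power_duty: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(power_duty, dtype=float) + self.intercept


def fit_dose_model(
    power_duty: Sequence[float],
    max_dT: Sequence[float],
    wavelength_nm: Optional[float] = None,
) -> LinearThermalModel:
    """Ordinary least squares (with intercept) of max ΔT on power × duty."""
    x = np.asarray(power_duty, dtype=float)
    y = np.asarray(max_dT, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("need >= 2 distinct predictor values")
    res = stats.linregress(x, y)
    return LinearThermalModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        x=x,
        y=y,
        wavelength_nm=wavelength_nm,
    )


def compare_frequencies(
    tcs_a: Sequence[TemperatureTimeCourse],
    tcs_b: Sequence[TemperatureTimeCourse],
) -> "np.ndarray":
    """Per-bin paired Wilcoxon signed-rank tests between two frequency
    conditions (e.g. 60 vs 20 Hz), across paired trials.

    Uses the exact null distribution (required at the n = 5 trials of the
    reference protocols), two-sided, dropping zero differences.  Returns a
    structured array of (bin_time, p_value, significant) with significance at
    p < 0.05; bins where every pair is tied get p = 1.
    """
    if len(tcs_a) != len(tcs_b) or len(tcs_a) == 0:
        raise ValueError("need equal, nonzero numbers of paired trials")
    n_bins = min(min(len(t.binned_dT_c) for t in tcs_a),
                 min(len(t.binned_dT_c) for t in tcs_b))
    out = np.zeros(
        n_bins, dtype=[("bin_time_s", float), ("p_value", float), ("significant", bool)]
    )
    for b in range(n_bins):
        a = np.array([t.binned_dT_c[b] for t in tcs_a])
        c = np.array([t.binned_dT_c[b] for t in tcs_b])
        d = a - c
        if np.all(d == 0):
            p = 1.0
        else:
            p = float(
                stats.wilcoxon(
                    a, c, zero_method="wilcox", alternative="two-sided", method="exact"
                ).pvalue
            )
        out[b] = (tcs_a[0].binned_times_s[b], p, p < 0.05)
    return out
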