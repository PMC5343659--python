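"""LFP band-power analysis: continuous Morlet wavelet power in the α
(6–10 Hz), β (15–40 Hz) and γ (60–100 Hz) bands over 3-s windows spaced 10 s
apart, per-phase averages, and Friedman tests across
baseline/stimulation/post conditions.

The Friedman null is evaluated exactly (full enumeration of within-subject
rank arrangements) for small numbers of subjects, where the χ² approximation
is poor — the reference experiments have n = 5 electrode positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import signal, stats

MORLET_OMEGA0 = 6.0
DEFAULT_BANDS = ((6.0, 10.0), (15.0, 40.0), (60.0, 100.0))


@dataclass
class BandPowerSeries:
    """Morlet power of one frequency band, one value per analysis window."""

    band_hz: Tuple[float, float]
    window_centers_s: np.ndarray
    power: np.ndarray
    phase_labels: np.ndarray  # "baseline" | "stim" | "post" per window
    window_s: float = 3.0


def make_windows(
    phase_boundaries_s: Sequence[float],
    window_s: float = 3.0,
    every_s: float = 10.0,
) -> list:
    """(start, end, phase) analysis windows: ``window_s`` of signal every
    ``every_s``, restarting at each phase onset; windows that would straddle
    a phase boundary are dropped."""
    b0, b1, b2 = phase_boundaries_s
    spans = [(0.0, b0, "baseline"), (b0, b1, "stim"), (b1, b2, "post")]
    windows = []
    for lo, hi, phase in spans:
        start = lo
        while start + window_s <= hi + 1e-9:
            windows.append((start, start + window_s, phase))
            start += every_s
    return windows


def _morlet_kernel(f_hz: float, fs_hz: float) -> np.ndarray:
    """Complex Morlet (ω₀ = 6) at center frequency ``f_hz``, L2-normalized."""
    sigma_t = MORLET_OMEGA0 / (2.0 * math.pi * f_hz)
    half = int(math.ceil(5.0 * sigma_t * fs_hz))
    t = np.arange(-half, half + 1) / fs_hz
    psi = np.exp(2j * math.pi * f_hz * t) * np.exp(-(t**2) / (2.0 * sigma_t**2))
    return psi / np.linalg.norm(psi)


def morlet_band_power(
    trace: np.ndarray,
    fs_hz: float,
    band_hz: Tuple[float, float],
    windows: Sequence[tuple],
    freq_step_hz: float = 1.0,
) -> BandPowerSeries:
    """Squared-magnitude Morlet CWT averaged over the band and each window.

    The band is sampled at ``freq_step_hz`` intervals (inclusive of both
    edges).  The trace mean is removed first, making the power invariant to
    constant offsets; power scales quadratically with signal amplitude.
    """
    f_lo, f_hi = band_hz
    if f_hi * 2.0 > fs_hz:
        raise ValueError(
            f"band upper edge {f_hi} Hz above Nyquist ({fs_hz / 2} Hz)"
        )
    x = np.asarray(trace, dtype=float)
    x = x - x.mean()
    freqs = np.arange(f_lo, f_hi + freq_step_hz / 2, freq_step_hz)
    power_t = np.zeros(len(x))
    for f in freqs:
        c = signal.oaconvolve(x, _morlet_kernel(float(f), fs_hz), mode="same")
        power_t += np.abs(c) ** 2
    power_t /= len(freqs)

    centers, values, phases = [], [], []
    for w in windows:
        start, end = w[0], w[1]
        phase = w[2] if len(w) > 2 else ""
        i0, i1 = int(round(start * fs_hz)), int(round(end * fs_hz))
        if i0 < 0 or i1 > len(x):
            raise ValueError(f"window ({start}, {end}) s outside the trace")
        centers.append(0.5 * (start + end))
        values.append(power_t[i0:i1].mean())
        phases.append(phase)
    return BandPowerSeries(
        band_hz=(f_lo, f_hi),
        window_centers_s=np.array(centers),
        power=np.array(values),
        phase_labels=np.array(phases),
        window_s=float(windows[0][1] - windows[0][0]) if windows else 3.0,
    )


def phase_average(series: BandPowerSeries) -> Dict[str, float]:
    """Mean window power per phase; raises if any phase has no windows."""
    out = {}
    for phase in ("baseline", "stim", "post"):
        sel = series.phase_labels == phase
        if not sel.any():
            raise ValueError(f"phase '{phase}' has no analysis windows")
        out[phase] = float(series.power[sel].mean())
    return out


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    p_value: float
    n_subjects: int
    k_conditions: int
    method: str  # "exact" | "chi2"


def _friedman_statistic(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman χ² from a (n × k) matrix of within-row ranks."""
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    a = float((ranks**2).sum())
    c = n * k * (k + 1) ** 2 / 4.0
    if a == c:  # every row completely tied
        return 0.0
    dev = col_sums - n * (k + 1) / 2.0
    return (k - 1) * float((dev**2).sum()) / (a - c)


def friedman_test(
    phase_means: np.ndarray, exact_max_n: int = 8
) -> FriedmanResult:
    """Friedman test on an (n subjects × k conditions) table.

    Ranks within each subject (average ranks for ties); the statistic is the
    tie-corrected χ²_F.  For n ≤ ``exact_max_n`` the p-value is computed by
    full enumeration of the (k!)ⁿ equally likely within-subject rank
    arrangements (conditional on the observed tie patterns); otherwise by
    the χ² approximation with k−1 degrees of freedom.
    """
    table = np.asarray(phase_means, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need an (n >= 2) x (k >= 2) table")
    if not np.all(np.isfinite(table)):
        raise ValueError("table has missing cells")
    n, k = table.shape
    ranks = np.vstack([stats.rankdata(row) for row in table])
    observed = _friedman_statistic(ranks)

    if n <= exact_max_n:
        p = _exact_friedman_pvalue(ranks, observed)
        method = "exact"
    else:
        p = float(stats.chi2.sf(observed, k - 1))
        method = "chi2"
    return FriedmanResult(
        statistic=observed,
        p_value=min(max(p, 0.0), 1.0),
        n_subjects=n,
        k_conditions=k,
        method=method,
    )


def _exact_friedman_pvalue(ranks: np.ndarray, observed: float) -> float:
    """Exact permutation p-value.

    The tie-corrected statistic depends on the permuted table only through
    the column rank sums (the denominator Σr² is invariant under within-row
    permutation), so the (k!)ⁿ arrangements are aggregated by dynamic
    programming over the distribution of column-sum vectors instead of being
    enumerated one by one.
    """
    n, k = ranks.shape
    a = float((ranks**2).sum())
    c = n * k * (k + 1) ** 2 / 4.0
    denom = a - c
    if denom <= 0:
        return 1.0
    # scale ranks by 2 so average ranks (x.5) become integers
    perms = list(permutations(range(k)))
    dist: Dict[tuple, float] = {tuple([0] * k): 1.0}
    w = 1.0 / len(perms)
    for row in np.rint(ranks * 2).astype(int):
        new: Dict[tuple, float] = {}
        for state, prob in dist.items():
            for perm in perms:
                nxt = tuple(state[j] + row[perm[j]] for j in range(k))
                new[nxt] = new.get(nxt, 0.0) + prob * w
        dist = new
    target = n * (k + 1)  # column sum under H0, in doubled-rank units
    p = 0.0
    for state, prob in dist.items():
        dev2 = sum((s - target) ** 2 for s in state) / 4.0
        stat = (k - 1) * dev2 / denom
        if stat >= observed - 1e-9:
            p += prob
    return p


def lfp_phase_table(
    traces: Sequence[np.ndarray],
    fs_hz: float,
    band_hz: Tuple[float, float],
    phase_boundaries_s: Sequence[float],
    window_s: float = 3.0,
    every_s: float = 10.0,
) -> np.ndarray:
    """Convenience: (n subjects × 3 phases) mean-power table for one band."""
    windows = make_windows(phase_boundaries_s, window_s, every_s)
    rows = []
    for tr in traces:
        series = morlet_band_power(tr, fs_hz, band_hz, windows)
        means = phase_average(series)
        rows.append([means["baseline"], means["stim"], means["post"]])
    return np.asarray(rows)
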