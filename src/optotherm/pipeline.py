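"""End-to-end simulate → render → analyze workflows with one master seed.

These are the experiment drivers used by the command-line interface, the
test suite and the reproduction script: the thermal-dose sweep (protocol
grid → Monte Carlo fluence → bioheat → camera rendering → ROI analysis →
linear dose model), the threshold-depth comparison between blue and red
light, the post-stimulation recovery check, and the LFP null calibration.
Per-stage seeds are derived from the master seed by stage-name hashing, so
any stage can be rerun independently and a rerun with the same config and
seed reproduces every numeric output bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from optotherm.bioheat import TemperatureField, TissueThermalProperties, solve
from optotherm.grid import VoxelGrid
from optotherm.io import (
    RunManifest,
    array_checksum,
    stage_seed,
    write_fluence,
    write_thermal_movie,
)
from optotherm.irradiance import scale_to_absolute, threshold_depth, IrradianceProfile
from optotherm.lfp import friedman_test, lfp_phase_table
from optotherm.mc_light import (
    FluenceGrid,
    TissueOpticalProperties,
    absorbed_power_map,
    propagate,
)
from optotherm.protocol import FiberSource, StimulationProtocol
from optotherm.synth import (
    CameraModel,
    SyntheticLFPSpec,
    generate_calibration_series,
    generate_lfp,
    render_thermal_movie,
)
from optotherm.thermal import (
    delta_maps,
    fit_calibration,
    fit_dose_model,
    hottest_roi,
    max_delta_t,
    roi_timecourse,
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def coarsen(values: np.ndarray, factor: int) -> np.ndarray:
    """Block-average a 3D array by an integer factor along every axis."""
    nx, ny, nz = values.shape
    if any(n % factor for n in values.shape):
        raise ValueError(f"dims {values.shape} not divisible by {factor}")
    return values.reshape(
        nx // factor, factor, ny // factor, factor, nz // factor, factor
    ).mean(axis=(1, 3, 5))


def coarsen_grid(grid: VoxelGrid, factor: int) -> VoxelGrid:
    return VoxelGrid(
        spacing_mm=grid.spacing_mm * factor,
        dims=tuple(d // factor for d in grid.dims),
        origin_mm=grid.origin_mm,
    )


def simulate_surface_movie(
    q_unit: np.ndarray,
    thermal_grid: VoxelGrid,
    protocol: StimulationProtocol,
    thermal_props: TissueThermalProperties,
    tip_index: Optional[tuple] = None,
) -> tuple:
    """Solve the bioheat equation for one protocol and return the full-movie
    surface ΔT (baseline zeros + solver frames) with camera-rate times.

    ``q_unit`` is the absorbed-power map per unit fiber-exit irradiance; it
    is scaled by the protocol's peak irradiance (the duty factor is applied
    inside the solver while the source is on).
    """
    fld = solve(
        q_unit * protocol.peak_irradiance_mw_mm2,
        thermal_props,
        protocol,
        thermal_grid,
        store="surface",
        surface_depth_mm=max(0.1, thermal_grid.spacing_mm),
        tip_index=tip_index,
    )
    frame_dt = 1.0 / 3.0
    n_base = int(round(protocol.baseline_s / frame_dt))
    base_times = -protocol.baseline_s + np.arange(n_base) * frame_dt
    frames = np.concatenate(
        [np.zeros((n_base,) + fld.frames.shape[1:]), fld.frames]
    )
    times = np.concatenate([base_times, fld.times_s])
    return frames, times, fld


@dataclass
class DoseExperimentResult:
    """Outcome of the protocol-sweep thermal-dose experiment."""

    table: pd.DataFrame  # per protocol: irradiance, freq, duty, x, gt/fitted max
    ground_truth_model: object
    fitted_model: object
    wavelength_nm: float
    fluence: FluenceGrid


def thermal_dose_experiment(
    seed: int,
    irradiances_mw_mm2: Sequence[float] = (200.0, 400.0, 600.0),
    frequencies_hz: Sequence[float] = (20.0, 40.0, 60.0),
    wavelength_nm: float = 638.0,
    pulse_ms: float = 5.0,
    n_trials: int = 5,
    n_photons: int = 200_000,
    thermal_factor: int = 2,
    camera: Optional[CameraModel] = None,
    optical_props: Optional[TissueOpticalProperties] = None,
    thermal_props: Optional[TissueThermalProperties] = None,
    post_s: float = 120.0,
) -> DoseExperimentResult:
    """Simulate the full protocol grid and recover the linear thermal-dose
    model from camera-noise-corrupted movies.

    One Monte Carlo transport run (per-unit irradiance) feeds all protocols;
    each protocol's temperature movie is rendered ``n_trials`` times with
    independent camera noise, calibrated against a synthetic beaker-cooling
    series, and pushed through the ΔT/ROI/binning analysis.  The ground
    truth is the same analysis applied to the noiseless movies.
    """
    optical_props = optical_props or TissueOpticalProperties.brain(wavelength_nm)
    thermal_props = thermal_props or TissueThermalProperties()
    source = FiberSource()
    fluence = propagate(
        n_photons, source, optical_props, seed=stage_seed(seed, "mc_light")
    )
    q = absorbed_power_map(fluence, optical_props)
    q_c = coarsen(q, thermal_factor)
    grid_c = coarsen_grid(fluence.grid, thermal_factor)
    if camera is None:
        camera = CameraModel(pixel_pitch_mm=grid_c.spacing_mm)

    rows = []
    gt_x, gt_y, fit_y = [], [], []
    for e in irradiances_mw_mm2:
        for f_hz in frequencies_hz:
            proto = StimulationProtocol(
                wavelength_nm, e, pulse_ms, f_hz, post_s=post_s
            )
            frames, times, _ = simulate_surface_movie(
                q_c, grid_c, proto, thermal_props
            )
            # ground truth: identical analysis on the noiseless movie
            gt_max = _analyze_movie(frames, times, camera.pixel_pitch_mm, proto)
            trial_maxima = []
            for trial in range(n_trials):
                s = stage_seed(seed, f"render:{e}:{f_hz}:{trial}")
                rec = render_thermal_movie(frames, camera, times_s=times, seed=s)
                calib = generate_calibration_series(
                    camera, seed=stage_seed(seed, f"calib:{e}:{f_hz}:{trial}")
                )
                cal = fit_calibration(calib)
                movie_c = cal.apply(rec.grey)
                trial_maxima.append(
                    _analyze_movie(movie_c, times, camera.pixel_pitch_mm, proto)
                )
            x = proto.average_irradiance_mw_mm2
            rows.append(
                dict(
                    irradiance_mw_mm2=e,
                    freq_hz=f_hz,
                    duty=proto.duty,
                    power_duty=x,
                    gt_max_dT_c=gt_max,
                    max_dT_c=float(np.mean(trial_maxima)),
                    max_dT_sd_c=float(np.std(trial_maxima)),
                )
            )
            gt_x.append(x)
            gt_y.append(gt_max)
            fit_y.append(float(np.mean(trial_maxima)))

    gt_model = fit_dose_model(gt_x, gt_y, wavelength_nm)
    fitted = fit_dose_model(gt_x, fit_y, wavelength_nm)
    return DoseExperimentResult(
        table=pd.DataFrame(rows),
        ground_truth_model=gt_model,
        fitted_model=fitted,
        wavelength_nm=wavelength_nm,
        fluence=fluence,
    )


def _analyze_movie(movie_c, times, pixel_pitch_mm, proto) -> float:
    """ΔT maps → hottest 1 mm² ROI → 8-s binned time course → stim max."""
    dmaps = delta_maps(movie_c, times, baseline_window_s=proto.baseline_s)
    roi = hottest_roi(dmaps, pixel_pitch_mm)
    tc = roi_timecourse(dmaps, roi, times)
    return max_delta_t(tc, stim_s=proto.stim_s)


def threshold_depth_experiment(
    seed: int,
    irradiances_mw_mm2: Sequence[float] = (100.0, 200.0, 400.0, 600.0),
    thresholds_mw_mm2: Sequence[float] = (1.0, 5.0),
    wavelengths_nm: Sequence[float] = (476.0, 638.0),
    n_photons: int = 200_000,
) -> dict:
    """Axial opsin-threshold depths from simulated fluence profiles.

    Returns depths[wavelength][irradiance][threshold] in mm (NaN when the
    profile never falls below the threshold inside the grid).
    """
    source = FiberSource()
    out = {}
    for wl in wavelengths_nm:
        props = TissueOpticalProperties.brain(wl)
        fl = propagate(
            n_photons, source, props, seed=stage_seed(seed, f"mc:{wl}")
        )
        d, v = fl.axial_profile(source)
        base = IrradianceProfile(d, np.clip(v, 0, None), axis="axial", wavelength_nm=wl)
        out[wl] = {}
        for e in irradiances_mw_mm2:
            absolute = scale_to_absolute(base, e)
            out[wl][e] = {
                thr: float(threshold_depth(absolute, thr))
                for thr in thresholds_mw_mm2
            }
    return out


def recovery_experiment(
    seed: int,
    irradiance_mw_mm2: float = 600.0,
    freq_hz: float = 40.0,
    n_photons: int = 100_000,
    thermal_props: Optional[TissueThermalProperties] = None,
) -> dict:
    """Fraction of the end-of-stimulation surface maximum remaining 90 s
    after the light is switched off (tissue cooling by diffusion, surface
    convection and perfusion)."""
    thermal_props = thermal_props or TissueThermalProperties()
    props = TissueOpticalProperties.brain(638)
    fl = propagate(
        n_photons, FiberSource(), props, seed=stage_seed(seed, "mc_light")
    )
    q_c = coarsen(absorbed_power_map(fl, props), 2)
    grid_c = coarsen_grid(fl.grid, 2)
    proto = StimulationProtocol(638, irradiance_mw_mm2, 5, freq_hz, post_s=120.0)
    frames, times, _ = simulate_surface_movie(q_c, grid_c, proto, thermal_props)
    tmax = frames.max(axis=(1, 2))
    i_end = int(np.argmin(np.abs(times - proto.stim_s)))
    i_p90 = int(np.argmin(np.abs(times - (proto.stim_s + 90.0))))
    return {
        "end_of_stim_dT_c": float(tmax[i_end]),
        "post90_dT_c": float(tmax[i_p90]),
        "remaining_fraction": float(tmax[i_p90] / tmax[i_end]),
    }


def lfp_null_calibration(
    seed: int,
    n_replicates: int = 200,
    n_subjects: int = 5,
    band_hz: tuple = (6.0, 10.0),
    fs_hz: float = 500.0,
    alpha: float = 0.05,
) -> dict:
    """Friedman type-I-error calibration on null synthetic LFP.

    Each replicate generates ``n_subjects`` independent null traces (equal
    band amplitudes in all phases), computes per-phase mean band power, and
    runs the exact Friedman test; returns the rejection rate at ``alpha``.
    """
    spec = SyntheticLFPSpec(sampling_rate_hz=fs_hz).null()
    rejections = 0
    for rep in range(n_replicates):
        traces = [
            generate_lfp(spec, seed=stage_seed(seed, f"lfp:{rep}:{s}")).trace
            for s in range(n_subjects)
        ]
        table = lfp_phase_table(
            traces, fs_hz, band_hz, spec.phase_boundaries_s
        )
        res = friedman_test(table)
        if res.p_value < alpha:
            rejections += 1
    return {
        "n_replicates": n_replicates,
        "rejections": rejections,
        "rejection_rate": rejections / n_replicates,
        "alpha": alpha,
    }


DEFAULT_CONFIG = {
    "seed": 1,
    "stages": ["thermal_dose", "lfp"],
    "wavelength_nm": 638,
    "irradiances_mw_mm2": [200, 400, 600],
    "frequencies_hz": [20, 40, 60],
    "pulse_ms": 5,
    "n_trials": 5,
    "n_photons": 200_000,
    "lfp_trials": 5,
    "lfp_fs_hz": 500.0,
}


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the configured stages and write results plus a manifest.

    Outputs under ``out_dir``: ``fluence.h5``, ``dose_model.json``,
    ``timecourses.csv``, an example rendered movie (TIFF + sidecar),
    ``lfp_friedman.json`` (when the lfp stage runs) and ``manifest.json``.
    Reruns with the same config and seed are bit-identical.
    """
    cfg = {**DEFAULT_CONFIG, **config}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = RunManifest(config=cfg, master_seed=seed)
    results: dict = {}

    stages = cfg["stages"]
    known = {"thermal_dose", "lfp"}
    unknown = set(stages) - known
    if unknown:
        raise PipelineError(str(sorted(unknown)), ValueError("unknown stage"))

    if "thermal_dose" in stages:
        try:
            res = thermal_dose_experiment(
                seed,
                irradiances_mw_mm2=cfg["irradiances_mw_mm2"],
                frequencies_hz=cfg["frequencies_hz"],
                wavelength_nm=cfg["wavelength_nm"],
                pulse_ms=cfg["pulse_ms"],
                n_trials=cfg["n_trials"],
                n_photons=cfg["n_photons"],
            )
            manifest.stage_seeds["mc_light"] = stage_seed(seed, "mc_light")
            write_fluence(out / "fluence.h5", res.fluence)
            res.table.to_csv(out / "timecourses.csv", index=False)
            dose = {
                "slope_c_per_power_duty": res.fitted_model.slope,
                "intercept_c": res.fitted_model.intercept,
                "r_squared": res.fitted_model.r_squared,
                "ground_truth_slope": res.ground_truth_model.slope,
                "wavelength_nm": cfg["wavelength_nm"],
            }
            (out / "dose_model.json").write_text(json.dumps(dose, indent=2))
            # example rendered movie for the strongest protocol
            proto = StimulationProtocol(
                cfg["wavelength_nm"], max(cfg["irradiances_mw_mm2"]),
                cfg["pulse_ms"], max(cfg["frequencies_hz"]),
            )
            q_c = coarsen(
                absorbed_power_map(
                    res.fluence, TissueOpticalProperties.brain(cfg["wavelength_nm"])
                ),
                2,
            )
            frames, times, _ = simulate_surface_movie(
                q_c, coarsen_grid(res.fluence.grid, 2), proto,
                TissueThermalProperties(),
            )
            cam = CameraModel(pixel_pitch_mm=coarsen_grid(res.fluence.grid, 2).spacing_mm)
            rec = render_thermal_movie(
                frames, cam, times_s=times, seed=stage_seed(seed, "demo_movie")
            )
            write_thermal_movie(out / "example_movie.tif", rec)
            manifest.checksums["fluence"] = array_checksum(res.fluence.values)
            manifest.checksums["dose_table"] = array_checksum(
                res.table.to_numpy(dtype=float)
            )
            manifest.checksums["example_movie"] = array_checksum(rec.grey)
            results["thermal_dose"] = dose
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate failing stage
            manifest.save(out / "manifest.json")
            raise PipelineError("thermal_dose", exc) from exc

    if "lfp" in stages:
        try:
            spec = SyntheticLFPSpec(sampling_rate_hz=cfg["lfp_fs_hz"]).null()
            traces = [
                generate_lfp(spec, seed=stage_seed(seed, f"lfp:{s}")).trace
                for s in range(cfg["lfp_trials"])
            ]
            bands_out = {}
            for band in ((6.0, 10.0), (15.0, 40.0), (60.0, 100.0)):
                table = lfp_phase_table(
                    traces, cfg["lfp_fs_hz"], band, spec.phase_boundaries_s
                )
                r = friedman_test(table)
                bands_out[f"{int(band[0])}-{int(band[1])}Hz"] = {
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "method": r.method,
                }
            (out / "lfp_friedman.json").write_text(json.dumps(bands_out, indent=2))
            manifest.checksums["lfp_traces"] = array_checksum(np.asarray(traces))
            results["lfp"] = bands_out
        except Exception as exc:  # noqa: BLE001
            manifest.save(out / "manifest.json")
            raise PipelineError("lfp", exc) from exc

    manifest.save(out / "manifest.json")
    results["manifest"] = str(out / "manifest.json")
    return results
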