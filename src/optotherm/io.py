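"""Readers/writers for the package's on-disk formats and the run manifest.

Formats: multi-frame TIFF (+ JSON sidecar) for movies and maps, HDF5 for
fluence/temperature grids and LFP traces, CSV for profiles, time courses and
calibration series, YAML for configuration.  All lengths are mm, times s,
temperatures °C, powers mW in serialized files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from optotherm.grid import VoxelGrid
from optotherm.mc_light import FluenceGrid
from optotherm.bioheat import TemperatureField
from optotherm.synth import CalibrationSeries, CameraModel, LFPRecord, ThermalMovieRecord

PathLike = Union[str, Path]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2³¹, derived by hashing the stage
    name with the master seed so stages can be rerun independently."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def array_checksum(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record written next to every pipeline output."""

    config: dict
    master_seed: int
    stage_seeds: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)
    created: str = ""
    package_version: str = ""

    def __post_init__(self) -> None:
        if not self.created:
            self.created = time.strftime("%Y-%m-%dT%H:%M:%S")
        if not self.package_version:
            from optotherm import __version__

            self.package_version = __version__

    def save(self, path: PathLike) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def load(cls, path: PathLike) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(**d)


# --------------------------------------------------------------------------
# thermal movies: 16-bit multi-frame TIFF + JSON sidecar

def write_thermal_movie(path: PathLike, record: ThermalMovieRecord) -> None:
    path = Path(path)
    tifffile.imwrite(path, record.grey, photometric="minisblack")
    sidecar = {
        "frame_rate_hz": record.camera.frame_rate_hz,
        "pixel_pitch_mm": record.camera.pixel_pitch_mm,
        "gain": record.camera.gain,
        "offset": record.camera.offset,
        "noise_sd_c": record.camera.noise_sd_c,
        "baseline_temp_c": record.baseline_temp_c,
        "seed": record.seed,
        "times_s": record.times_s.tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_thermal_movie(path: PathLike):
    """Read a multi-frame TIFF movie and its JSON sidecar.

    Returns (frames, metadata dict).  A missing sidecar produces explicit
    defaults (3 fps, 0.05 mm/pixel) with a warning.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
    else:
        warnings.warn(
            f"no sidecar for {path.name}; assuming 3 fps and 0.05 mm/pixel"
        )
        meta = {"frame_rate_hz": 3.0, "pixel_pitch_mm": 0.05}
    if "times_s" not in meta:
        meta["times_s"] = (np.arange(len(frames)) / meta["frame_rate_hz"]).tolist()
    return frames, meta


# --------------------------------------------------------------------------
# fluence / temperature grids: HDF5

def _write_grid(group: h5py.Group, grid: VoxelGrid) -> None:
    group.attrs["spacing_mm"] = grid.spacing_mm
    group.attrs["origin_mm"] = grid.origin_mm
    group.attrs["dims"] = grid.dims


def _read_grid(group: h5py.Group) -> VoxelGrid:
    return VoxelGrid(
        spacing_mm=float(group.attrs["spacing_mm"]),
        dims=tuple(int(d) for d in group.attrs["dims"]),
        origin_mm=tuple(float(c) for c in group.attrs["origin_mm"]),
    )


def write_fluence(path: PathLike, fl: FluenceGrid, properties: Optional[dict] = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=fl.values, compression="gzip")
        _write_grid(f, fl.grid)
        for name in (
            "source_irradiance_mw_mm2", "launched_weight", "absorbed_weight",
            "escaped_surface_weight", "escaped_domain_weight",
            "terminated_weight", "total_reflection_fraction", "n_photons", "seed",
        ):
            f.attrs[name] = getattr(fl, name)
        if properties:
            f.attrs["optical_properties"] = json.dumps(properties)


def read_fluence(path: PathLike) -> FluenceGrid:
    with h5py.File(path, "r") as f:
        grid = _read_grid(f)
        kw = {name: f.attrs[name] for name in (
            "source_irradiance_mw_mm2", "launched_weight", "absorbed_weight",
            "escaped_surface_weight", "escaped_domain_weight",
            "terminated_weight", "total_reflection_fraction",
        )}
        return FluenceGrid(
            grid=grid,
            values=f["values"][()],
            n_photons=int(f.attrs["n_photons"]),
            seed=int(f.attrs["seed"]),
            **{k: float(v) for k, v in kw.items()},
        )


def write_temperature(path: PathLike, field_: TemperatureField) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=field_.frames.astype(np.float32), compression="gzip")
        f.create_dataset("times_s", data=field_.times_s)
        _write_grid(f, field_.grid)
        f.attrs["max_dT_c"] = field_.max_dT_c
        f.attrs["tip_max_dT_c"] = field_.tip_max_dT_c
        if field_.surface_depth_mm is not None:
            f.attrs["surface_depth_mm"] = field_.surface_depth_mm


def read_temperature(path: PathLike) -> TemperatureField:
    with h5py.File(path, "r") as f:
        return TemperatureField(
            grid=_read_grid(f),
            times_s=f["times_s"][()],
            frames=f["frames"][()].astype(float),
            surface_depth_mm=(
                float(f.attrs["surface_depth_mm"]) if "surface_depth_mm" in f.attrs else None
            ),
            max_dT_c=float(f.attrs["max_dT_c"]),
            tip_max_dT_c=float(f.attrs["tip_max_dT_c"]),
        )


# --------------------------------------------------------------------------
# LFP traces: HDF5

def write_lfp(path: PathLike, rec: LFPRecord) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("trace", data=rec.trace)
        f.attrs["fs_hz"] = rec.fs_hz
        f.attrs["phase_boundaries_s"] = rec.phase_boundaries_s
        f.attrs["seed"] = rec.seed


def read_lfp(path: PathLike):
    with h5py.File(path, "r") as f:
        return (
            f["trace"][()],
            float(f.attrs["fs_hz"]),
            tuple(float(b) for b in f.attrs["phase_boundaries_s"]),
        )


# --------------------------------------------------------------------------
# calibration series and tabular outputs: CSV

def write_calibration_csv(path: PathLike, series: CalibrationSeries) -> None:
    pd.DataFrame(
        {
            "time_s": series.times_s,
            "grey_level": series.grey_levels,
            "reference_temperature_c": series.reference_temperatures_c,
        }
    ).to_csv(path, index=False)


def read_calibration_csv(path: PathLike) -> CalibrationSeries:
    df = pd.read_csv(path)
    return CalibrationSeries(
        times_s=df["time_s"].to_numpy(),
        grey_levels=df["grey_level"].to_numpy(),
        reference_temperatures_c=df["reference_temperature_c"].to_numpy(),
    )


def write_profile_csv(path: PathLike, profile) -> None:
    pd.DataFrame(
        {"distance_mm": profile.distances_mm, "value": profile.values}
    ).to_csv(path, index=False)


def load_config(path: PathLike) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def default_camera(meta: Optional[dict] = None) -> CameraModel:
    meta = meta or {}
    return CameraModel(
        gain=float(meta.get("gain", 100.0)),
        offset=float(meta.get("offset", 1000.0)),
        noise_sd_c=float(meta.get("noise_sd_c", 0.08)),
        frame_rate_hz=float(meta.get("frame_rate_hz", 3.0)),
        pixel_pitch_mm=float(meta.get("pixel_pitch_mm", 0.05)),
    )
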