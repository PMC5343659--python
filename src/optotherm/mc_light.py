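"""Voxelized Monte Carlo photon transport from a multimode fiber in brain tissue.

Weighted photon packets are launched from the fiber exit face, take
exponentially distributed steps (μt = μa + μs), deposit absorption weight
continuously along their path (pathlength fluence estimator), deflect by the
Henyey–Greenstein phase function, and are terminated by Russian roulette at
low weight.  The plane z = 0 is a smooth brain–air interface: packets hitting
it beyond the critical angle for n_tissue → n_air undergo total internal
reflection (tallied per packet), otherwise unpolarized Fresnel reflection /
refraction is sampled.  Packets leaving the voxel grid through any other face
are terminated as escaped.

Fluence is scored per voxel as Σ w·Δl / V and scaled so the fluence across
the fiber exit face equals the source irradiance; with a unit source the grid
therefore holds fluence rate per unit fiber-exit irradiance (dimensionless),
and multiplying by a protocol irradiance in mW/mm² gives absolute fluence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from numba import njit

from optotherm.grid import VoxelGrid
from optotherm.protocol import FiberSource

N_AIR = 1.0

#: Literature-based homogeneous rat-cortex optical properties (overridable):
#: absorption and reduced scattering are both higher in the blue, which is why
#: red light penetrates deeper.
BRAIN_OPTICAL_DEFAULTS = {
    638: dict(mu_a_mm=0.06, mu_s_mm=7.0, g=0.88, n=1.36),
    476: dict(mu_a_mm=0.15, mu_s_mm=10.0, g=0.88, n=1.36),
}


@dataclass(frozen=True)
class TissueOpticalProperties:
    """Homogeneous optical properties: μa, μs (1/mm), anisotropy g, index n."""

    mu_a_mm: float
    mu_s_mm: float
    g: float
    n: float = 1.36

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mu_a_mm) and self.mu_a_mm >= 0):
            raise ValueError("mu_a must be finite and >= 0")
        if not (math.isfinite(self.mu_s_mm) and self.mu_s_mm >= 0):
            raise ValueError("mu_s must be finite and >= 0")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError("anisotropy g must be in [-1, 1]")
        if not self.n >= 1.0:
            raise ValueError("refractive index must be >= 1")

    @property
    def mu_t_mm(self) -> float:
        return self.mu_a_mm + self.mu_s_mm

    @property
    def reduced_mu_s_mm(self) -> float:
        return self.mu_s_mm * (1.0 - self.g)

    @classmethod
    def brain(cls, wavelength_nm: float) -> "TissueOpticalProperties":
        key = int(round(wavelength_nm))
        if key not in BRAIN_OPTICAL_DEFAULTS:
            raise ValueError(
                f"no default brain properties at {wavelength_nm} nm; "
                f"available: {sorted(BRAIN_OPTICAL_DEFAULTS)}"
            )
        return cls(**BRAIN_OPTICAL_DEFAULTS[key])

    def scaled(self, mu_a_factor: float = 1.0, mu_s_factor: float = 1.0):
        return replace(
            self, mu_a_mm=self.mu_a_mm * mu_a_factor, mu_s_mm=self.mu_s_mm * mu_s_factor
        )


@dataclass
class FluenceGrid:
    """Fluence rate per voxel plus Monte Carlo interface/weight statistics.

    ``values`` is fluence in mW/mm² for the source irradiance passed to
    :func:`propagate` (per-unit-irradiance when that is 1).  Weights are in
    units of launched packets.
    """

    grid: VoxelGrid
    values: np.ndarray
    source_irradiance_mw_mm2: float
    launched_weight: float
    absorbed_weight: float
    escaped_surface_weight: float
    escaped_domain_weight: float
    terminated_weight: float
    total_reflection_fraction: float
    n_photons: int
    seed: int

    @property
    def escaped_weight(self) -> float:
        return self.escaped_surface_weight + self.escaped_domain_weight

    def weight_balance_error(self) -> float:
        """Relative imbalance of launched vs accounted weight (should be ~0)."""
        acc = self.absorbed_weight + self.escaped_weight + self.terminated_weight
        return abs(acc - self.launched_weight) / self.launched_weight

    def axial_profile(
        self,
        source: FiberSource,
        step_mm: Optional[float] = None,
        radius_mm: float = 0.15,
    ):
        """Fluence along the fiber axis from the tip.

        Returns (distances_mm, values) sampled at voxel-center spacing by
        trilinear interpolation, averaged over perpendicular offsets within
        ``radius_mm`` of the axis to suppress single-voxel Monte Carlo noise
        at depth; used for penetration-depth work.
        """
        from scipy.ndimage import map_coordinates

        h = self.grid.spacing_mm
        step = h if step_mm is None else step_mm
        tip = np.asarray(source.tip_mm)
        ax = np.asarray(source.axis, dtype=float)
        e1, e2 = _orthonormal_basis(ax)
        # perpendicular offsets on the voxel lattice within radius_mm
        m = int(radius_mm / h)
        offs = []
        for a in range(-m, m + 1):
            for b in range(-m, m + 1):
                if math.hypot(a * h, b * h) <= radius_mm:
                    offs.append(a * h * e1 + b * h * e2)
        offs = np.asarray(offs) if offs else np.zeros((1, 3))
        # max distance until leaving the grid
        dmax = 0.0
        while self.grid.contains_point(tip + (dmax + step) * ax):
            dmax += step
        dists = np.arange(0.0, dmax + step / 2, step)
        vals = np.zeros(len(dists))
        for off in offs:
            pts = tip[None, :] + dists[:, None] * ax[None, :] + off[None, :]
            coords = (pts - np.asarray(self.grid.origin_mm)) / h - 0.5
            vals += map_coordinates(self.values, coords.T, order=1, mode="nearest")
        return dists, vals / len(offs)


def fresnel_unpolarized(theta_i_rad: float, n1: float, n2: float) -> float:
    """Unpolarized Fresnel reflectance for light going from index n1 to n2.

    Mean of the s- and p-polarized reflectances; returns 1 at and beyond the
    critical angle when n1 > n2.
    """
    if not 0.0 <= theta_i_rad <= math.pi / 2 + 1e-12:
        raise ValueError("incidence angle must be in [0, pi/2]")
    sin_i = math.sin(theta_i_rad)
    sin_t = sin_i * n1 / n2
    if sin_t >= 1.0:
        return 1.0
    cos_i = math.cos(theta_i_rad)
    cos_t = math.sqrt(1.0 - sin_t * sin_t)
    rs = ((n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)) ** 2
    rp = ((n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)) ** 2
    return 0.5 * (rs + rp)


def critical_angle_rad(n1: float, n2: float) -> float:
    """Total-internal-reflection threshold asin(n2/n1) (requires n1 > n2)."""
    if n1 <= n2:
        raise ValueError("total reflection requires n1 > n2")
    return math.asin(n2 / n1)


def sample_launch(
    n: int, source: FiberSource, n_tissue: float, rng: np.random.Generator
):
    """Sample initial packet positions and directions at the fiber exit.

    Positions are uniform on the core disc (perpendicular to the axis);
    directions are uniform in solid angle within the emission cone of
    half-angle asin(NA / n_tissue) about the axis.
    """
    half = source.cone_half_angle_rad(n_tissue)  # validates NA < n
    ax = np.asarray(source.axis, dtype=float)
    e1, e2 = _orthonormal_basis(ax)
    r = source.radius_mm * np.sqrt(rng.random(n))
    phi = 2.0 * math.pi * rng.random(n)
    pos = (
        np.asarray(source.tip_mm)[None, :]
        + r[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
    )
    cos_t = 1.0 - rng.random(n) * (1.0 - math.cos(half))
    sin_t = np.sqrt(1.0 - cos_t**2)
    psi = 2.0 * math.pi * rng.random(n)
    dirs = (
        cos_t[:, None] * ax[None, :]
        + (sin_t * np.cos(psi))[:, None] * e1
        + (sin_t * np.sin(psi))[:, None] * e2
    )
    return pos, dirs


def _orthonormal_basis(axis: np.ndarray):
    helper = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


@njit(cache=True, fastmath=True)
def _transport_kernel(
    seed,
    n_photons,
    tipx, tipy, tipz,
    axx, axy, axz,
    e1x, e1y, e1z,
    e2x, e2y, e2z,
    radius,
    cos_half,
    mua, mus, g, n_rel,
    has_interface,
    x0, y0, z0, h, nx, ny, nz,
    w_thresh, m_roulette,
    path,
):  # pragma: no cover - exercised through propagate()
    np.random.seed(seed)
    mut = mua + mus
    # sin^2 of the critical angle (tissue -> air); >1 disables TIR
    if n_rel > 1.0:
        crit_sin2 = 1.0 / (n_rel * n_rel)
    else:
        crit_sin2 = 2.0
    absorbed = 0.0
    esc_surface = 0.0
    esc_domain = 0.0
    terminated = 0.0
    tir_packets = 0
    inv_m = 1.0 / m_roulette

    for _ in range(n_photons):
        # --- launch: uniform disc position, uniform-solid-angle cone direction
        r = radius * math.sqrt(np.random.random())
        phi = 2.0 * math.pi * np.random.random()
        cp = math.cos(phi)
        sp = math.sin(phi)
        px = tipx + r * (cp * e1x + sp * e2x)
        py = tipy + r * (cp * e1y + sp * e2y)
        pz = tipz + r * (cp * e1z + sp * e2z)
        ct = 1.0 - np.random.random() * (1.0 - cos_half)
        st = math.sqrt(max(0.0, 1.0 - ct * ct))
        psi = 2.0 * math.pi * np.random.random()
        cps = math.cos(psi)
        sps = math.sin(psi)
        ux = ct * axx + st * (cps * e1x + sps * e2x)
        uy = ct * axy + st * (cps * e1y + sps * e2y)
        uz = ct * axz + st * (cps * e1z + sps * e2z)

        ix = int((px - x0) / h)
        iy = int((py - y0) / h)
        iz = int((pz - z0) / h)
        w = 1.0
        had_tir = False
        alive = True

        while alive:
            if mut > 0.0:
                s = -math.log(np.random.random()) / mut
            else:
                s = 1.0e30
            # --- march the step through the voxel grid
            while s > 0.0:
                if ux > 0.0:
                    tx = ((x0 + (ix + 1) * h) - px) / ux
                elif ux < 0.0:
                    tx = ((x0 + ix * h) - px) / ux
                else:
                    tx = 1.0e30
                if uy > 0.0:
                    ty = ((y0 + (iy + 1) * h) - py) / uy
                elif uy < 0.0:
                    ty = ((y0 + iy * h) - py) / uy
                else:
                    ty = 1.0e30
                if uz > 0.0:
                    tz = ((z0 + (iz + 1) * h) - pz) / uz
                elif uz < 0.0:
                    tz = ((z0 + iz * h) - pz) / uz
                else:
                    tz = 1.0e30
                tb = min(tx, min(ty, tz))
                if tb < 0.0:
                    tb = 0.0
                if tb >= s:
                    path[ix, iy, iz] += w * s
                    px += ux * s
                    py += uy * s
                    pz += uz * s
                    s = 0.0
                    break
                path[ix, iy, iz] += w * tb
                px += ux * tb
                py += uy * tb
                pz += uz * tb
                s -= tb
                if tb == tx:
                    if ux > 0.0:
                        ix += 1
                        px = x0 + ix * h
                        if ix >= nx:
                            esc_domain += w
                            alive = False
                            break
                    else:
                        px = x0 + ix * h
                        ix -= 1
                        if ix < 0:
                            esc_domain += w
                            alive = False
                            break
                elif tb == ty:
                    if uy > 0.0:
                        iy += 1
                        py = y0 + iy * h
                        if iy >= ny:
                            esc_domain += w
                            alive = False
                            break
                    else:
                        py = y0 + iy * h
                        iy -= 1
                        if iy < 0:
                            esc_domain += w
                            alive = False
                            break
                else:
                    if uz > 0.0:
                        iz += 1
                        pz = z0 + iz * h
                        if iz >= nz:
                            esc_domain += w
                            alive = False
                            break
                    else:
                        pz = z0 + iz * h
                        iz -= 1
                        if iz < 0:
                            if has_interface:
                                # brain-air interface at z = 0
                                cosi = -uz
                                sin2 = 1.0 - cosi * cosi
                                if sin2 >= crit_sin2:
                                    if not had_tir:
                                        tir_packets += 1
                                        had_tir = True
                                    uz = -uz
                                    iz = 0
                                else:
                                    # unpolarized Fresnel, n_rel = n1/n2
                                    sint = math.sqrt(sin2) * n_rel
                                    cost = math.sqrt(max(0.0, 1.0 - sint * sint))
                                    rs = (n_rel * cosi - cost) / (n_rel * cosi + cost)
                                    rp = (n_rel * cost - cosi) / (n_rel * cost + cosi)
                                    refl = 0.5 * (rs * rs + rp * rp)
                                    if np.random.random() < refl:
                                        uz = -uz
                                        iz = 0
                                    else:
                                        esc_surface += w
                                        alive = False
                                        break
                            else:
                                esc_domain += w
                                alive = False
                                break
            if not alive:
                break
            if mut <= 0.0:
                # vacuum: a straight flight must exit the grid
                esc_domain += w
                break
            # --- absorb
            dw = w * mua / mut
            absorbed += dw
            w -= dw
            if mus <= 0.0 or w <= 0.0:
                terminated += w
                break
            # --- Henyey-Greenstein deflection
            u = np.random.random()
            if g != 0.0:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
                cost = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                if cost > 1.0:
                    cost = 1.0
                elif cost < -1.0:
                    cost = -1.0
            else:
                cost = 2.0 * u - 1.0
            sint = math.sqrt(1.0 - cost * cost)
            phi2 = 2.0 * math.pi * np.random.random()
            cosp = math.cos(phi2)
            sinp = math.sin(phi2)
            if abs(uz) > 0.99999:
                ux = sint * cosp
                uy = sint * sinp
                uz = cost if uz > 0.0 else -cost
            else:
                denom = math.sqrt(1.0 - uz * uz)
                nux = sint * (ux * uz * cosp - uy * sinp) / denom + ux * cost
                nuy = sint * (uy * uz * cosp + ux * sinp) / denom + uy * cost
                nuz = -sint * cosp * denom + uz * cost
                norm = math.sqrt(nux * nux + nuy * nuy + nuz * nuz)
                ux = nux / norm
                uy = nuy / norm
                uz = nuz / norm
            # --- Russian roulette
            if w < w_thresh:
                if np.random.random() < inv_m:
                    terminated -= (m_roulette - 1.0) * w
                    w *= m_roulette
                else:
                    terminated += w
                    break

    return absorbed, esc_surface, esc_domain, terminated, tir_packets


def propagate(
    n_photons: int,
    source: FiberSource,
    props: TissueOpticalProperties,
    grid: Optional[VoxelGrid] = None,
    seed: int = 0,
    source_irradiance_mw_mm2: float = 1.0,
    roulette_threshold: float = 1e-4,
    roulette_survival: float = 10.0,
) -> FluenceGrid:
    """Run the photon-transport simulation and score a fluence grid.

    Parameters
    ----------
    n_photons : int
        Number of photon packets (≥ 1).
    source : FiberSource
        Fiber geometry; its tip must lie inside ``grid``.
    props : TissueOpticalProperties
        Homogeneous tissue optical properties.
    grid : VoxelGrid, optional
        Scoring grid; defaults to the 12×12×6 mm tissue block at 0.1 mm.
        A grid whose low-z face sits at z = 0 has the brain–air interface
        there; any other grid face terminates packets as escaped.
    seed : int
        Seed for the single RNG stream driving launch and transport.
    source_irradiance_mw_mm2 : float
        Fiber-exit irradiance the fluence is scaled to (1 → per-unit grid).
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if grid is None:
        grid = VoxelGrid.default_tissue()
    if not grid.contains_point(source.tip_mm):
        raise ValueError("grid too small: fiber tip outside the voxel grid")
    if source.numerical_aperture >= props.n:
        raise ValueError("fiber NA must be smaller than the tissue index")

    ax = np.asarray(source.axis, dtype=float)
    e1, e2 = _orthonormal_basis(ax)
    half = source.cone_half_angle_rad(props.n)
    has_interface = abs(grid.origin_mm[2]) < 1e-12

    path = np.zeros(grid.dims, dtype=np.float64)
    absorbed, esc_surf, esc_dom, terminated, tir = _transport_kernel(
        np.uint32(seed & 0x7FFFFFFF),
        n_photons,
        source.tip_mm[0], source.tip_mm[1], source.tip_mm[2],
        ax[0], ax[1], ax[2],
        e1[0], e1[1], e1[2],
        e2[0], e2[1], e2[2],
        source.radius_mm,
        math.cos(half),
        props.mu_a_mm, props.mu_s_mm, props.g, props.n / N_AIR,
        has_interface,
        grid.origin_mm[0], grid.origin_mm[1], grid.origin_mm[2],
        grid.spacing_mm, grid.dims[0], grid.dims[1], grid.dims[2],
        roulette_threshold, roulette_survival,
        path,
    )

    # pathlength estimator -> fluence, scaled to the requested irradiance:
    # each packet carries E * A_fiber / N of optical power.
    power_per_packet = source_irradiance_mw_mm2 * source.area_mm2 / n_photons
    values = path * (power_per_packet / grid.voxel_volume_mm3)

    return FluenceGrid(
        grid=grid,
        values=values,
        source_irradiance_mw_mm2=source_irradiance_mw_mm2,
        launched_weight=float(n_photons),
        absorbed_weight=absorbed,
        escaped_surface_weight=esc_surf,
        escaped_domain_weight=esc_dom,
        terminated_weight=terminated,
        total_reflection_fraction=tir / n_photons,
        n_photons=n_photons,
        seed=seed,
    )


def absorbed_power_map(fluence: FluenceGrid, props: TissueOpticalProperties) -> np.ndarray:
    """Volumetric heat source q = μa · Φ (mW/mm³ per voxel)."""
    return props.mu_a_mm * fluence.values


def absorbed_power_total_mw(q: np.ndarray, grid: VoxelGrid) -> float:
    """∫ q dV over the grid, for tally-consistency checks."""
    return float(q.sum() * grid.voxel_volume_mm3)
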