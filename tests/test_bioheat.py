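import math

import numpy as np
import pytest
from scipy.special import erfc

from optotherm.bioheat import (
    TemperatureField,
    TissueThermalProperties,
    solve,
    stability_dt_s,
    surface_projection,
    tip_correction,
)
from optotherm.grid import VoxelGrid
from optotherm.protocol import StimulationProtocol


@pytest.fixture(scope="module")
def small_grid():
    return VoxelGrid(0.2, (20, 20, 20), (-2.0, -2.0, 0.0))


@pytest.fixture(scope="module")
def no_perfusion():
    return TissueThermalProperties(perfusion_per_s=0.0)


def short_protocol(stim_s=5.0, post_s=0.0, freq_hz=40.0, pulse_ms=5.0):
    return StimulationProtocol(638, 600, pulse_ms, freq_hz, stim_s=stim_s, post_s=post_s)


class TestSolve:
    def test_zero_source_stays_at_baseline(self, small_grid):
        f = solve(
            np.zeros(small_grid.dims),
            TissueThermalProperties(),
            short_protocol(),
            small_grid,
            store="full",
        )
        assert np.all(f.frames == 0.0)

    def test_energy_conservation_insulated(self, small_grid, no_perfusion):
        """With insulated boundaries and no perfusion, the final enthalpy
        equals the duty-weighted injected optical energy."""
        q = np.zeros(small_grid.dims)
        q[10, 10, 10] = 5.0  # mW/mm^3
        proto = short_protocol()
        f = solve(
            q, no_perfusion, proto, small_grid,
            store="full", boundary_z0="insulated", boundary_far="insulated",
        )
        enthalpy = (
            f.frames[-1].sum() * small_grid.voxel_volume_mm3
            * no_perfusion.rho_c_mj_mm3_c
        )
        injected = q.sum() * small_grid.voxel_volume_mm3 * proto.duty * proto.stim_s
        assert enthalpy == pytest.approx(injected, rel=0.01)

    def test_point_source_matches_greens_function(self, no_perfusion):
        """Transient response to a continuous point source in effectively
        infinite medium: ΔT(r,t) = P/(4πkr) · erfc(r / 2√(αt)), checked at
        r ≥ 5 voxels within 5%."""
        grid = VoxelGrid(0.1, (61, 61, 61), (-3.05, -3.05, 0.0))
        q = np.zeros(grid.dims)
        P = 10.0
        q[30, 30, 30] = P / grid.voxel_volume_mm3
        proto = short_protocol(stim_s=3.0, freq_hz=40.0, pulse_ms=25.0)  # duty 1
        f = solve(
            q, no_perfusion, proto, grid,
            store="full", boundary_z0="dirichlet", boundary_far="dirichlet",
        )
        T, t = f.frames[-1], f.times_s[-1]
        alpha, k = no_perfusion.diffusivity_mm2_s, no_perfusion.k_mw_mm_c
        centers = [grid.axis_centers(a) for a in range(3)]
        X, Y, Z = np.meshgrid(*centers, indexing="ij")
        r = np.sqrt(
            (X - centers[0][30]) ** 2
            + (Y - centers[1][30]) ** 2
            + (Z - centers[2][30]) ** 2
        )
        for rv in (0.5, 0.8, 1.2):
            shell = np.abs(r - rv) < 0.02
            analytic = P / (4 * math.pi * k * rv) * erfc(rv / (2 * math.sqrt(alpha * t)))
            assert T[shell].mean() == pytest.approx(analytic, rel=0.05)

    def test_linearity_in_source_amplitude(self, small_grid, no_perfusion):
        q = np.zeros(small_grid.dims)
        q[10, 10, 5] = 2.0
        f1 = solve(q, no_perfusion, short_protocol(), small_grid, store="full")
        f2 = solve(2 * q, no_perfusion, short_protocol(), small_grid, store="full")
        assert np.allclose(f2.frames, 2 * f1.frames, rtol=1e-10, atol=1e-14)

    def test_unstable_timestep_refused(self, small_grid):
        props = TissueThermalProperties()
        bound = stability_dt_s(small_grid, props)
        with pytest.raises(ValueError, match="stability bound"):
            solve(
                np.zeros(small_grid.dims), props, short_protocol(), small_grid,
                dt_s=bound * 2,
            )

    def test_grid_mismatch_refused(self, small_grid):
        with pytest.raises(ValueError, match="shape"):
            solve(
                np.zeros((4, 4, 4)), TissueThermalProperties(), short_protocol(),
                small_grid,
            )

    def test_decay_after_source_off_with_perfusion(self, small_grid):
        """Once the light turns off, the peak ΔT decays monotonically."""
        q = np.zeros(small_grid.dims)
        q[10, 10, 5] = 5.0
        props = TissueThermalProperties(perfusion_per_s=0.01)
        f = solve(q, props, short_protocol(stim_s=5.0, post_s=30.0), small_grid,
                  store="full")
        maxima = f.frames.max(axis=(1, 2, 3))
        post = maxima[f.times_s > 6.0]
        assert np.all(np.diff(post) <= 1e-12)

    def test_grid_refinement_converged(self, no_perfusion):
        """Halving the voxel size changes the peak ΔT by < 3%."""
        results = {}
        for h in (0.2, 0.1):
            grid = VoxelGrid(h, tuple(int(round(4.0 / h)) for _ in range(3)),
                             (-2.0, -2.0, 0.0))
            q = np.zeros(grid.dims)
            centers = [grid.axis_centers(a) for a in range(3)]
            X, Y, Z = np.meshgrid(*centers, indexing="ij")
            # smooth Gaussian heat blob, identical in physical space
            q[:] = 5.0 * np.exp(
                -((X - 0.0) ** 2 + (Y - 0.0) ** 2 + (Z - 2.0) ** 2) / (2 * 0.3**2)
            )
            f = solve(q, no_perfusion, short_protocol(stim_s=10.0), grid,
                      store="full", boundary_z0="insulated")
            results[h] = f.max_dT_c
        assert results[0.1] == pytest.approx(results[0.2], rel=0.03)

    def test_pulsed_source_matches_duty_average(self, small_grid, no_perfusion):
        """Explicit ms-pulse gating and the duty-averaged source agree on the
        end-of-stimulation field for a spatially smooth source (pulse period
        ≪ thermal time constants of the heated region)."""
        centers = [small_grid.axis_centers(a) for a in range(3)]
        X, Y, Z = np.meshgrid(*centers, indexing="ij")
        q = 5.0 * np.exp(-((X**2 + Y**2 + (Z - 1.0) ** 2)) / (2 * 0.3**2))
        proto = short_protocol(stim_s=4.0, freq_hz=40.0)
        dt = 1.0 / 1600.0  # resolve the 5 ms pulses
        avg = solve(q, no_perfusion, proto, small_grid, dt_s=dt, store="full")
        pulsed = solve(
            q, no_perfusion, proto, small_grid, dt_s=dt, store="full",
            pulsed_source=True,
        )
        assert pulsed.frames[-1].max() == pytest.approx(
            avg.frames[-1].max(), rel=0.05
        )


class TestSurfaceProjection:
    def make_field(self, frames, grid):
        times = np.arange(len(frames), dtype=float) + 1.0
        return TemperatureField(grid=grid, times_s=times, frames=np.asarray(frames))

    def test_uniform_field(self):
        grid = VoxelGrid(0.05, (4, 4, 4), (0.0, 0.0, 0.0))
        f = self.make_field([np.full(grid.dims, 2.5)], grid)
        assert np.allclose(surface_projection(f, 0.1), 2.5)

    def test_linear_in_depth(self):
        """ΔT = a·z with 0.05 mm voxels and 0.1 mm integration: the top two
        voxel centers are 0.025 and 0.075 mm, so the map is a·0.05."""
        grid = VoxelGrid(0.05, (4, 4, 4), (0.0, 0.0, 0.0))
        a = 3.0
        z = grid.axis_centers(2)
        frame = np.broadcast_to(a * z, grid.dims).copy()
        f = self.make_field([frame], grid)
        assert np.allclose(surface_projection(f, 0.1), a * 0.05)

    def test_single_hot_column(self):
        grid = VoxelGrid(0.1, (5, 5, 5), (0.0, 0.0, 0.0))
        frame = np.zeros(grid.dims)
        frame[2, 3, 0] = 1.0
        f = self.make_field([frame], grid)
        proj = surface_projection(f, 0.1)
        assert proj[0, 2, 3] > 0
        proj[0, 2, 3] = 0.0
        assert np.all(proj == 0)

    def test_depth_below_spacing_rejected(self):
        grid = VoxelGrid(0.2, (4, 4, 4), (0.0, 0.0, 0.0))
        f = self.make_field([np.zeros(grid.dims)], grid)
        with pytest.raises(ValueError, match="depth"):
            surface_projection(f, 0.1)


class TestTipCorrection:
    @pytest.mark.parametrize(
        "surface, factor, expected", [(0.2, 1.5, 0.3), (1.0, 1.0, 1.0)]
    )
    def test_multiplicative(self, surface, factor, expected):
        assert tip_correction(surface, factor) == pytest.approx(expected)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            tip_correction(-0.1)

    def test_simulated_tip_exceeds_surface_reading(self, fluence_small, red_props):
        """The hottest tissue voxel (near the fiber tip) reads higher than
        the camera-style surface projection; the simulated ratio sits in a
        modest band — diffusion flattens vertical gradients by the end of a
        90 s stimulation."""
        from optotherm.mc_light import absorbed_power_map
        from optotherm.pipeline import coarsen, coarsen_grid

        q = coarsen(absorbed_power_map(fluence_small, red_props), 2) * 600.0
        grid = coarsen_grid(fluence_small.grid, 2)
        proto = StimulationProtocol(638, 600, 5, 40, post_s=0.0)
        tip_idx = grid.index_of((0.25, 0.0, 0.5))
        f = solve(q, TissueThermalProperties(), proto, grid,
                  store="surface", surface_depth_mm=0.2, tip_index=tip_idx)
        ratio = f.max_dT_c / f.frames.max()
        assert 1.05 < ratio < 2.0


class TestTemperatureField:
    def test_times_must_increase(self):
        grid = VoxelGrid(0.1, (2, 2, 2), (0.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="increasing"):
            TemperatureField(
                grid=grid, times_s=np.array([0.0, 0.0]),
                frames=np.zeros((2, 2, 2, 2)),
            )

    def test_frames_must_be_finite(self):
        grid = VoxelGrid(0.1, (2, 2, 2), (0.0, 0.0, 0.0))
        bad = np.zeros((1, 2, 2, 2))
        bad[0, 0, 0, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            TemperatureField(grid=grid, times_s=np.array([1.0]), frames=bad)
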