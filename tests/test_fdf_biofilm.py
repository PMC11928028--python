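"""Tests for the 3D agent-based fire-diffuse-fire simulator."""

import math

import numpy as np
import pytest
from dataclasses import replace

from biofilm_electro.fdf_biofilm import (BiofilmGeometry, CellState,
                                         FDFParams, PotassiumField,
                                         build_spherical_biofilm,
                                         diffuse_step, find_critical_radius,
                                         fire_update, global_tht_trace,
                                         propagation_success, run_simulation,
                                         SimFrame)


def brute_force_lattice_count(radius: float, spacing: float) -> int:
    """Independent enumeration of lattice points inside the sphere."""
    kmax = int(math.floor(radius / spacing))
    count = 0
    for i in range(-kmax, kmax + 1):
        for j in range(-kmax, kmax + 1):
            for k in range(-kmax, kmax + 1):
                if spacing * math.sqrt(i * i + j * j + k * k) <= radius + 1e-9:
                    count += 1
    return max(count, 1)


class TestGeometry:
    def test_tiny_radius_single_cell(self):
        geo = build_spherical_biofilm(radius=0.1, spacing=1.5, jitter=0.0)
        assert geo.n_cells == 1
        assert np.allclose(geo.positions[0], 0.0, atol=0.1)

    @pytest.mark.parametrize("radius", [3.0, 5.5, 8.0])
    def test_cell_count_matches_lattice_enumeration(self, radius):
        geo = build_spherical_biofilm(radius=radius, spacing=1.5, jitter=0.0)
        assert geo.n_cells == brute_force_lattice_count(radius, 1.5)

    def test_deterministic_per_seed(self):
        a = build_spherical_biofilm(radius=6.0, spacing=1.5, jitter=0.2, seed=3)
        b = build_spherical_biofilm(radius=6.0, spacing=1.5, jitter=0.2, seed=3)
        assert np.array_equal(a.positions, b.positions)

    def test_all_cells_inside_radius(self):
        geo = build_spherical_biofilm(radius=6.0, spacing=1.5, jitter=0.3, seed=1)
        assert np.all(geo.radial_distance <= 6.0 + 1e-9)

    def test_agent_limit_reports_count(self):
        with pytest.raises(ValueError, match=r"\d+ agents"):
            build_spherical_biofilm(radius=40.0, spacing=1.5, max_agents=1000)

    def test_cell_records(self):
        geo = build_spherical_biofilm(radius=2.0, spacing=1.5, jitter=0.0)
        cells = geo.cells
        assert len(cells) == geo.n_cells
        assert all(c.state == "quiescent" for c in cells)


class TestDiffusion:
    def test_mass_conserved_without_decay(self):
        # interior point source, absorbing walls far away
        field = PotassiumField.for_domain(half_width=15.0, dx=1.0)
        field.deposit(np.array([[0.0, 0.0, 0.0]]), np.array([100.0]))
        mass0 = field.total_mass()
        for _ in range(20):
            before = field.total_mass()
            field = diffuse_step(field, D=1.0, k_decay=0.0, dt=0.15)
            assert abs(field.total_mass() - before) / mass0 < 1e-3
        assert abs(field.total_mass() - mass0) / mass0 < 0.01

    def test_point_release_spreads_like_heat_kernel(self):
        """The second moment of a point release grows as 2 D t per axis."""
        D = 1.5
        field = PotassiumField.for_domain(half_width=20.0, dx=1.0,
                                          boundary="reflective")
        field.deposit(np.array([[0.0, 0.0, 0.0]]), np.array([1.0]))
        n = field.grid.shape[0]
        ax = field.origin[0] + np.arange(n)
        X = ax[:, None, None]
        dt = 0.1
        times, variances = [], []
        for step in range(1, 61):
            field = diffuse_step(field, D=D, k_decay=0.0, dt=dt)
            if step % 10 == 0:
                w = field.grid / field.grid.sum()
                var_x = float((w * X**2).sum())
                times.append(step * dt)
                variances.append(var_x)
        slope = np.polyfit(times, variances, 1)[0]
        assert slope == pytest.approx(2.0 * D, rel=0.05)

    def test_pure_decay(self):
        field = PotassiumField.for_domain(half_width=5.0, dx=1.0,
                                          boundary="reflective")
        field.grid[:] = 3.0
        r, dt = 0.4, 0.1
        out = diffuse_step(field, D=0.0, k_decay=r, dt=dt)
        assert np.allclose(out.grid, 3.0 * (1.0 - r * dt))

    def test_stability_checked_before_stepping(self):
        field = PotassiumField.for_domain(half_width=5.0, dx=1.0)
        with pytest.raises(ValueError, match="stability"):
            diffuse_step(field, D=10.0, k_decay=0.0, dt=1.0)

    def test_non_negativity(self):
        field = PotassiumField.for_domain(half_width=8.0, dx=1.0)
        field.deposit(np.array([[0.0, 0.0, 0.0]]), np.array([50.0]))
        for _ in range(50):
            field = diffuse_step(field, D=1.0, k_decay=0.3, dt=0.15)
            assert np.all(field.grid >= 0.0)


def _two_cell_setup(sigma=60.0, D=2.0, k=0.2, dt=0.05, t_fire=0.5):
    params = replace(
        FDFParams(), D=D, k_decay=k, dt=dt, t_fire=t_fire,
        sigma_release=sigma, jitter=0.0, interior_decay_fraction=1.0,
        k_uptake=0.0,
    )
    geo = BiofilmGeometry(
        positions=np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]]),
        radius=1.5, spacing=1.5, bounding_box=9.0,
    )
    field = PotassiumField.for_domain(half_width=9.0, dx=1.5)
    return params, geo, field


class TestFireUpdate:
    def test_no_firing_only_decay(self):
        params, geo, field = _two_cell_setup()
        geo.tht[:] = 1.0
        geo.states[:] = CellState.REFRACTORY  # fired cells decay
        fire_update(geo, field, params, t=0.0)
        assert np.all(geo.tht < 1.0)
        assert np.all(geo.states == CellState.REFRACTORY)

    def test_threshold_is_inclusive(self):
        params, geo, field = _two_cell_setup()
        # put the cell's local concentration exactly at threshold
        i = tuple(((geo.positions[0] - field.origin) / field.dx).astype(int))
        field.grid[i] = params.c_thresh
        fire_update(geo, field, params, t=0.0)
        assert geo.states[0] == CellState.FIRING

    def test_relay_delay_matches_independent_integration(self):
        """The second cell fires when the diffusing pulse first crosses
        threshold, as computed by an independently built sparse-operator
        integration of the same discretized dynamics."""
        from scipy.sparse import identity, kron, diags

        params, geo, field = _two_cell_setup()
        # drive the simulation: cell 0 forced to fire at t=0
        geo.states[0] = CellState.FIRING
        geo.fire_time[0] = 0.0
        f = field
        n_steps = 200
        for step in range(n_steps):
            f = diffuse_step(f, params.D, params.k_decay, params.dt)
            geo, f = fire_update(geo, f, params, t=step * params.dt)
            if np.isfinite(geo.fire_time[1]):
                break
        assert np.isfinite(geo.fire_time[1]), "second cell never fired"

        # independent oracle: explicit Euler with a sparse 3D Laplacian
        n = field.grid.shape[0]
        lap1 = diags([1.0, -2.0, 1.0], [-1, 0, 1], shape=(n, n)) / field.dx**2
        eye = identity(n)
        L = (kron(kron(lap1, eye), eye) + kron(kron(eye, lap1), eye)
             + kron(kron(eye, eye), lap1))
        c = np.zeros(n**3)
        iA = np.ravel_multi_index(
            tuple(((geo.positions[0] - field.origin) / field.dx).astype(int)),
            (n, n, n))
        iB = np.ravel_multi_index(
            tuple(((geo.positions[1] - field.origin) / field.dx).astype(int)),
            (n, n, n))
        rate = params.sigma_release / params.t_fire / field.voxel_volume
        t_oracle = None
        for step in range(n_steps):
            t = step * params.dt
            c = c + params.dt * (params.D * (L @ c) - params.k_decay * c)
            if t < params.t_fire:
                c[iA] += rate * params.dt
            if c[iB] >= params.c_thresh:
                t_oracle = t
                break
        assert t_oracle is not None
        assert geo.fire_time[1] == pytest.approx(t_oracle, abs=2 * params.dt)


@pytest.fixture(scope="module")
def small_run():
    params = FDFParams()
    geo = build_spherical_biofilm(radius=9.0, spacing=params.spacing,
                                  jitter=params.jitter, seed=1)
    frames = run_simulation(params, geo, duration=40.0, frame_dt=0.2)
    return params, geo, frames


class TestRunSimulation:
    def test_global_trace_has_peak_trough_plateau(self, small_run):
        _, _, frames = small_run
        trace = global_tht_trace(frames)
        y = trace.intensity
        i_peak = int(np.argmax(y))
        i_trough = i_peak + int(np.argmin(y[i_peak:]))
        assert 0 < i_peak < i_trough < len(y) - 1
        assert y[i_peak] > 3 * y[i_trough]
        assert y[-1] > 2 * y[i_trough]  # habituated plateau rises again

    def test_each_cell_fires_at_most_once_in_first_peak(self, small_run):
        _, geo, frames = small_run
        trace = global_tht_trace(frames)
        # refractoriness: through the first-peak event nobody fires twice
        assert np.all(geo.fired_count <= 2)
        i_trough = int(np.argmax(trace.intensity))
        t_trough = trace.times[i_trough]
        assert np.all(geo.fired_count[geo.fire_time <= t_trough] >= 1)

    def test_bit_identical_reproducibility(self):
        params = FDFParams()
        out = []
        for _ in range(2):
            geo = build_spherical_biofilm(radius=4.0, spacing=params.spacing,
                                          jitter=params.jitter, seed=5)
            frames = run_simulation(params, geo, duration=5.0, frame_dt=0.5)
            out.append(np.concatenate([f.tht for f in frames]))
        assert np.array_equal(out[0], out[1])

    def test_empty_trigger_rejected(self):
        params = FDFParams()
        geo = build_spherical_biofilm(radius=3.0, spacing=params.spacing,
                                      jitter=0.0, seed=0)
        with pytest.raises(ValueError, match="trigger"):
            run_simulation(params, geo, duration=1.0,
                           trigger=np.zeros(geo.n_cells, dtype=bool))

    def test_mass_balance_reflective_no_losses(self):
        """With no clearance, no uptake, and a reflective test boundary,
        the dissolved mass equals the cumulative released mass."""
        params = replace(FDFParams(), k_decay=0.0, k_uptake=0.0,
                         interior_decay_fraction=1.0, jitter=0.0)
        geo = build_spherical_biofilm(radius=3.0, spacing=params.spacing,
                                      jitter=0.0, seed=0)
        field = PotassiumField.for_domain(half_width=9.0, dx=params.grid_dx,
                                          boundary="reflective")
        trigger = geo.radial_distance <= params.spacing
        geo.states[trigger] = CellState.FIRING
        geo.fire_time[trigger] = 0.0
        for step in range(100):
            field = diffuse_step(field, params.D, params.k_decay, params.dt)
            geo, field = fire_update(geo, field, params, t=step * params.dt)
        assert field.total_mass() == pytest.approx(geo.released_mass, rel=0.005)


class TestCriticalRadius:
    def test_small_biofilm_fails_large_succeeds(self):
        params = FDFParams()
        assert not propagation_success(params, 3.0, seed=0)
        assert propagation_success(params, 15.0, seed=0, duration=40.0)

    def test_degenerate_threshold_everything_fires(self):
        params = replace(FDFParams(), c_thresh=1e-9)
        # with a vanishing threshold even a biofilm of one spacing
        # propagates: the critical radius collapses to the cell spacing
        assert propagation_success(params, 1.5, seed=0, duration=5.0)

    def test_bracket_violation_instructs_widening(self):
        params = replace(FDFParams(), c_thresh=1e-9)
        with pytest.raises(ValueError, match="widen"):
            find_critical_radius(params, 1.5, 6.0, n_seeds=1, duration=5.0)

    def test_success_non_increasing_in_threshold(self):
        """A higher firing threshold makes propagation harder at fixed
        radius, so the critical radius grows with c_thresh."""
        outcomes = []
        for c_thresh in (0.5, 1.0, 2.0):
            params = replace(FDFParams(), c_thresh=c_thresh)
            outcomes.append(int(propagation_success(params, 9.0, seed=1)))
        assert outcomes == sorted(outcomes, reverse=True)
        assert outcomes[0] == 1 and outcomes[-1] == 0


class TestGlobalTrace:
    def test_empty_frames_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            global_tht_trace([])

    def test_mean_matches_hand_computation(self):
        frames = [
            SimFrame(t=0.0, states=np.zeros(3, dtype=np.int8),
                     tht=np.array([0.0, 1.0, 2.0]), global_tht=1.0,
                     released_mass=0.0, field_mass=0.0),
            SimFrame(t=1.0, states=np.zeros(3, dtype=np.int8),
                     tht=np.array([3.0, 3.0, 3.0]), global_tht=3.0,
                     released_mass=0.0, field_mass=0.0),
        ]
        trace = global_tht_trace(frames)
        assert np.allclose(trace.intensity, [1.0, 3.0])

    def test_single_frame(self):
        frame = SimFrame(t=0.0, states=np.zeros(2, dtype=np.int8),
                         tht=np.zeros(2), global_tht=0.0,
                         released_mass=0.0, field_mass=0.0)
        trace = global_tht_trace([frame])
        assert len(trace) == 1
        assert trace.intensity[0] == 0.0
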