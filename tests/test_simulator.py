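import warnings

import numpy as np
import pytest

from suturesim import (
    FieldState,
    SimulationParams,
    Trajectory,
    extract_interface,
    grow_domain,
    initial_condition,
    make_disc_field,
    make_step_field,
    mean_suture_width,
    run_simulation,
    step_u,
    step_v,
)
from suturesim.simulator import (
    _smoothed_row_noise,
    detect_steady_state,
    front_positions,
    growth_balance_ratio,
)


class TestInitialCondition:
    def test_zero_noise_straight_and_symmetric(self):
        p = SimulationParams(nx=64, ny=32, noise_amp=0.0)
        s = initial_condition(p)
        # every row identical
        assert np.allclose(s.u, s.u[0])
        # mirror symmetry about the strip centreline (domain centre)
        np.testing.assert_allclose(s.u, s.u[:, ::-1], atol=1e-12)
        np.testing.assert_allclose(s.v, s.v[:, ::-1], atol=1e-9)

    def test_seed_determinism(self):
        p = SimulationParams(nx=64, ny=32, seed=7)
        a = initial_condition(p)
        b = initial_condition(p)
        assert np.array_equal(a.u, b.u) and np.array_equal(a.v, b.v)

    def test_different_seeds_differ(self):
        p = SimulationParams(nx=64, ny=32)
        a = initial_condition(p.replace(seed=0))
        b = initial_condition(p.replace(seed=1))
        assert not np.array_equal(a.u, b.u)

    def test_noise_statistics(self):
        # 10^4 rows aggregated over seeds: mean ~ 0, sd ~ noise_amp (= dx)
        amp = 50.0
        rng = np.random.default_rng(0)
        draws = np.concatenate(
            [_smoothed_row_noise(np.random.default_rng(s), 1000, amp) for s in range(10)]
        )
        assert abs(draws.mean()) < 3 * amp / np.sqrt(draws.size / 3)  # smoothed corr
        assert draws.std() == pytest.approx(amp, rel=0.05)
        del rng

    def test_strip_too_wide_rejected(self):
        p = SimulationParams(nx=16, ny=8, noise_amp=0.0)
        with pytest.raises(ValueError, match="no bone remains"):
            initial_condition(p, w0=16 * p.dx)

    def test_state_satisfies_invariants(self):
        s = initial_condition(SimulationParams(nx=64, ny=32))
        s.validate()


class TestStepV:
    def test_uniform_mesenchyme_fixed_point(self):
        p = SimulationParams(nx=24, ny=16, noise_amp=0.0)
        s = FieldState(u=np.zeros((16, 24)), v=np.zeros((16, 24)))
        for _ in range(200):
            s.v = step_v(s, p)
        np.testing.assert_allclose(s.v, p.k_p / p.k_d, rtol=1e-3)

    def test_pure_decay_geometric(self):
        p = SimulationParams(nx=24, ny=16)
        v0 = np.full((16, 24), 0.8)
        s = FieldState(u=np.ones((16, 24)), v=v0)
        v1 = step_v(s, p)
        np.testing.assert_allclose(v1, v0 / (1.0 + p.dt * p.k_d), rtol=1e-12)

    def test_screened_diffusion_cosh_profile(self):
        # sharp 1-D strip source: steady profile matches the matched
        # closed form v_in = vmax (1 - exp(-w/2l) cosh(x/l))
        p = SimulationParams(nx=128, ny=8, noise_amp=0.0)
        x = np.arange(p.nx) * p.dx
        center = 0.5 * (p.nx - 1) * p.dx
        w = 16 * p.dx
        inside = np.abs(x - center) <= w / 2
        u = np.tile(np.where(inside, 0.0, 1.0), (p.ny, 1))
        s = FieldState(u=u, v=np.zeros_like(u))
        for _ in range(600):
            s.v = step_v(s, p)
        ell = np.sqrt(p.D_v / p.k_d)
        vmax = p.k_p / p.k_d
        xi = x - center
        analytic = np.where(
            inside,
            vmax * (1 - np.exp(-w / (2 * ell)) * np.cosh(xi / ell)),
            vmax * np.sinh(w / (2 * ell)) * np.exp(-np.abs(xi) / ell),
        )
        mid = np.argmin(np.abs(xi))
        assert s.v[4, mid] == pytest.approx(analytic[mid], rel=0.02)

    def test_convergence_to_steady_state(self):
        p = SimulationParams(nx=32, ny=16, noise_amp=0.0)
        s = initial_condition(p)
        for _ in range(300):
            s.v = step_v(s, p)
        v_inf = s.v.copy()
        s.v = step_v(s, p)
        assert np.abs(s.v - v_inf).max() < 1e-8

    def test_nonnegative(self):
        p = SimulationParams(nx=24, ny=16)
        s = FieldState(u=np.ones((16, 24)), v=np.zeros((16, 24)))
        assert step_v(s, p).min() >= 0.0


class TestStepU:
    def test_stationary_at_threshold(self):
        p = SimulationParams(nx=96, ny=8, c=0.0, noise_amp=0.0)
        u = make_step_field(p.nx, p.ny, 2400.0, 2 * p.eps, p.dx)
        s = FieldState(u=u, v=np.full_like(u, p.v_c))
        x0 = extract_interface(s.u, p.dx).left.mean()
        for _ in range(500):
            s.u = step_u(s, p)
        x1 = extract_interface(s.u, p.dx).left.mean()
        assert abs(x1 - x0) < p.dx / 10

    @pytest.mark.parametrize("delta", [0.05, 0.5])
    def test_planar_front_speed(self, delta):
        # measured speed = alpha*(v - v_c) within 5% at both decade ends
        p = SimulationParams(alpha=1.0, sigma=150.0, nx=128, ny=8, c=0.0, noise_amp=0.0)
        u = make_step_field(p.nx, p.ny, 4800.0, 2 * p.eps, p.dx)
        s = FieldState(u=u, v=np.full_like(u, p.v_c + delta))
        n = int((3000 if delta < 0.3 else 1500) / p.dt)
        ts, xs = [], []
        for i in range(n):
            s.u = step_u(s, p)
            t = (i + 1) * p.dt
            if i % 50 == 0 and t > 400:
                ts.append(t)
                xs.append(extract_interface(s.u, p.dx).left.mean())
        speed = -np.polyfit(ts, xs, 1)[0]
        assert speed == pytest.approx(p.alpha * delta, rel=0.05)

    def test_shrinking_hole_curvature_flow(self):
        # R^2(t) decreases with slope -2 sigma while R > 5 eps
        sigma = 200.0
        p = SimulationParams(sigma=sigma, nx=64, ny=64, c=0.0, noise_amp=0.0)
        u = make_disc_field(
            p.nx, p.ny, (1575.0, 1575.0), 800.0, p.eps, "hole", p.dx
        )
        s = FieldState(u=u, v=np.full_like(u, p.v_c))
        ts, r2 = [], []
        for i in range(600):
            s.u = step_u(s, p)
            if i % 20 == 0:
                R = np.sqrt((s.u < 0.5).sum() * p.dx**2 / np.pi)
                if R > 5 * p.eps:
                    ts.append((i + 1) * p.dt)
                    r2.append(R * R)
        slope = np.polyfit(ts, r2, 1)[0]
        assert slope == pytest.approx(-2 * sigma, rel=0.05)

    def test_clipped_to_unit_interval(self):
        p = SimulationParams(nx=24, ny=16)
        s = initial_condition(p.replace(nx=24, ny=16, noise_amp=0.0))
        u1 = step_u(s, p.replace(nx=24, ny=16))
        assert u1.min() >= 0.0 and u1.max() <= 1.0


class TestGrowDomain:
    def _state(self, nx=24, ny=8):
        u = np.ones((ny, nx))
        u[:, 10:14] = 0.0
        v = np.linspace(1.0, 0.0, nx)[None, :].repeat(ny, axis=0)
        return FieldState(u=u, v=v)

    def test_zero_growth_identity(self):
        p = SimulationParams(nx=24, ny=8, c=0.0)
        s = self._state()
        assert grow_domain(s, p) is s

    def test_accumulator_bookkeeping(self):
        # c*t_end/dx = 12 exactly -> 12 insertions over the run
        p = SimulationParams(nx=48, ny=16, c=0.1, t_end=6000.0)
        s = initial_condition(p.replace(noise_amp=0.0))
        for _ in range(p.n_steps):
            s = grow_domain(s, p)
        assert s.inserted_columns == 12

    def test_shapes_preserved(self):
        p = SimulationParams(nx=24, ny=8, c=30.0)  # inserts every step
        s = grow_domain(self._state(), p)
        assert s.u.shape == (8, 24) and s.v.shape == (8, 24)
        assert s.inserted_columns == 1

    def test_inserts_at_min_v_mesenchyme_column(self):
        p = SimulationParams(nx=24, ny=8, c=30.0)
        s = self._state()
        # mesenchyme columns are 10..13; v decreases with x so min is col 13
        out = grow_domain(s, p)
        # column 13 duplicated, one column deleted from the left edge
        np.testing.assert_array_equal(out.v[:, 12], s.v[:, 13])
        np.testing.assert_array_equal(out.v[:, 13], s.v[:, 13])

    def test_tie_break_lowest_index(self):
        p = SimulationParams(nx=24, ny=8, c=30.0)
        s = self._state()
        s.v[:] = 0.5  # all columns tie
        out = grow_domain(s, p)
        # lowest-index mesenchyme column (10) duplicated; left edge deleted
        np.testing.assert_array_equal(out.u[:, 9], s.u[:, 10])

    def test_fused_suture_skips_with_warning(self):
        p = SimulationParams(nx=24, ny=8, c=30.0)
        s = FieldState(u=np.ones((8, 24)), v=np.zeros((8, 24)))
        with pytest.warns(RuntimeWarning, match="fused"):
            out = grow_domain(s, p)
        assert out.inserted_columns == 0

    def test_alternating_edge_deletion_keeps_centre(self):
        p = SimulationParams(nx=48, ny=8, c=0.0)
        s = initial_condition(p.replace(noise_amp=0.0))
        pgrow = p.replace(c=50.0)  # two insertions per step
        out = grow_domain(grow_domain(s, pgrow), pgrow)
        assert out.inserted_columns == 4
        # suture stays centred: mesenchyme centroid within 2 dx of centre
        cols = np.flatnonzero((out.u < 0.5).any(axis=0))
        centre = cols.mean() * p.dx
        assert abs(centre - 0.5 * p.nx * p.dx) < 2 * p.dx


class TestRunSimulation:
    def test_zero_length_returns_initial_condition_only(self):
        p = SimulationParams(nx=32, ny=16, t_end=0.0)
        traj = run_simulation(p)
        assert len(traj.snapshots) == 1
        assert traj.snapshots[0].t == 0.0

    def test_determinism(self, tiny_params):
        a = run_simulation(tiny_params)
        b = run_simulation(tiny_params)
        assert np.array_equal(a.final.u, b.final.u)
        assert np.array_equal(a.final.v, b.final.v)

    def test_snapshot_times(self, tiny_params):
        times = [0.0, 100.0, 200.0]
        traj = run_simulation(tiny_params, snapshot_times=times)
        np.testing.assert_allclose(traj.times, times)

    def test_snapshot_outside_range_rejected(self, tiny_params):
        with pytest.raises(ValueError):
            run_simulation(tiny_params, snapshot_times=[0.0, 999.0])

    def test_invariants_along_run(self, tiny_params):
        traj = run_simulation(
            tiny_params, snapshot_times=np.linspace(0, tiny_params.t_end, 5)
        )
        for s in traj.snapshots:
            s.validate()

    def test_fuzzed_parameter_sets_keep_invariants(self):
        # random valid parameter sets on small lattices never break the
        # field invariants
        rng = np.random.default_rng(99)
        for _ in range(50):
            p = SimulationParams(
                alpha=10 ** rng.uniform(-1, 1),
                sigma=10 ** rng.uniform(1, 2.7),
                v_c=rng.uniform(0.0, 0.6),
                D_v=10 ** rng.uniform(3.5, 5.0),
                c=rng.uniform(0.0, 0.5) * rng.integers(0, 2),
                nx=24,
                ny=12,
                t_end=40.0,
                noise_amp=rng.uniform(0.0, 50.0),
                seed=int(rng.integers(0, 2**31)),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                traj = run_simulation(p)
            traj.final.validate()


class TestSteadyStateDetector:
    def _traj(self, widths, dt=100.0):
        # synthetic trajectory with prescribed mask widths
        p = SimulationParams(nx=32, ny=4, t_end=dt * (len(widths) - 1), c=0.0)
        snaps = []
        for i, w in enumerate(widths):
            u = np.ones((4, 32))
            ncols = int(round(w / p.dx))
            u[:, 8 : 8 + ncols] = 0.0
            snaps.append(FieldState(u=u, v=np.zeros_like(u), t=i * dt))
        return Trajectory(params=p, seed=0, snapshots=snaps)

    def test_constant_width_fires_at_first_snapshot(self):
        traj = self._traj([500.0] * 6)
        assert detect_steady_state(traj, window=200.0, tol=1e-3) == 0.0

    def test_linear_growth_never_fires(self):
        widths = [500.0 + 50.0 * i for i in range(6)]
        traj = self._traj(widths)
        assert detect_steady_state(traj, window=200.0, tol=1e-3) is None

    def test_settling_trajectory(self):
        widths = [500.0, 700.0, 800.0, 800.0, 800.0, 800.0]
        traj = self._traj(widths)
        assert detect_steady_state(traj, window=200.0, tol=0.01) == 200.0

    def test_needs_three_snapshots(self):
        traj = self._traj([500.0, 500.0])
        with pytest.raises(ValueError):
            detect_steady_state(traj, window=100.0)

    def test_simulated_run_equilibrates_without_growth(self):
        # width equilibration at c = 0 on a reduced lattice
        p = SimulationParams(nx=96, ny=64, t_end=3000.0, c=0.0)
        traj = run_simulation(p, snapshot_times=np.linspace(0, 3000, 13))
        assert detect_steady_state(traj, window=750.0, tol=0.05) is not None


class TestGrowthBalance:
    def test_front_positions_monotone_under_growth(self):
        p = SimulationParams(nx=96, ny=64, t_end=3000.0, c=0.2)
        traj = run_simulation(p, snapshot_times=np.linspace(0, 3000, 13))
        pos = front_positions(traj)
        assert pos[-1] > pos[0]

    def test_requires_growth(self, tiny_params):
        traj = run_simulation(
            tiny_params, snapshot_times=np.linspace(0, tiny_params.t_end, 5)
        )
        with pytest.raises(ValueError):
            growth_balance_ratio(traj)


def test_mean_suture_width_simple_band():
    p = SimulationParams(nx=32, ny=8, c=0.0)
    u = np.ones((8, 32))
    u[:, 10:20] = 0.0
    s = FieldState(u=u, v=np.zeros_like(u))
    assert mean_suture_width(s, p) == pytest.approx(10 * p.dx)
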