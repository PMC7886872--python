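import math

import numpy as np
import pytest

from hepasim.boundary import OutletBC
from hepasim.hemodynamics import SimulationConfig, WaveformParams, solve_branch_flows
from hepasim.transport import (
    MicrosphereProperties,
    ParticleState,
    TransportResult,
    bifurcation_assignment,
    flux_fraction_above,
    flux_weighted_radii,
    injection_schedule,
    partition_offset,
    run_transport,
    step_particle,
)
from hepasim.vasculature import CatheterPlacement, branch_frame

from conftest import make_single_branch_tree, small_study

NEUTRAL = MicrosphereProperties(density=1060.0)
NO_GRAVITY = SimulationConfig(gravity=(0.0, 0.0, 0.0))


def catheter(offset=0.0, azimuth=0.0, radius=2.5e-4, velocity=0.5):
    return CatheterPlacement("v", 0.5, offset, azimuth, velocity, 0.5, radius)


class TestInjectionSchedule:
    def test_release_times_within_first_cycle(self):
        sched = injection_schedule(1000, catheter(), 1.0, seed=0,
                                   vessel_radius=2e-3, vessel_length=0.02)
        assert len(sched) == 1000
        assert all(0.0 <= t < 1.0 for t, _ in sched)

    def test_centered_release_mean_near_axis(self):
        sched = injection_schedule(20_000, catheter(), 1.0, seed=1,
                                   vessel_radius=2e-3)
        cross = np.stack([s.cross_position for _, s in sched])
        # SE of the mean of a uniform disc coordinate: r/2/sqrt(n)
        assert np.all(np.abs(cross.mean(axis=0)) < 4 * 2.5e-4 / 2 / math.sqrt(20_000))

    def test_deterministic(self):
        a = injection_schedule(50, catheter(), 1.0, seed=9, vessel_radius=2e-3)
        b = injection_schedule(50, catheter(), 1.0, seed=9, vessel_radius=2e-3)
        for (ta, sa), (tb, sb) in zip(a, b):
            assert ta == tb
            assert np.array_equal(sa.cross_position, sb.cross_position)

    def test_lumen_outside_vessel_rejected(self):
        with pytest.raises(ValueError):
            injection_schedule(10, catheter(offset=0.95), 1.0, seed=0,
                               vessel_radius=2e-3)

    def test_initial_velocity_along_axis(self):
        frame = branch_frame(np.array([0.0, 1.0, 0.0]))
        sched = injection_schedule(5, catheter(velocity=1.2), 1.0, seed=0,
                                   vessel_radius=2e-3, frame=frame)
        for _, s in sched:
            assert np.allclose(s.velocity, 1.2 * frame[0])


class TestStepParticle:
    def test_neutral_buoyancy_equilibrium(self):
        cfg = SimulationConfig()
        u = np.array([0.1, 0.0, 0.0])
        state = ParticleState(0, "v", 0.0, np.zeros(2), u.copy())
        out = step_particle(state, 1e-3, u, cfg, NEUTRAL, viscosity=0.0035)
        assert np.allclose(out.velocity, u, rtol=1e-12)

    def test_stokes_terminal_velocity(self):
        cfg = SimulationConfig()
        props = MicrosphereProperties()
        mu = 0.0035
        state = ParticleState(0, "v", 0.0, np.zeros(2), np.zeros(3))
        for _ in range(300):
            state = step_particle(state, 1e-5, np.zeros(3), cfg, props,
                                  viscosity=mu)
        v_t = (props.density - cfg.blood_density) * 9.8 * props.diameter**2 / (
            18 * mu)
        assert -state.velocity[2] == pytest.approx(v_t, rel=1e-3)

    def test_streamline_following(self):
        """Relaxed neutrally-buoyant particle keeps its radius, advances u(r) dt."""
        cfg = NO_GRAVITY
        frame = branch_frame(np.array([1.0, 0.0, 0.0]))
        u_local = 0.08
        u = u_local * frame[0]
        state = ParticleState(0, "v", 0.0, np.array([3e-4, -2e-4]), u.copy())
        dt = 2e-3
        out = step_particle(state, dt, u, cfg, NEUTRAL, viscosity=0.0035,
                            frame=frame, radius=2e-3)
        assert np.allclose(out.cross_position, state.cross_position, atol=1e-15)
        assert out.axial_position == pytest.approx(u_local * dt, rel=1e-12)

    def test_non_finite_raises(self):
        state = ParticleState(7, "v", 0.0, np.zeros(2),
                              np.array([np.nan, 0.0, 0.0]))
        with pytest.raises(RuntimeError, match="7"):
            step_particle(state, 1e-3, np.zeros(3), SimulationConfig(), NEUTRAL,
                          viscosity=0.0035)

    def test_not_in_transit_rejected(self):
        state = ParticleState(0, "v", 0.0, np.zeros(2), np.zeros(3),
                              status="exited")
        with pytest.raises(ValueError):
            step_particle(state, 1e-3, np.zeros(3), SimulationConfig(), NEUTRAL)


class TestBifurcationPartition:
    DIRS = (np.array([math.cos(0.5), 0.0, math.sin(0.5)]),
            np.array([math.cos(0.5), 0.0, -math.sin(0.5)]))
    FRAME = branch_frame(np.array([1.0, 0.0, 0.0]))

    def test_all_to_daughter_one(self):
        for z in (-0.9e-3, 0.0, 0.9e-3):
            assert bifurcation_assignment(
                np.array([z, 0.0]), 1e-3, self.DIRS, (1.0, 0.0),
                parent_frame=self.FRAME) == 0

    def test_symmetric_split_by_sign(self):
        # frame e1 = +z; daughter 0 separates along +z
        assert bifurcation_assignment(np.array([1e-4, 0.0]), 1e-3, self.DIRS,
                                      (0.5, 0.5), parent_frame=self.FRAME) == 0
        assert bifurcation_assignment(np.array([-1e-4, 0.0]), 1e-3, self.DIRS,
                                      (0.5, 0.5), parent_frame=self.FRAME) == 1

    def test_flux_fraction_closed_form_against_quadrature(self):
        from scipy import integrate
        for u in (-0.8, -0.3, 0.0, 0.4, 0.9):
            num, _ = integrate.dblquad(
                lambda y, x: (1 - x**2 - y**2),
                u, 1.0,
                lambda x: -math.sqrt(1 - x**2), lambda x: math.sqrt(1 - x**2))
            total = math.pi / 2.0
            assert flux_fraction_above(u) == pytest.approx(num / total, abs=1e-9)

    def test_monte_carlo_split_matches_fraction(self):
        rng = np.random.default_rng(0)
        n = 100_000
        r = flux_weighted_radii(1e-3, n, rng)
        th = rng.uniform(0, 2 * math.pi, n)
        pts = np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
        for f1 in (0.2, 0.5, 0.7):
            d_star = partition_offset(f1) * 1e-3
            frac = float(np.mean(pts[:, 0] > d_star))
            assert frac == pytest.approx(f1, abs=3 * math.sqrt(f1 * (1 - f1) / n))

    def test_degenerate_directions_warn(self):
        d = np.array([1.0, 0.0, 0.0])
        with pytest.warns(UserWarning):
            bifurcation_assignment(np.array([1e-4, 0.0]), 1e-3, (d, d),
                                   (0.5, 0.5), parent_frame=self.FRAME)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            bifurcation_assignment(np.zeros(2), 1e-3, self.DIRS, (0.7, 0.7),
                                   parent_frame=self.FRAME)


class TestRunTransport:
    def test_single_branch_everything_exits(self):
        tree = make_single_branch_tree()
        bcs = [OutletBC("v", 60.0, 1.0)]
        flow = solve_branch_flows(tree, bcs, waveform=WaveformParams.constant())
        res = run_transport(tree, flow, catheter(), NO_GRAVITY, NEUTRAL,
                            n_particles=500, seed=0)
        assert res.exit_fraction == 1.0
        assert res.exit_counts == {"v": 500}

    def test_symmetric_tree_even_split(self, y_tree):
        bcs = [OutletBC("v0", 30.0, 0.5), OutletBC("v1", 30.0, 0.5)]
        flow = solve_branch_flows(y_tree, bcs, waveform=WaveformParams.constant())
        res = run_transport(y_tree, flow, catheter(), NO_GRAVITY, NEUTRAL,
                            n_particles=10_000, seed=3, release="flux_weighted")
        n = res.exited_count
        se = math.sqrt(0.25 / n)
        assert res.exit_counts["v0"] / n == pytest.approx(0.5, abs=3 * se)

    def test_conservation_and_determinism(self, y_tree, y_flow):
        bcs, flow = y_flow
        a = run_transport(y_tree, flow, catheter(), SimulationConfig(),
                          MicrosphereProperties(), n_particles=2000, seed=11)
        b = run_transport(y_tree, flow, catheter(), SimulationConfig(),
                          MicrosphereProperties(), n_particles=2000, seed=11)
        assert sum(a.exit_counts.values()) + a.resident_count == 2000
        assert a.exit_counts == b.exit_counts
        assert a.resident_count == b.resident_count

    def test_dt_halving_within_binomial_error(self, y_tree, y_flow):
        bcs, flow = y_flow
        n = 10_000
        res = {}
        for dt in (2e-3, 1e-3):
            cfg = SimulationConfig(dt=dt, gravity=(0, 0, 0))
            r = run_transport(y_tree, flow, catheter(), cfg, NEUTRAL,
                              n_particles=n, seed=5, release="flux_weighted")
            res[dt] = r.exit_counts["v0"] / r.exited_count
        f = res[2e-3]
        tol = 3 * math.sqrt(2 * f * (1 - f) / n)
        assert abs(res[2e-3] - res[1e-3]) < tol

    def test_eccentric_release_shifts_split_monotonically(self, y_tree, y_flow):
        bcs, flow = y_flow
        shares = []
        for off in (0.0, 0.4, 0.8):
            res = run_transport(y_tree, flow, catheter(offset=off),
                                NO_GRAVITY, NEUTRAL, n_particles=4000, seed=2)
            shares.append(res.exit_counts["v0"] / res.exited_count)
        assert shares[0] <= shares[1] <= shares[2]
        assert shares[2] > shares[0]

    def test_result_invariant_enforced(self):
        with pytest.raises(ValueError):
            TransportResult(injected_count=10, exit_counts={"a": 4},
                            resident_count=3)

    def test_low_exit_fraction_warns(self, y_tree, y_flow):
        bcs, flow = y_flow
        cfg = SimulationConfig(n_cycles=1, dt=2e-3, gravity=(0, 0, 0))
        # give the flow field a near-zero mean so particles barely move
        slow = solve_branch_flows(y_tree, bcs, mean_inlet_flow=0.01,
                                  waveform=WaveformParams.constant())
        with pytest.warns(UserWarning, match="exited"):
            run_transport(y_tree, slow, catheter(velocity=1e-4), cfg, NEUTRAL,
                          n_particles=100, seed=0)
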