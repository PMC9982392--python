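"""Discrete-phase model: drag law, integrator, wall collisions, cohorts."""

import numpy as np
import pytest

from gastroflow.fixtures import straight_tube
from gastroflow.mesh import discretize
from gastroflow.solver import FlowField, FluidProperties
from gastroflow.tracking import (
    ParticleSpec,
    TrackingConfig,
    acceleration,
    drag_coefficient,
    drag_response_rate,
    gravity_body_force,
    inject_positions,
    particle_reynolds,
    reflect,
    step_trapezoidal,
    track_cohort,
)

FLUID = FluidProperties()
SPEC = ParticleSpec()
CFG = TrackingConfig()


def _plug_field(mesh, speed=0.02):
    """Synthetic uniform axial flow (no solve needed)."""
    u = np.zeros((mesh.n_cells, 3))
    u[:, 0] = speed
    return FlowField(
        u=u,
        p=np.zeros(mesh.n_cells),
        flux_int=np.zeros(mesh.n_faces),
        flux_bnd=np.zeros(len(mesh.bnd_cell)),
        rho=FLUID.density,
        residuals={},
        converged=True,
        n_iter=0,
    )


class TestDragModel:
    def test_zero_slip_gives_zero_reynolds(self):
        u = np.array([0.01, 0.0, 0.0])
        assert particle_reynolds(u, u, SPEC, FLUID) == 0.0

    def test_reynolds_of_default_particle(self):
        """Re = rho d_p |slip| / mu for a 50 nm particle slipping at 1 cm/s."""
        re = particle_reynolds(np.zeros(3), np.array([0.01, 0, 0]), SPEC, FLUID)
        assert re == pytest.approx(998.2 * 50e-9 * 0.01 / 0.001003, rel=1e-12)
        assert re == pytest.approx(4.98e-4, rel=0.01)

    def test_reynolds_linear_in_diameter(self):
        big = ParticleSpec(diameter=2 * SPEC.diameter)
        slip = np.array([0.01, 0, 0])
        assert particle_reynolds(np.zeros(3), slip, big, FLUID) == pytest.approx(
            2 * particle_reynolds(np.zeros(3), slip, SPEC, FLUID)
        )

    def test_stokes_limit_of_drag_coefficient(self):
        for re in (1e-6, 1e-4, 1e-2):
            assert drag_coefficient(re) * re / 24.0 == pytest.approx(1.0, rel=2e-2)

    @pytest.mark.parametrize("re,cd", [(1.0, 27.6), (10.0, 4.1513)])
    def test_schiller_naumann_values(self, re, cd):
        assert drag_coefficient(re, "schiller_naumann") == pytest.approx(cd, rel=1e-3)

    def test_out_of_range_reynolds_warns_and_clamps(self):
        with pytest.warns(UserWarning, match="Schiller-Naumann"):
            cd = drag_coefficient(2000.0)
        assert cd == pytest.approx(24.0 / 2000.0 * (1 + 0.15 * 1000**0.687), rel=1e-6)


class TestAcceleration:
    def test_equilibrium_is_zero(self):
        u = np.array([0.01, 0.002, 0.0])
        assert np.allclose(acceleration(u, u, SPEC, FLUID, CFG), 0.0)

    def test_stokes_response_rate_of_default_particle(self):
        """F_D = 18 mu / (rho_p d_p^2) ~ 5.55e9 1/s for the 50 nm food particle."""
        fd = drag_response_rate(np.zeros(3), np.array([1e-4, 0, 0]), SPEC, FLUID)
        assert fd == pytest.approx(18 * 0.001003 / (1300 * (50e-9) ** 2), rel=1e-3)
        assert fd == pytest.approx(5.55e9, rel=0.01)

    def test_stokes_settling_terminal_velocity(self):
        """Heavy sphere in still fluid settles at (rho_p - rho) g d^2 / (18 mu)."""
        spec = ParticleSpec(diameter=50e-6)  # the micron-scale preset
        cfg = TrackingConfig(body_force=gravity_body_force(spec, FLUID), drag_law="stokes")
        v_ref = (spec.density - FLUID.density) * 9.81 * spec.diameter**2 / (18 * FLUID.viscosity)
        pos = np.zeros((1, 3))
        vel = np.zeros((1, 3))
        fd = drag_response_rate(np.zeros((1, 3)), vel, spec, FLUID, "stokes")
        dt = np.full(1, 0.05 / fd)
        for _ in range(400):
            pos, vel = step_trapezoidal(pos, vel, np.zeros((1, 3)), dt, spec, FLUID, cfg)
        assert -vel[0, 1] == pytest.approx(v_ref, rel=0.01)


class TestTrapezoidalStep:
    def test_velocity_decay_matches_exponential(self):
        """Still fluid: |u_p| decays as exp(-F_D t) for resolved steps."""
        spec = ParticleSpec(diameter=100e-6)
        fd = drag_response_rate(np.zeros((1, 3)), np.array([[0.01, 0, 0]]), spec, FLUID, "stokes")
        cfg = TrackingConfig(drag_law="stokes")
        dt_step = 0.1 / fd
        pos = np.zeros((1, 3))
        vel = np.array([[0.01, 0.0, 0.0]])
        speeds = [0.01]
        for _ in range(30):
            pos, vel = step_trapezoidal(
                pos, vel, np.zeros((1, 3)), np.full(1, dt_step), spec, FLUID, cfg
            )
            speeds.append(float(np.linalg.norm(vel)))
        speeds = np.array(speeds)
        assert np.all(np.diff(speeds) < 0)  # monotone decay
        t = np.arange(31) * dt_step
        assert np.allclose(speeds, 0.01 * np.exp(-fd * t), rtol=0.01)

    def test_uniform_flow_advects_in_straight_line(self):
        u0 = np.array([[0.01, 0.005, 0.0]])
        pos = np.zeros((1, 3))
        vel = u0.copy()
        for _ in range(50):
            pos, vel = step_trapezoidal(pos, vel, u0, np.full(1, 0.1), SPEC, FLUID, CFG)
        assert np.allclose(pos, u0 * 5.0, rtol=1e-12)
        assert np.allclose(vel, u0, rtol=1e-12)

    def test_second_order_in_time(self):
        """Halving dt shrinks the end-position error ~4x (O(dt^2) accuracy)."""
        spec = ParticleSpec(diameter=200e-6)
        cfg = TrackingConfig(drag_law="stokes")
        fd = float(drag_response_rate(np.zeros((1, 3)), np.array([[1.0, 0, 0]]), spec, FLUID, "stokes"))
        v0 = 0.01
        t_end = 1.0 / fd

        def final_x(nsteps):
            pos = np.zeros((1, 3))
            vel = np.array([[v0, 0.0, 0.0]])
            dt = np.full(1, t_end / nsteps)
            for _ in range(nsteps):
                pos, vel = step_trapezoidal(pos, vel, np.zeros((1, 3)), dt, spec, FLUID, cfg)
            return pos[0, 0]

        exact = v0 / fd * (1 - np.exp(-fd * t_end))
        e1 = abs(final_x(8) - exact)
        e2 = abs(final_x(16) - exact)
        e3 = abs(final_x(32) - exact)
        assert e1 / e2 == pytest.approx(4.0, rel=0.3)
        assert e2 / e3 == pytest.approx(4.0, rel=0.3)


class TestWallReflection:
    @pytest.fixture(scope="class")
    def tube(self):
        return straight_tube(10.0, 60.0)

    def test_normal_incidence_reverses_normal_velocity(self, tube):
        pos = np.array([[0.03, 0.0101, 0.0]])  # just past the wall at y=10mm
        vel = np.array([[0.0, 0.02, 0.0]])
        new_pos, new_vel = reflect(pos, vel, tube)
        assert new_vel[0, 1] == pytest.approx(-0.02, rel=1e-9)
        assert tube.sdf(new_pos / 1e-3)[0] < 0

    def test_speed_preserved_to_machine_precision(self, tube):
        rng = np.random.default_rng(1)
        pos = np.column_stack(
            [
                rng.uniform(0.01, 0.05, 50),
                np.full(50, 0.0102),
                rng.uniform(-0.002, 0.002, 50),
            ]
        )
        vel = rng.normal(0, 0.02, (50, 3))
        _, new_vel = reflect(pos, vel, tube)
        s0 = np.linalg.norm(vel, axis=1)
        s1 = np.linalg.norm(new_vel, axis=1)
        assert np.max(np.abs(s1 - s0)) < 1e-12

    def test_grazing_incidence_preserves_tangential_component(self, tube):
        pos = np.array([[0.03, 0.0101, 0.0]])
        vel = np.array([[0.02, 0.001, 0.0]])  # mostly tangential
        _, new_vel = reflect(pos, vel, tube)
        assert new_vel[0, 0] == pytest.approx(0.02, rel=1e-6)
        assert new_vel[0, 1] == pytest.approx(-0.001, rel=1e-6)

    def test_interior_particles_untouched(self, tube):
        pos = np.array([[0.03, 0.0, 0.0]])
        vel = np.array([[0.01, 0.01, 0.0]])
        new_pos, new_vel = reflect(pos, vel, tube)
        assert np.array_equal(new_pos, pos) and np.array_equal(new_vel, vel)


class TestTrackCohort:
    @pytest.fixture(scope="class")
    def plug(self):
        geom = straight_tube(10.0, 60.0)
        mesh = discretize(geom, 2.0)
        return mesh, _plug_field(mesh, speed=0.02)

    def test_plug_flow_transit_time(self, plug):
        mesh, field = plug
        spec = ParticleSpec(count=150, seed=4)
        trajs = track_cohort(field, mesh, spec, TrackingConfig(max_time=20.0))
        assert np.all([t.status == "ESCAPED_OUTLET" for t in trajs])
        # trilinear sampling blends to zero inside the wall, so judge the plug
        # transit on particles whose path stays clear of the wall layer
        core = [
            t
            for t in trajs
            if np.linalg.norm(t.positions[0, 1:]) < 0.010 - 2.5 * mesh.h
        ]
        assert len(core) > 10
        expected = (0.060 - 1.5 * mesh.h) / 0.02  # injected 1.5 cells inside
        times = np.array([t.retention_time for t in core])
        assert times == pytest.approx(expected, rel=0.01)
        speeds = np.array([t.mean_speed for t in core])
        assert speeds == pytest.approx(0.02, rel=0.01)

    def test_same_seed_bitwise_identical(self, plug):
        mesh, field = plug
        spec = ParticleSpec(count=20, seed=9)
        cfg = TrackingConfig(max_time=20.0)
        a = track_cohort(field, mesh, spec, cfg)
        b = track_cohort(field, mesh, spec, cfg)
        for ta, tb in zip(a, b):
            assert ta.retention_time == tb.retention_time
            assert ta.mean_speed == tb.mean_speed
            assert np.array_equal(ta.positions, tb.positions)

    def test_count_conserved(self, plug):
        mesh, field = plug
        trajs = track_cohort(field, mesh, ParticleSpec(count=30, seed=2), TrackingConfig(max_time=20.0))
        statuses = {t.status for t in trajs}
        assert len(trajs) == 30
        assert statuses <= {"ESCAPED_OUTLET", "ESCAPED_INLET", "TIMED_OUT"}

    def test_poiseuille_fastest_particle_rides_the_axis(self, tube_solution):
        """Minimum transit ~ L / (2 u_mean): the centreline of the parabola."""
        _, mesh, field = tube_solution
        spec = ParticleSpec(count=200, seed=7)
        trajs = track_cohort(field, mesh, spec, TrackingConfig(max_time=60.0))
        esc = [t.retention_time for t in trajs if t.status == "ESCAPED_OUTLET"]
        assert esc
        t_min = min(esc)
        l_eff = 0.100 - 1.5 * mesh.h
        assert t_min == pytest.approx(l_eff / 0.08, rel=0.05)

    def test_timeout_warning(self, plug):
        mesh, field = plug
        with pytest.warns(UserWarning, match="max_time"):
            track_cohort(
                field, mesh, ParticleSpec(count=10, seed=1), TrackingConfig(max_time=0.5)
            )

    def test_injection_uniform_over_inlet_disc(self, plug):
        mesh, _ = plug
        pts = inject_positions(mesh, ParticleSpec(count=4000, seed=3))
        r = np.linalg.norm(pts[:, 1:], axis=1)
        assert r.max() < 0.010
        # uniform disc: mean radius = 2R/3
        assert r.mean() == pytest.approx(2 / 3 * 0.0098, rel=0.03)
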