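import numpy as np
import pytest

from panelflash.flow import turbulence_field
from panelflash.geometry import build_geometry, points_in_fluid
from panelflash.transport import (
    DiscreteRandomWalk,
    ParticleSpec,
    advance,
    inject_particles,
    reflect_boundary,
    track,
    trajectories_from_csv,
    trajectories_to_csv,
)


class _UniformField:
    def __init__(self, vx, vz):
        self._v = (vx, vz)

    def velocity(self, x, z, respect_baffles=True):
        x = np.asarray(x, dtype=float)
        return np.full_like(x, self._v[0]), np.full_like(x, self._v[1])


class _SolidRotationField:
    """v = omega x r about the origin; orbit period 2 pi / omega."""

    def __init__(self, omega):
        self.omega = omega

    def velocity(self, x, z, respect_baffles=True):
        x = np.asarray(x, dtype=float)
        z = np.asarray(z, dtype=float)
        return -self.omega * z, self.omega * x


class TestParticleSpec:
    def test_relaxation_time(self):
        spec = ParticleSpec()
        # rho d^2 / (18 mu) = 1000 * (5e-6)^2 / (18e-3)
        assert spec.relaxation_time == pytest.approx(1000 * 25e-12 / 18e-3, rel=1e-12)
        assert spec.relaxation_time < 2e-6

    def test_positive_validation(self):
        with pytest.raises(ValueError):
            ParticleSpec(diameter_um=-1.0)


class TestInjection:
    def test_even_split(self, geom, rng):
        pos = inject_particles(geom, 1000, rng)
        near_first = np.abs(pos[:, 0] - 60.0) < 3.0
        assert near_first.sum() == 500

    def test_odd_count_extra_at_first_port(self, geom, rng):
        pos = inject_particles(geom, 11, rng)
        near_first = np.abs(pos[:, 0] - 60.0) < 3.0
        assert near_first.sum() == 6

    def test_zero_jitter_exact_ports(self, geom, rng):
        pos = inject_particles(geom, 2, rng, jitter_radius=0.0)
        np.testing.assert_allclose(pos, [(60.0, 10.0), (-60.0, 700.0)])

    def test_deterministic(self, geom):
        a = inject_particles(geom, 100, np.random.default_rng(7))
        b = inject_particles(geom, 100, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_all_in_fluid(self, geom, rng):
        pos = inject_particles(geom, 500, rng)
        assert points_in_fluid(geom, pos).all()

    def test_bad_port_rejected(self, rng):
        g = build_geometry({"ports": [(0.0, 90.0), (-60.0, 700.0)]})
        with pytest.raises(ValueError, match="port"):
            inject_particles(g, 10, rng)


class TestDRW:
    def test_zero_k_zero_fluctuation(self, rng):
        drw = DiscreteRandomWalk(100, 0.5, rng)
        u = drw.sample(np.zeros(100), 0.004)
        assert np.all(u == 0.0)

    def test_moments(self, rng):
        # force a redraw every call: dt much larger than the eddy time
        k = 6.0  # sd per component = sqrt(2k/3) = 2
        drw = DiscreteRandomWalk(1000, 0.01, rng)
        draws = [drw.sample(np.full(1000, k), 1.0)[:, 0] for _ in range(100)]
        u = np.concatenate(draws)
        n = len(u)
        sd = np.sqrt(2 * k / 3)
        assert abs(u.mean()) < 3 * sd / np.sqrt(n)
        var_se = sd**2 * np.sqrt(2.0 / n)
        assert abs(u.var() - sd**2) < 3 * var_se

    def test_fluctuation_held_within_eddy(self, rng):
        drw = DiscreteRandomWalk(10, 1e9, rng)  # eddies effectively never expire
        a = drw.sample(np.full(10, 3.0), 0.004)
        b = drw.sample(np.full(10, 3.0), 0.004)
        np.testing.assert_array_equal(a, b)


class TestAdvance:
    def test_equilibrium_tracer_in_uniform_field(self):
        fld = _UniformField(10.0, -5.0)
        spec = ParticleSpec()
        pos = np.array([[0.0, 100.0]])
        vel = np.array([[10.0, -5.0]])
        new_pos, new_vel = advance(fld, spec, pos, vel, 0.004)
        np.testing.assert_allclose(new_pos, [[0.04, 99.98]], rtol=1e-12)
        np.testing.assert_allclose(new_vel, [[10.0, -5.0]], rtol=1e-12)

    def test_statics(self):
        fld = _UniformField(0.0, 0.0)
        pos = np.array([[1.0, 2.0]])
        vel = np.zeros((1, 2))
        new_pos, new_vel = advance(fld, ParticleSpec(), pos, vel, 0.004)
        np.testing.assert_array_equal(new_pos, pos)
        np.testing.assert_array_equal(new_vel, vel)

    def test_solid_rotation_orbit_period(self):
        omega = 1.0
        fld = _SolidRotationField(omega)
        spec = ParticleSpec()
        dt = 0.004
        period = 2 * np.pi / omega
        n_steps = int(round(period / dt))
        pos = np.array([[10.0, 0.0]])
        vel = np.column_stack(fld.velocity(pos[:, 0], pos[:, 1]))
        angles = [0.0]
        for _ in range(n_steps + 200):
            pos, vel = advance(fld, spec, pos, vel, dt)
            angles.append(np.arctan2(pos[0, 1], pos[0, 0]))
        unwrapped = np.unwrap(angles)
        # time to accumulate 2 pi of phase
        idx = int(np.searchsorted(unwrapped, 2 * np.pi))
        t_lo = (idx - 1) * dt + dt * (2 * np.pi - unwrapped[idx - 1]) / (
            unwrapped[idx] - unwrapped[idx - 1]
        )
        assert t_lo == pytest.approx(period, rel=1e-3)

    def test_nonfinite_field_raises(self):
        class BadField:
            def velocity(self, x, z, respect_baffles=True):
                x = np.asarray(x, dtype=float)
                return np.full_like(x, np.nan), np.full_like(x, np.nan)

        with pytest.raises(FloatingPointError, match="position"):
            advance(
                BadField(),
                ParticleSpec(),
                np.array([[0.0, 0.0]]),
                np.zeros((1, 2)),
                0.004,
                include_pressure_gradient=False,
            )


class TestReflectBoundary:
    def test_specular_wall_reflection(self, geom):
        pos, vel = reflect_boundary(
            geom,
            np.array([[-79.0, 450.0]]),
            np.array([[-81.0, 450.0]]),
            np.array([[-500.0, 0.0]]),
        )
        np.testing.assert_allclose(pos, [[-79.0, 450.0]], atol=1e-6)
        assert vel[0, 0] == 500.0

    def test_no_op_inside_fluid(self, geom):
        old = np.array([[10.0, 400.0]])
        new = np.array([[11.0, 401.0]])
        vel = np.array([[1.0, 1.0]])
        pos, v = reflect_boundary(geom, old, new, vel)
        np.testing.assert_array_equal(pos, new)
        np.testing.assert_array_equal(v, vel)

    def test_baffle_reflection_exits_on_incoming_side(self, geom):
        # step ending inside the lowest baffle (centre (0, 90), r = 35)
        old = np.array([[-40.0, 90.0]])
        new = np.array([[-30.0, 90.0]])
        vel = np.array([[2500.0, 0.0]])
        pos, v = reflect_boundary(geom, old, new, vel)
        # geometric oracle: entry at (-35, 90), reflected x = -35 - (new - (-35))
        assert pos[0, 0] == pytest.approx(-40.0, abs=1e-6)
        assert pos[0, 1] == pytest.approx(90.0, abs=1e-9)
        assert v[0, 0] == -2500.0
        assert points_in_fluid(geom, pos).all()

    def test_oblique_baffle_reflection_oracle(self, geom):
        # independent check against a hand-computed circle-segment intersection
        old = np.array([[-45.0, 80.0]])
        new = np.array([[-25.0, 80.0]])  # crosses circle x^2+(z-90)^2=35^2 at z=80
        x_entry = -np.sqrt(35.0**2 - 10.0**2)  # -33.54...
        vel = np.array([[1000.0, 0.0]])
        pos, v = reflect_boundary(geom, old, new, vel)
        n_hat = np.array([x_entry, -10.0]) / 35.0
        dp = new[0] - np.array([x_entry, 80.0])
        dp_reflected = dp - 2 * np.dot(dp, n_hat) * n_hat
        expected = np.array([x_entry, 80.0]) + dp_reflected
        np.testing.assert_allclose(pos[0], expected, atol=1e-6)
        assert points_in_fluid(geom, pos).all()

    def test_corner_double_reflection(self, geom):
        pos, _ = reflect_boundary(
            geom,
            np.array([[-79.0, 1.0]]),
            np.array([[-82.0, -2.0]]),
            np.array([[-10.0, -10.0]]),
        )
        assert points_in_fluid(geom, pos).all()


class TestTrack:
    def test_record_count(self, geom_unbaffled, field_unbaffled_002):
        traj = track(field_unbaffled_002, geom_unbaffled, n=4, t_max=60.0, seed=1)
        assert traj.positions.shape == (4, 601, 2)
        assert traj.record_times[0] == 0.0
        assert traj.record_times[-1] == pytest.approx(60.0)

    def test_determinism(self, geom, field_baffled_002):
        fld = turbulence_field(field_baffled_002, 0.2, 0.5)
        a = track(fld, geom, n=8, t_max=2.0, seed=11)
        b = track(fld, geom, n=8, t_max=2.0, seed=11)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_seed_changes_result(self, geom, field_baffled_002):
        fld = turbulence_field(field_baffled_002, 0.2, 0.5)
        a = track(fld, geom, n=8, t_max=2.0, seed=11)
        b = track(fld, geom, n=8, t_max=2.0, seed=12)
        assert not np.array_equal(a.positions, b.positions)

    def test_all_positions_in_fluid(self, geom, field_baffled_002):
        fld = turbulence_field(field_baffled_002, 0.25, 0.5)
        traj = track(fld, geom, n=20, t_max=10.0, seed=3)
        flat = traj.positions.reshape(-1, 2)
        assert points_in_fluid(geom, flat).all()

    def test_record_dt_multiple_enforced(self, geom, field_baffled_002):
        with pytest.raises(ValueError, match="multiple"):
            track(field_baffled_002, geom, n=2, dt=0.004, record_dt=0.01)

    def test_laminar_tracers_stay_on_streamlines(
        self, geom_unbaffled, field_unbaffled_002
    ):
        traj = track(field_unbaffled_002, geom_unbaffled, n=10, t_max=60.0, seed=5)
        f = field_unbaffled_002
        psi_start = f.psi(traj.positions[:, 0, 0], traj.positions[:, 0, 1])
        psi_end = f.psi(traj.positions[:, -1, 0], traj.positions[:, -1, 1])
        xs = np.linspace(-79, 79, 60)
        zs = np.linspace(1, 899, 60)
        xx, zz = np.meshgrid(xs, zs)
        psi_max = np.max(np.abs(f.psi(xx, zz)))
        assert np.max(np.abs(psi_end - psi_start)) < 1e-3 * psi_max

    def test_unbaffled_circulation_changes_x_sign(
        self, geom_unbaffled, field_unbaffled_002
    ):
        traj = track(field_unbaffled_002, geom_unbaffled, n=10, t_max=60.0, seed=5)
        x = traj.positions[:, :, 0]
        assert np.all(x.min(axis=1) < 0) and np.all(x.max(axis=1) > 0)

    def test_mean_speed_consistent_with_field(self, geom_unbaffled, field_unbaffled_002):
        traj = track(field_unbaffled_002, geom_unbaffled, n=60, t_max=30.0, seed=9)
        d = np.diff(traj.positions, axis=1)
        speeds = np.linalg.norm(d, axis=2) / traj.record_dt
        mean_traj_speed = speeds.mean()
        pos = traj.positions.reshape(-1, 2)
        field_speed = field_unbaffled_002.speed(pos[:, 0], pos[:, 1]).mean()
        assert mean_traj_speed == pytest.approx(field_speed, rel=0.10)


class TestTrajectoryIO:
    def test_roundtrip(self, tmp_path, geom, field_baffled_002):
        fld = turbulence_field(field_baffled_002, 0.2, 0.5)
        traj = track(fld, geom, n=5, t_max=1.0, seed=2)
        path = tmp_path / "traj.csv"
        trajectories_to_csv(traj, path)
        back = trajectories_from_csv(path)
        assert back.seed == 2
        np.testing.assert_allclose(back.positions, traj.positions, atol=1e-6)
        np.testing.assert_allclose(back.record_times, traj.record_times)
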