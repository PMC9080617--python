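"""Lagrangian cell tracking through a flow field.

Simulated algal cells (5 um, neutrally buoyant) are advanced with Stokes drag
toward the local fluid velocity plus a discrete-random-walk (DRW) turbulent
fluctuation, and a pressure-gradient force for the material acceleration of
the carrier fluid.  Because the particle relaxation time (~1.4 us) is vastly
smaller than the 0.004 s step, velocity relaxation is integrated exactly
(exponential integrator) and the position update uses a midpoint stage so
tracer-limit trajectories stay on streamlines over the full 60 s horizon.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np

from .geometry import ReactorGeometry, points_in_fluid

__all__ = [
    "ParticleSpec",
    "TrajectorySet",
    "DiscreteRandomWalk",
    "inject_particles",
    "advance",
    "reflect_boundary",
    "track",
    "trajectories_to_csv",
    "trajectories_from_csv",
]

_MM_PER_M = 1000.0


@dataclass(frozen=True)
class ParticleSpec:
    """Physical particle / fluid parameters (SI units except diameter)."""

    diameter_um: float = 5.0
    density: float = 1000.0  # kg/m^3
    fluid_viscosity: float = 1.0e-3  # Pa s
    fluid_density: float = 1000.0  # kg/m^3

    def __post_init__(self) -> None:
        for name in ("diameter_um", "density", "fluid_viscosity", "fluid_density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def relaxation_time(self) -> float:
        """Stokes relaxation time tau_p = rho_p d^2 / (18 mu), seconds."""
        d = self.diameter_um * 1e-6
        return self.density * d * d / (18.0 * self.fluid_viscosity)


@dataclass(frozen=True)
class TrajectorySet:
    """Recorded particle positions on a uniform grid of record times."""

    record_times: np.ndarray  # (n_times,) s
    positions: np.ndarray  # (n_particles, n_times, 2) mm
    particle_ids: np.ndarray  # (n_particles,)
    seed: int
    provenance: dict = field(default_factory=dict)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def record_dt(self) -> float:
        return float(self.record_times[1] - self.record_times[0])


class DiscreteRandomWalk:
    """Per-particle eddy velocity fluctuations.

    Each particle holds a Gaussian fluctuation (sd = sqrt(2k/3) per component)
    for an exponentially distributed eddy lifetime with mean ``eddy_time``,
    then redraws from the local turbulence level.
    """

    def __init__(self, n: int, eddy_time: float, rng: np.random.Generator):
        if eddy_time <= 0:
            raise ValueError("eddy_time must be positive")
        self.eddy_time = eddy_time
        self.rng = rng
        self.uprime = np.zeros((n, 2))
        self.remaining = np.zeros(n)  # force a draw on first sample

    def sample(self, k: np.ndarray, dt: float) -> np.ndarray:
        """Advance eddy clocks by ``dt`` and return fluctuations, mm/s."""
        k = np.broadcast_to(np.asarray(k, dtype=float), self.remaining.shape)
        expired = self.remaining <= 0.0
        n_new = int(expired.sum())
        if n_new:
            sd = np.sqrt(2.0 * k[expired] / 3.0)
            self.uprime[expired] = self.rng.standard_normal((n_new, 2)) * sd[:, None]
            self.remaining[expired] = self.rng.exponential(self.eddy_time, n_new)
        self.remaining -= dt
        out = self.uprime.copy()
        out[k == 0.0] = 0.0
        return out


def inject_particles(
    geom: ReactorGeometry,
    n: int,
    rng: np.random.Generator,
    jitter_radius: float = 2.0,
) -> np.ndarray:
    """Initial positions: even split across the two ports, uniform jitter.

    Odd ``n`` places the extra particle at the first port.  Jittered points
    falling outside the fluid are redrawn.
    """
    if n < 2:
        raise ValueError("need at least 2 particles")
    ports = geom.port_positions
    if len(ports) != 2:
        raise ValueError("expected exactly 2 injection ports")
    for p in ports:
        if not points_in_fluid(geom, np.asarray(p))[0]:
            raise ValueError(f"injection port {p} is not in the fluid domain")
    counts = (n - n // 2, n // 2)
    chunks = []
    for (px, pz), m in zip(ports, counts):
        pos = np.empty((m, 2))
        filled = 0
        while filled < m:
            need = m - filled
            r = jitter_radius * np.sqrt(rng.random(need))
            th = rng.random(need) * 2.0 * np.pi
            cand = np.column_stack([px + r * np.cos(th), pz + r * np.sin(th)])
            ok = points_in_fluid(geom, cand)
            good = cand[ok]
            pos[filled : filled + len(good)] = good
            filled += len(good)
            if jitter_radius == 0.0:
                pos[:] = (px, pz)
                break
        chunks.append(pos)
    return np.vstack(chunks)


def _material_acceleration(fld, pos: np.ndarray, h: float = 0.5) -> np.ndarray:
    """(u . grad) u by central differences, mm/s^2 (steady carrier field)."""
    x, z = pos[:, 0], pos[:, 1]
    ux, uz = fld.velocity(x, z)
    uxp, uzp = fld.velocity(x + h, z)
    uxm, uzm = fld.velocity(x - h, z)
    dux_dx = (uxp - uxm) / (2 * h)
    duz_dx = (uzp - uzm) / (2 * h)
    uxp, uzp = fld.velocity(x, z + h)
    uxm, uzm = fld.velocity(x, z - h)
    dux_dz = (uxp - uxm) / (2 * h)
    duz_dz = (uzp - uzm) / (2 * h)
    ax = ux * dux_dx + uz * dux_dz
    az = ux * duz_dx + uz * duz_dz
    return np.column_stack([ax, az])


def advance(
    fld,
    spec: ParticleSpec,
    pos: np.ndarray,
    vel: np.ndarray,
    dt: float,
    uprime: np.ndarray | None = None,
    include_pressure_gradient: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """One integration step; returns (new_position, new_velocity).

    Velocity relaxes exactly toward the seen fluid velocity (mean + DRW
    fluctuation) with the Stokes time constant; the position update is a
    midpoint (RK2) step, which in the tracer limit keeps particles on
    streamlines.  The pressure-gradient force enters as the steady material
    acceleration of the carrier scaled by the density ratio.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    vel = np.atleast_2d(np.asarray(vel, dtype=float))
    if uprime is None:
        uprime = np.zeros_like(pos)
    tau = spec.relaxation_time
    beta = spec.fluid_density / spec.density

    def seen(p: np.ndarray) -> np.ndarray:
        ux, uz = fld.velocity(p[:, 0], p[:, 1])
        u = np.column_stack([ux, uz]) + uprime
        if not np.all(np.isfinite(u)):
            bad = np.argwhere(~np.isfinite(u))[0, 0]
            raise FloatingPointError(
                f"non-finite fluid velocity at position {p[bad]} mm"
            )
        return u

    accel = (
        beta * _material_acceleration(fld, pos)
        if include_pressure_gradient
        else np.zeros_like(pos)
    )
    drift = accel * tau

    u1 = seen(pos)
    v_half = u1 + drift + (vel - u1 - drift) * np.exp(-0.5 * dt / tau)
    pos_mid = pos + 0.5 * dt * v_half
    u2 = seen(pos_mid)
    v_new = u2 + drift + (vel - u2 - drift) * np.exp(-dt / tau)
    return pos + dt * v_new, v_new


_WALL_EPS = 1e-9


def reflect_boundary(
    geom: ReactorGeometry,
    old_pos: np.ndarray,
    new_pos: np.ndarray,
    velocity: np.ndarray,
    max_reflections: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Specularly reflect steps that cross a wall or baffle surface.

    Applied repeatedly (up to ``max_reflections``); any particle still outside
    the fluid afterwards is returned to its previous position.
    """
    old_pos = np.atleast_2d(np.asarray(old_pos, dtype=float))
    pos = np.atleast_2d(np.asarray(new_pos, dtype=float)).copy()
    vel = np.atleast_2d(np.asarray(velocity, dtype=float)).copy()
    x0, x1 = geom.x_extent
    z0, z1 = geom.z_extent
    r = geom.baffle_radius

    for _ in range(max_reflections):
        done = points_in_fluid(geom, pos)
        if done.all():
            break
        # rectangle walls: mirror coordinate, flip normal velocity
        for axis, lo, hi in ((0, x0, x1), (1, z0, z1)):
            low = ~done & (pos[:, axis] <= lo)
            pos[low, axis] = 2.0 * lo - pos[low, axis] + _WALL_EPS
            vel[low, axis] = -vel[low, axis]
            high = ~done & (pos[:, axis] >= hi)
            pos[high, axis] = 2.0 * hi - pos[high, axis] - _WALL_EPS
            vel[high, axis] = -vel[high, axis]
        # baffle circles: reflect about the tangent at the entry point
        for cx, cz in geom.baffle_centers:
            d2 = (pos[:, 0] - cx) ** 2 + (pos[:, 1] - cz) ** 2
            hit = ~done & (d2 <= r * r)
            if not hit.any():
                continue
            p_old = old_pos[hit]
            p_new = pos[hit]
            entry = _circle_entry_point(p_old, p_new, (cx, cz), r)
            n_hat = (entry - np.array([cx, cz])) / r
            dp = p_new - entry
            dp -= 2.0 * np.sum(dp * n_hat, axis=1, keepdims=True) * n_hat
            pos[hit] = entry + dp + n_hat * _WALL_EPS
            v = vel[hit]
            v -= 2.0 * np.sum(v * n_hat, axis=1, keepdims=True) * n_hat
            vel[hit] = v

    still_out = ~points_in_fluid(geom, pos)
    if still_out.any():
        pos[still_out] = old_pos[still_out]
    return pos, vel


def _circle_entry_point(
    p_old: np.ndarray, p_new: np.ndarray, center: tuple[float, float], r: float
) -> np.ndarray:
    """First intersection of segments old->new with the circle.

    Falls back to the radial projection of the old point when the segment
    geometry is degenerate (e.g. the old point already touches the surface).
    """
    c = np.asarray(center, dtype=float)
    d = p_new - p_old
    f = p_old - c
    a = np.sum(d * d, axis=1)
    b = 2.0 * np.sum(f * d, axis=1)
    cc = np.sum(f * f, axis=1) - r * r
    disc = b * b - 4.0 * a * cc
    t = np.full(len(p_old), np.nan)
    ok = (disc >= 0) & (a > 0)
    sq = np.sqrt(np.clip(disc, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (-b - sq) / (2.0 * a)
        t2 = (-b + sq) / (2.0 * a)
    for cand in (t1, t2):
        use = ok & np.isnan(t) & (cand >= -1e-12) & (cand <= 1.0)
        t[use] = cand[use]
    entry = p_old + np.clip(t, 0.0, 1.0)[:, None] * d
    bad = np.isnan(t)
    if bad.any():
        f_bad = p_old[bad] - c
        norm = np.linalg.norm(f_bad, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        entry[bad] = c + f_bad / norm * r
    return entry


def track(
    fld,
    geom: ReactorGeometry,
    spec: ParticleSpec | None = None,
    n: int = 1000,
    dt: float = 0.004,
    record_dt: float = 0.1,
    t_max: float = 60.0,
    seed: int = 0,
    include_pressure_gradient: bool = True,
    jitter_radius: float = 2.0,
) -> TrajectorySet:
    """Full tracking loop; deterministic for a given seed.

    Positions are recorded every ``record_dt`` (must be an integer multiple of
    ``dt``) from t = 0 to ``t_max`` inclusive.
    """
    spec = spec or ParticleSpec()
    steps_per_record = record_dt / dt
    if abs(steps_per_record - round(steps_per_record)) > 1e-9:
        raise ValueError("record_dt must be an integer multiple of dt")
    m = int(round(steps_per_record))
    n_records = int(round(t_max / record_dt)) + 1

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pos = inject_particles(geom, n, rng, jitter_radius=jitter_radius)
    vx, vz = fld.velocity(pos[:, 0], pos[:, 1])
    vel = np.column_stack([vx, vz])
    drw = DiscreteRandomWalk(n, getattr(fld, "eddy_time", 0.5), rng)
    turbulent = getattr(fld, "turbulence_intensity", 0.0) > 0.0

    positions = np.empty((n, n_records, 2))
    positions[:, 0] = pos
    record_times = np.arange(n_records) * record_dt

    for rec in range(1, n_records):
        for _ in range(m):
            if turbulent:
                k = fld.k(pos[:, 0], pos[:, 1])
                uprime = drw.sample(k, dt)
            else:
                uprime = None
            new_pos, vel = advance(
                fld,
                spec,
                pos,
                vel,
                dt,
                uprime=uprime,
                include_pressure_gradient=include_pressure_gradient,
            )
            pos, vel = reflect_boundary(geom, pos, new_pos, vel)
        positions[:, rec] = pos

    provenance = {
        "regime": getattr(fld, "regime_tag", "unknown"),
        "aeration_vvm": getattr(fld, "aeration_rate", None),
        "turbulence_intensity": getattr(fld, "turbulence_intensity", 0.0),
        "eddy_time_s": getattr(fld, "eddy_time", None),
        "dt_s": dt,
        "n_particles": n,
    }
    return TrajectorySet(
        record_times=record_times,
        positions=positions,
        particle_ids=np.arange(n),
        seed=seed,
        provenance=provenance,
    )


def trajectories_to_csv(traj: TrajectorySet, path) -> None:
    """Write t_s, particle_id, x_mm, z_mm rows with '#' metadata headers."""
    buf = io.StringIO()
    buf.write(f"# seed={traj.seed}\n")
    for key in ("regime", "aeration_vvm"):
        buf.write(f"# {key}={traj.provenance.get(key)}\n")
    w = csv.writer(buf)
    w.writerow(["t_s", "particle_id", "x_mm", "z_mm"])
    for j, t in enumerate(traj.record_times):
        for i, pid in enumerate(traj.particle_ids):
            x, z = traj.positions[i, j]
            w.writerow([f"{t:.1f}", int(pid), f"{x:.6f}", f"{z:.6f}"])
    with open(path, "w", newline="") as fh:
        fh.write(buf.getvalue())


def trajectories_from_csv(path) -> TrajectorySet:
    meta: dict = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
                continue
            rows.append(line)
    reader = csv.reader(rows)
    header = next(reader)
    if header[:4] != ["t_s", "particle_id", "x_mm", "z_mm"]:
        raise ValueError(f"unexpected trajectory header {header!r}")
    data = np.array([[float(a), float(b), float(c), float(d)] for a, b, c, d in reader])
    times = np.unique(data[:, 0])
    ids = np.unique(data[:, 1]).astype(int)
    positions = np.empty((len(ids), len(times), 2))
    t_index = {t: j for j, t in enumerate(times)}
    id_index = {i: k for k, i in enumerate(ids)}
    for t, pid, x, z in data:
        positions[id_index[int(pid)], t_index[t]] = (x, z)
    return TrajectorySet(
        record_times=times,
        positions=positions,
        particle_ids=ids,
        seed=int(meta.get("seed", -1)),
        provenance={k: v for k, v in meta.items() if k != "seed"},
    )
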