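"""Massless particle tracing along streamlines of a solved velocity field.

At the library's scales (water, particle diameters 1-20 um) the particle
relaxation time ``d^2 rho_p / (18 eta)`` is at most a few tens of
microseconds, so a drag-coupled particle follows fluid streamlines to an
excellent approximation.  Default tracing therefore integrates the kinematic
system ``dX/dt = u(X)`` with 4th-order Runge-Kutta and bilinear velocity
interpolation on the staggered grid.  Finite particle size enters only
through the wall-freeze rule (a particle whose center comes within one radius
of a wall sticks there) and through release insets at channel mouths.

The cumulative-flow coordinate ``q``
------------------------------------
Across a fully developed channel cross section the flow fraction

    q(y) = int_0^y u dy' / int_0^w u dy',   q in [0, 1],

labels streamlines: ``q`` is conserved along a streamline through straight
channels and low-Reynolds turns, which is what lets intersection-local
trajectories be expanded through the rest of a chip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .geometry import Domain, Mouth, mouth_faces
from .stokes import VelocityField

__all__ = [
    "ParticleSpec",
    "Trajectory",
    "StepControl",
    "StagnationError",
    "FieldSampler",
    "flow_fraction",
    "inverse_flow_fraction",
    "trace_particle",
    "release_positions",
    "release_uniform",
    "relaxation_time",
]


class StagnationError(RuntimeError):
    """Integration stalled (speed underflow or step cap) before any exit."""

    def __init__(self, message: str, last_position):
        super().__init__(message)
        self.last_position = tuple(last_position)


@dataclass(frozen=True)
class ParticleSpec:
    """A particle: diameter (m) and release position (m)."""

    diameter: float
    start: tuple[float, float]

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass
class Trajectory:
    points: np.ndarray  # (n, 2) polyline, m
    fate: str  # "exited" | "frozen"
    exit_name: str | None = None  # mouth name if exited
    q_entry: float | None = None
    q_exit: float | None = None
    diameter: float | None = None
    provenance: dict = dc_field(default_factory=dict)

    @property
    def arc_length(self) -> float:
        d = np.diff(self.points, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass(frozen=True)
class StepControl:
    """Adaptive step control: per-step displacement <= frac * grid spacing."""

    frac: float = 0.5
    max_steps: int = 10_000_000
    speed_floor_rel: float = 1e-9  # relative to the field's peak speed


def flow_fraction(y: float, width: float):
    """Cumulative flow fraction of the parabolic profile at offset ``y``.

    With ``s = y/width``, ``q = s^2 (3 - 2 s)``; strictly increasing from 0
    at one wall to 1 at the other, 0.5 on the centerline.
    """
    y = np.asarray(y, dtype=float)
    if np.any((y < -1e-12 * width) | (y > width * (1 + 1e-12))):
        raise ValueError(f"transverse position outside [0, {width}]")
    s = np.clip(y / width, 0.0, 1.0)
    out = s * s * (3.0 - 2.0 * s)
    return float(out) if out.ndim == 0 else out


def inverse_flow_fraction(q: float, width: float):
    """Transverse position with a given flow fraction (inverse of the cubic)."""
    q_arr = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any((q_arr < 0.0) | (q_arr > 1.0)):
        raise ValueError("flow fraction must lie in [0, 1]")
    s = np.clip(q_arr, 0.0, 1.0)  # starting guess; exact at 0, 1/2, 1
    for _ in range(60):
        f = s * s * (3.0 - 2.0 * s) - q_arr
        df = 6.0 * s * (1.0 - s)
        step = np.where(df > 1e-12, f / np.maximum(df, 1e-12), 0.0)
        s_new = np.clip(s - step, 0.0, 1.0)
        if np.max(np.abs(s_new - s)) < 1e-16:
            s = s_new
            break
        s = s_new
    # bisection fallback for endpoints where Newton's slope vanishes
    bad = np.abs(s * s * (3 - 2 * s) - q_arr) > 1e-12
    for i in np.nonzero(bad)[0]:
        lo, hi = 0.0, 1.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if mid * mid * (3 - 2 * mid) < q_arr[i]:
                lo = mid
            else:
                hi = mid
        s[i] = 0.5 * (lo + hi)
    out = s * width
    return float(out[0]) if np.isscalar(q) or np.ndim(q) == 0 else out


class FieldSampler:
    """Bilinear velocity interpolation with wall and mouth ghost handling.

    Tangential velocities reflect across walls (no-slip); one layer of faces
    beyond each mouth is filled by zero-gradient extrapolation so Runge-Kutta
    substeps that peek past a mouth plane see sensible velocities.
    """

    def __init__(self, fld: VelocityField, sign: float = 1.0):
        dom = fld.domain
        self.origin = dom.origin
        self.h = dom.spacing
        mask = dom.mask
        nx, ny = mask.shape
        act_u = np.zeros((nx + 1, ny), dtype=bool)
        act_u[1:, :] |= mask
        act_u[:-1, :] |= mask
        act_v = np.zeros((nx, ny + 1), dtype=bool)
        act_v[:, 1:] |= mask
        act_v[:, :-1] |= mask
        u = fld.u.copy()
        v = fld.v.copy()
        # no-slip reflection ghosts one layer into walls
        for arr, act, axis in ((u, act_u, 1), (v, act_v, 0)):
            for d in (1, -1):
                shifted_act = np.roll(act, d, axis=axis)
                shifted_val = np.roll(arr, d, axis=axis)
                edge = ~act & shifted_act
                if d == 1:
                    if axis == 1:
                        edge[:, 0] = False
                    else:
                        edge[0, :] = False
                else:
                    if axis == 1:
                        edge[:, -1] = False
                    else:
                        edge[-1, :] = False
                arr[edge] = -shifted_val[edge]
        # zero-gradient layer beyond each mouth (overrides reflections)
        for m in dom.mouths.values():
            axis, face, lo, hi, sgn = mouth_faces(dom, m)
            if axis == 0:
                src = u[face, lo:hi]
                tgt = face + sgn
                if 0 <= tgt <= nx:
                    u[tgt, lo:hi] = src
                col = face if sgn > 0 else face - 1
                if 0 <= col < nx:
                    v[col, lo:hi + 1] = v[col - sgn, lo:hi + 1]
            else:
                src = v[lo:hi, face]
                tgt = face + sgn
                if 0 <= tgt <= ny:
                    v[lo:hi, tgt] = src
                row = face if sgn > 0 else face - 1
                if 0 <= row < ny:
                    u[lo:hi + 1, row] = u[lo:hi + 1, row - sgn]
        self.u = sign * u
        self.v = sign * v

    def __call__(self, point):
        x = (point[0] - self.origin[0]) / self.h
        y = (point[1] - self.origin[1]) / self.h
        return (_interp(self.u, x, y - 0.5), _interp(self.v, x - 0.5, y))


def _interp(arr, gx, gy):
    nx, ny = arr.shape
    gx = min(max(gx, 0.0), nx - 1.0)
    gy = min(max(gy, 0.0), ny - 1.0)
    x0 = min(int(gx), nx - 2) if nx > 1 else 0
    y0 = min(int(gy), ny - 2) if ny > 1 else 0
    fx = gx - x0
    fy = gy - y0
    return (arr[x0, y0] * (1 - fx) * (1 - fy)
            + arr[x0 + 1, y0] * fx * (1 - fy)
            + arr[x0, y0 + 1] * (1 - fx) * fy
            + arr[x0 + 1, y0 + 1] * fx * fy)


def trace_particle(
    fld: VelocityField,
    particle: ParticleSpec,
    step_ctrl: StepControl | None = None,
    backward: bool = False,
) -> Trajectory:
    """Advect a particle along streamlines until it exits or freezes.

    The trajectory ends with fate ``"exited"`` when the particle crosses a
    mouth plane (the final point is clipped onto the plane and the exit flow
    fraction recorded from the analytic profile), or ``"frozen"`` when its
    center comes within one radius of a wall.  A stagnation point (speed
    underflow) raises :class:`StagnationError`.
    """
    ctrl = step_ctrl or StepControl()
    dom = fld.domain
    sampler = FieldSampler(fld, sign=-1.0 if backward else 1.0)
    vmax = fld.max_speed()
    if vmax == 0.0:
        raise StagnationError("velocity field is identically zero", particle.start)
    floor = ctrl.speed_floor_rel * vmax
    h = dom.spacing
    r = particle.radius

    pos = np.asarray(particle.start, dtype=float)
    q_entry = None
    m0 = _mouth_of_point(dom, pos)
    if m0 is not None:
        q_entry = flow_fraction(
            min(max(m0.coord_of(pos, "in"), 0.0), m0.width), m0.width)

    pts = [pos.copy()]
    frozen = dom.wall_distance(pos) <= r
    exit_mouth = None
    q_exit = None
    steps = 0
    while not frozen and exit_mouth is None:
        if steps >= ctrl.max_steps:
            raise StagnationError(
                f"step cap {ctrl.max_steps} exceeded", tuple(pos))
        ux, uy = sampler(pos)
        speed = math.hypot(ux, uy)
        if speed < floor:
            raise StagnationError(
                f"stagnation: speed {speed:.3e} m/s below floor", tuple(pos))
        dt = ctrl.frac * h / speed
        k1 = np.array([ux, uy])
        k2 = np.asarray(sampler(pos + 0.5 * dt * k1))
        k3 = np.asarray(sampler(pos + 0.5 * dt * k2))
        k4 = np.asarray(sampler(pos + dt * k3))
        new = pos + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        steps += 1

        m = dom.mouth_hit(new)
        if m is not None and m is not m0:
            d_old = ((pos[0] - m.center[0]) * m.outward[0]
                     + (pos[1] - m.center[1]) * m.outward[1])
            d_new = ((new[0] - m.center[0]) * m.outward[0]
                     + (new[1] - m.center[1]) * m.outward[1])
            frac = 0.0 if d_new == d_old else max(0.0, min(1.0, -d_old / (d_new - d_old)))
            new = pos + frac * (new - pos)
            exit_mouth = m
            t = min(max(m.coord_of(new, "out"), 0.0), m.width)
            q_exit = flow_fraction(t, m.width)
        elif dom.wall_distance(new) <= r:
            frozen = True
        elif m0 is not None and _mouth_dist(m0, new) < 0.0:
            pass  # still crossing the entry plane region
        else:
            m0 = None
        pos = new
        pts.append(pos.copy())

    return Trajectory(
        points=np.asarray(pts),
        fate="frozen" if frozen else "exited",
        exit_name=None if frozen else exit_mouth.name,
        q_entry=q_entry,
        q_exit=q_exit,
        diameter=particle.diameter,
        provenance={
            "steps": steps,
            "backward": backward,
            "freeze_rule": "center-to-wall distance <= radius",
            "step_frac": ctrl.frac,
        },
    )


def _mouth_dist(m: Mouth, point) -> float:
    return ((point[0] - m.center[0]) * m.outward[0]
            + (point[1] - m.center[1]) * m.outward[1])


def _mouth_of_point(dom: Domain, point, tol_frac: float = 1e-6):
    for m in dom.mouths.values():
        if abs(_mouth_dist(m, point)) <= tol_frac * m.width:
            t = m.coord_of(point, "in")
            if -1e-9 * m.width <= t <= m.width * (1 + 1e-9):
                return m
    return None


def release_positions(width: float, n: int, diameter: float) -> np.ndarray:
    """Evenly spaced transverse release offsets, inset one radius from walls.

    ``n = 1`` releases on the centerline; for ``n >= 2`` the positions span
    ``[r, width - r]`` inclusively (10 per release by default upstream).
    """
    if n < 1:
        raise ValueError("need n >= 1")
    if diameter >= width:
        raise ValueError(
            f"particle diameter {diameter} does not fit in a {width} wide channel")
    r = diameter / 2.0
    if n == 1:
        return np.array([width / 2.0])
    return np.linspace(r, width - r, n)


def release_uniform(mouth: Mouth, n: int, diameter: float) -> list[ParticleSpec]:
    """Uniformly distributed release of ``n`` particles across an inlet mouth."""
    return [
        ParticleSpec(diameter=diameter, start=mouth.point_at(float(t), "in"))
        for t in release_positions(mouth.width, n, diameter)
    ]


def relaxation_time(diameter: float, particle_density: float = 1050.0,
                    viscosity: float = 1.0e-3) -> float:
    """Stokes relaxation time ``d^2 rho_p / (18 eta)`` in seconds.

    Below ~1e-4 s (true for all supported diameters in water) the massless
    streamline-following approximation is justified.
    """
    return diameter**2 * particle_density / (18.0 * viscosity)
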