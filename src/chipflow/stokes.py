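"""Steady incompressible viscous flow on masked 2D channel domains.

This module stands in for the finite-element laminar-flow step: it solves the
stationary Stokes equations

    mu * laplace(u) = grad(p),   div(u) = 0

on the cross/T-shaped unit-intersection domain (and, as an internal oracle,
on whole-chip domains) with no-slip walls and prescribed fully-developed
(parabolic) velocity profiles at inflow/outflow mouths.

At the library's operating point (water, 200 um channels, <= 2 cm/s) the
Reynolds number is of order 1, so inertia is neglected by default; this keeps
the problem linear, which the library exploits (velocity fields scale exactly
with the boundary velocities, so one stored field covers a whole ray of
operating points).  An optional Picard-iterated convective correction is
available behind the ``convective`` flag for parity experiments.

Discretization: uniform staggered (MAC) grid; x-velocity ``u`` on vertical
faces, y-velocity ``v`` on horizontal faces, pressure at cell centers.
Second-order centered differences; no-slip enters tangentially through
ghost-value reflection across walls.  The saddle-point system is solved with
a sparse direct factorization.  One outflow mouth is left "open" (zero
normal-velocity gradient, fixed boundary pressure), which both absorbs the
discrete mass balance and anchors the pressure level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import Domain, Mouth, mouth_faces, unit_intersection_domain
from .netlist import ARMS, ChipNetlist

__all__ = [
    "ConservationError",
    "StokesError",
    "VelocityField",
    "poiseuille_profile",
    "solve_stokes",
    "solve_full_chip",
    "solve_masked_stokes",
    "check_divergence",
    "mouth_flux",
]


class StokesError(RuntimeError):
    """The viscous-flow solve failed."""


class ConservationError(ValueError):
    """Prescribed boundary velocities do not conserve mass."""


def poiseuille_profile(width: float, mean_u: float):
    """Fully developed plane-channel profile with the given mean velocity.

    Returns a vectorized function ``f(t)`` of the transverse coordinate
    ``t in [0, width]`` with ``f(0) = f(width) = 0``, apex ``1.5 * mean_u``
    and mean exactly ``mean_u``.
    """
    if not width > 0:
        raise ValueError("width must be positive")

    def profile(t):
        s = np.asarray(t, dtype=float) / width
        return 1.5 * mean_u * (1.0 - (2.0 * s - 1.0) ** 2)

    return profile


@dataclass
class VelocityField:
    """A discrete MAC velocity/pressure field over a masked domain.

    ``u`` has shape ``(nx+1, ny)`` (x-velocity on vertical faces), ``v``
    shape ``(nx, ny+1)``, ``p`` shape ``(nx, ny)``.  Velocities on inactive
    faces are zero.  ``provenance`` records the boundary spec and solver
    settings that produced the field.
    """

    domain: Domain
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    provenance: dict = dc_field(default_factory=dict)

    @property
    def spacing(self) -> float:
        return self.domain.spacing

    def max_speed(self) -> float:
        return float(max(np.abs(self.u).max(initial=0.0),
                         np.abs(self.v).max(initial=0.0)))

    def scaled(self, factor: float) -> "VelocityField":
        return VelocityField(self.domain, self.u * factor, self.v * factor,
                             self.p * factor,
                             {**self.provenance, "scaled_by": factor})


def check_divergence(fld: VelocityField) -> float:
    """Maximum absolute discrete divergence (1/s) over fluid cells."""
    m = fld.domain.mask
    h = fld.spacing
    div = (fld.u[1:, :] - fld.u[:-1, :] + fld.v[:, 1:] - fld.v[:, :-1]) / h
    return float(np.abs(div[m]).max(initial=0.0))


def flux_across(fld: VelocityField, center, normal, width: float) -> float:
    """Volumetric flux per unit depth (m^2/s) across a transverse line.

    ``center`` is a point on a channel centerline, ``normal`` the axis-aligned
    flow direction; positive flux flows along ``normal``.
    """
    from .geometry import Mouth, mouth_faces

    m = Mouth("_section", tuple(center), (float(normal[0]), float(normal[1])), width)
    axis, face, lo, hi, sign = mouth_faces(fld.domain, m)
    vals = fld.u[face, lo:hi] if axis == 0 else fld.v[lo:hi, face]
    return float(sign * vals.sum() * fld.domain.spacing)


def mouth_flux(fld: VelocityField, name: str) -> float:
    """Signed volumetric flux per unit depth (m^2/s) *into* the domain."""
    dom = fld.domain
    axis, face, lo, hi, sign = mouth_faces(dom, dom.mouths[name])
    vals = fld.u[face, lo:hi] if axis == 0 else fld.v[lo:hi, face]
    return float(-sign * vals.sum() * dom.spacing)


# ---------------------------------------------------------------------------
# Core masked solver

_INACTIVE, _UNKNOWN, _KNOWN, _OPEN = 0, 1, 2, 3


def _classify(domain: Domain, bcs: dict):
    """Face classification and known values for both velocity components."""
    nx, ny = domain.mask.shape
    fluid = np.zeros((nx + 2, ny + 2), dtype=bool)
    fluid[1:-1, 1:-1] = domain.mask

    def fl(ix, iy):  # fluid test with implicit solid border
        return fluid[ix + 1, iy + 1]

    cls_u = np.zeros((nx + 1, ny), dtype=np.int8)
    val_u = np.zeros((nx + 1, ny))
    cls_v = np.zeros((nx, ny + 1), dtype=np.int8)
    val_v = np.zeros((nx, ny + 1))
    # cells one layer beyond each mouth -> True if the mouth is open
    beyond: dict[tuple[int, int], bool] = {}
    open_pressure: dict[tuple, float] = {}

    for name, (kind, value) in bcs.items():
        mouth = domain.mouths[name]
        axis, face, lo, hi, sign = mouth_faces(domain, mouth)
        is_open = kind == "pressure"
        n_faces = hi - lo
        h = domain.spacing
        if kind == "velocity":
            prof = poiseuille_profile(mouth.width, value)
            t = (np.arange(n_faces) + 0.5) * h
            normal = prof(t) * (-sign)  # velocity component along the axis
        for k in range(n_faces):
            if axis == 0:
                pos = (face, lo + k)
                cls, val = cls_u, val_u
                gcell = (face if sign > 0 else face - 1, lo + k)
            else:
                pos = (lo + k, face)
                cls, val = cls_v, val_v
                gcell = (lo + k, face if sign > 0 else face - 1)
            if is_open:
                cls[pos] = _OPEN
                open_pressure[(axis,) + pos] = value
            else:
                cls[pos] = _KNOWN
                val[pos] = normal[k]
            beyond[gcell] = is_open

    for ix in range(nx + 1):
        for iy in range(ny):
            if cls_u[ix, iy]:
                continue
            l, r = fl(ix - 1, iy), fl(ix, iy)
            if l and r:
                cls_u[ix, iy] = _UNKNOWN
            elif l or r:
                cls_u[ix, iy] = _KNOWN  # wall face, value 0
    for ix in range(nx):
        for iy in range(ny + 1):
            if cls_v[ix, iy]:
                continue
            b, t = fl(ix, iy - 1), fl(ix, iy)
            if b and t:
                cls_v[ix, iy] = _UNKNOWN
            elif b or t:
                cls_v[ix, iy] = _KNOWN
    return cls_u, val_u, cls_v, val_v, beyond, open_pressure


def solve_masked_stokes(
    domain: Domain,
    bcs: dict,
    viscosity: float = 1.0e-3,
    convective: bool = False,
    density: float = 998.0,
    picard_iterations: int = 5,
) -> VelocityField:
    """Solve steady Stokes flow on ``domain``.

    ``bcs`` maps mouth names to ``("velocity", signed_mean)`` (positive into
    the domain, parabolic profile) or ``("pressure", value_pa)`` (open mouth,
    zero normal-velocity gradient).  At least one open mouth is required to
    anchor the pressure.  With ``convective=True`` the nonlinear term
    ``rho (u . grad) u`` is added by Picard iteration on the right-hand side.
    """
    for name in bcs:
        if name not in domain.mouths:
            raise KeyError(f"no mouth named {name!r} in domain")
    if not any(kind == "pressure" for kind, _ in bcs.values()):
        raise StokesError("need at least one open (pressure) mouth")

    nx, ny = domain.mask.shape
    h = domain.spacing
    cls_u, val_u, cls_v, val_v, beyond, open_p = _classify(domain, bcs)

    uid = -np.ones(cls_u.shape, dtype=np.int64)
    vid = -np.ones(cls_v.shape, dtype=np.int64)
    un = np.flatnonzero((cls_u == _UNKNOWN) | (cls_u == _OPEN))
    uid.ravel()[un] = np.arange(un.size)
    vn = np.flatnonzero((cls_v == _UNKNOWN) | (cls_v == _OPEN))
    vid.ravel()[vn] = un.size + np.arange(vn.size)
    n_uv = un.size + vn.size
    cells = np.argwhere(domain.mask)
    pid = -np.ones((nx, ny), dtype=np.int64)
    pid[domain.mask] = n_uv + np.arange(len(cells))
    n_tot = n_uv + len(cells)

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    rhs = np.zeros(n_tot)

    fluid = np.zeros((nx + 2, ny + 2), dtype=bool)
    fluid[1:-1, 1:-1] = domain.mask

    def fl(ix, iy):
        return fluid[ix + 1, iy + 1]

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    pscale = h / viscosity  # p_tilde = p * h / mu, makes the system O(1)

    def neighbor(cls, val, ids, pos, row, ghost_cells):
        """Add one Laplacian neighbor; returns diagonal adjustment."""
        arr_ok = 0 <= pos[0] < cls.shape[0] and 0 <= pos[1] < cls.shape[1]
        c = cls[pos] if arr_ok else _INACTIVE
        if c in (_UNKNOWN, _OPEN):
            add(row, ids[pos], 1.0)
            return 0.0
        if c == _KNOWN:
            rhs[row] -= val[pos]
            return 0.0
        # inactive: ghost across a wall (reflect) or an open mouth (copy)
        if any(beyond.get(g, False) for g in ghost_cells):
            return 1.0  # copy: u_ghost = u_self
        return -1.0  # reflect: u_ghost = -u_self

    # momentum equations for u faces -----------------------------------
    for ix, iy in zip(*np.where(uid >= 0)):
        row = uid[ix, iy]
        diag = -4.0
        is_open = cls_u[ix, iy] == _OPEN
        if is_open:
            # outward side: ghost u = u (zero gradient), ghost p = spec
            sgn = 1 if fl(ix - 1, iy) else -1  # +1: fluid to the left, open to the right
            diag += 1.0
            inner = (ix - sgn, iy)
            c = cls_u[inner]
            if c in (_UNKNOWN, _OPEN):
                add(row, uid[inner], 1.0)
            else:
                rhs[row] -= val_u[inner]
            pspec = open_p[(0, ix, iy)] * pscale
            if sgn > 0:  # d(p)/dx uses (p_spec - p_L)
                add(row, pid[ix - 1, iy], 1.0)
                rhs[row] += pspec
            else:
                add(row, pid[ix, iy], -1.0)
                rhs[row] -= pspec
        else:
            for dx in (-1, 1):
                diag += neighbor(cls_u, val_u, uid, (ix + dx, iy), row,
                                 ghost_cells=())
            add(row, pid[ix, iy], -1.0)
            add(row, pid[ix - 1, iy], 1.0)
        for dy in (-1, 1):
            diag += neighbor(
                cls_u, val_u, uid, (ix, iy + dy), row,
                ghost_cells=((ix - 1, iy + dy), (ix, iy + dy)),
            )
        add(row, row, diag)

    # momentum equations for v faces -----------------------------------
    for ix, iy in zip(*np.where(vid >= 0)):
        row = vid[ix, iy]
        diag = -4.0
        is_open = cls_v[ix, iy] == _OPEN
        if is_open:
            sgn = 1 if fl(ix, iy - 1) else -1
            diag += 1.0
            inner = (ix, iy - sgn)
            c = cls_v[inner]
            if c in (_UNKNOWN, _OPEN):
                add(row, vid[inner], 1.0)
            else:
                rhs[row] -= val_v[inner]
            pspec = open_p[(1, ix, iy)] * pscale
            if sgn > 0:
                add(row, pid[ix, iy - 1], 1.0)
                rhs[row] += pspec
            else:
                add(row, pid[ix, iy], -1.0)
                rhs[row] -= pspec
        else:
            for dy in (-1, 1):
                diag += neighbor(cls_v, val_v, vid, (ix, iy + dy), row,
                                 ghost_cells=())
            add(row, pid[ix, iy], -1.0)
            add(row, pid[ix, iy - 1], 1.0)
        for dx in (-1, 1):
            diag += neighbor(
                cls_v, val_v, vid, (ix + dx, iy), row,
                ghost_cells=((ix + dx, iy - 1), (ix + dx, iy)),
            )
        add(row, row, diag)

    # continuity per fluid cell ----------------------------------------
    for ix, iy in cells:
        row = pid[ix, iy]
        for pos, cls, val, ids, sgn in (
            ((ix + 1, iy), cls_u, val_u, uid, 1.0),
            ((ix, iy), cls_u, val_u, uid, -1.0),
            ((ix, iy + 1), cls_v, val_v, vid, 1.0),
            ((ix, iy), cls_v, val_v, vid, -1.0),
        ):
            if cls[pos] in (_UNKNOWN, _OPEN):
                add(row, ids[pos], sgn)
            else:
                rhs[row] -= sgn * val[pos]

    A = sp.csc_matrix(
        (np.asarray(vals), (np.asarray(rows), np.asarray(cols))),
        shape=(n_tot, n_tot),
    )
    try:
        lu = spla.splu(A)
    except RuntimeError as exc:
        raise StokesError(f"sparse factorization failed: {exc}") from None
    x = lu.solve(rhs)
    if not np.all(np.isfinite(x)):
        raise StokesError("singular viscous-flow system")

    def unpack(xvec):
        u = val_u.copy()
        u.ravel()[un] = xvec[:un.size]
        v = val_v.copy()
        v.ravel()[vn] = xvec[un.size:n_uv]
        p = np.zeros((nx, ny))
        p[domain.mask] = xvec[n_uv:] / pscale
        return u, v, p

    u, v, p = unpack(x)

    if convective:
        coeff = density * h / viscosity  # scaled momentum rows were * h^2/mu
        for _ in range(picard_iterations):
            rhs_c = rhs.copy()
            adv_u, adv_v = _advection(u, v, cls_u, cls_v, h)
            rhs_c[:un.size] += coeff * adv_u.ravel()[un] * h
            rhs_c[un.size:n_uv] += coeff * adv_v.ravel()[vn] * h
            x = lu.solve(rhs_c)
            u, v, p = unpack(x)

    return VelocityField(
        domain=domain, u=u, v=v, p=p,
        provenance={
            "bcs": {k: tuple(vv) for k, vv in bcs.items()},
            "viscosity": viscosity,
            "spacing": h,
            "convective": convective,
            "solver": "MAC/splu",
        },
    )


def _advection(u, v, cls_u, cls_v, h):
    """Centered (u . grad) u at u and v faces; crude, for the Picard flag."""
    adv_u = np.zeros_like(u)
    iu = cls_u == _UNKNOWN
    ux = np.zeros_like(u)
    ux[1:-1, :] = (u[2:, :] - u[:-2, :]) / (2 * h)
    uy = np.zeros_like(u)
    uy[:, 1:-1] = (u[:, 2:] - u[:, :-2]) / (2 * h)
    v_at_u = np.zeros_like(u)
    v_at_u[1:-1, :] = 0.25 * (v[1:, :-1] + v[1:, 1:] + v[:-1, :-1] + v[:-1, 1:])
    adv_u[iu] = (u * ux + v_at_u * uy)[iu]
    adv_v = np.zeros_like(v)
    iv = cls_v == _UNKNOWN
    vx = np.zeros_like(v)
    vx[1:-1, :] = (v[2:, :] - v[:-2, :]) / (2 * h)
    vy = np.zeros_like(v)
    vy[:, 1:-1] = (v[:, 2:] - v[:, :-2]) / (2 * h)
    u_at_v = np.zeros_like(v)
    u_at_v[:, 1:-1] = 0.25 * (u[:-1, 1:] + u[1:, 1:] + u[:-1, :-1] + u[1:, :-1])
    adv_v[iv] = (u_at_v * vx + v * vy)[iv]
    return adv_u, adv_v


# ---------------------------------------------------------------------------
# High-level entry points


def reference_outlet(arm_velocities: dict[str, float]) -> str:
    """The outflow arm left open during a unit-intersection solve.

    Chosen as the arm with the largest outflow magnitude, ties broken in
    N < E < S < W order.
    """
    best = None
    for arm in ARMS:
        vel = arm_velocities.get(arm, 0.0)
        if vel < 0.0 and (best is None or vel < arm_velocities[best]):
            best = arm
    if best is None:
        raise ConservationError("no outflow arm among the boundary conditions")
    return best


def solve_stokes(
    domain: Domain,
    arm_velocities: dict[str, float],
    viscosity: float = 1.0e-3,
    convective: bool = False,
) -> VelocityField:
    """Solve a unit intersection for signed mean arm velocities (+ = inflow).

    All arms except the reference outlet get prescribed parabolic profiles;
    the reference outlet is open.  Raises :class:`ConservationError` if the
    signed velocities do not sum to (nearly) zero.
    """
    active = [a for a in ARMS if a in domain.mouths]
    vels = {a: float(arm_velocities.get(a, 0.0)) for a in active}
    for arm, vel in arm_velocities.items():
        if arm not in active and abs(vel) > 0.0:
            raise ConservationError(f"velocity on unused arm {arm!r}")
    total = sum(abs(v) for v in vels.values())
    if total > 0 and abs(sum(vels.values())) > 1e-6 * total:
        raise ConservationError(
            f"arm velocities {vels} violate mass conservation"
        )
    ref = reference_outlet(vels)
    bcs = {
        arm: (("pressure", 0.0) if arm == ref else ("velocity", vels[arm]))
        for arm in active
    }
    fld = solve_masked_stokes(domain, bcs, viscosity=viscosity,
                              convective=convective)
    fld.provenance["arm_velocities"] = dict(vels)
    fld.provenance["reference_outlet"] = ref
    return fld


def solve_full_chip(
    netlist: ChipNetlist,
    spacing: float,
    convective: bool = False,
) -> VelocityField:
    """Direct whole-chip solve; the oracle the decomposition is judged against.

    Terminal boundary conditions come from the netlist: velocity terminals
    get parabolic profiles, pressure terminals are open.  If the netlist has
    no pressure terminal, the velocity terminal with the largest outflow is
    opened instead (its flux is implied by the balance of the others).
    """
    from .geometry import chip_domain

    domain = chip_domain(netlist, spacing)
    bcs = {}
    vel_terms = []
    for tid, bc in netlist.bc_map.items():
        if bc.kind == "pressure":
            bcs[tid] = ("pressure", bc.value)
        else:
            bcs[tid] = ("velocity", bc.value)
            vel_terms.append((bc.value, tid))
    if not any(kind == "pressure" for kind, _ in bcs.values()):
        _, tid = min(vel_terms)
        bcs[tid] = ("pressure", 0.0)
    return solve_masked_stokes(domain, bcs, viscosity=netlist.fluid.viscosity,
                               convective=convective,
                               density=netlist.fluid.density)
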