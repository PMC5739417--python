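"""Whole-chip particle simulation by stitching library intersections.

Given a netlist, the hydraulic network solution supplies every
intersection's arm boundary conditions; the library supplies each
intersection's pre-simulated flow and trajectories; and the cumulative-flow
coordinate ``q`` carries particles through the channels in between (``q`` is
conserved along streamlines in straight channels and 90-degree turns at low
Reynolds number).  The result is a complete particle path through the chip
computed without solving any new flow field.

Two retrieval modes exist at each intersection:

* mode ``"A"`` (default): re-trace the particle on the *stored* velocity
  field from its actual entry position — no new flow solve, one cheap
  streamline integration;
* mode ``"B"``: pure lookup — interpolate the exit flow fraction between the
  two stored release trajectories bracketing the entry position (snapping to
  the nearer release when the two disagree on the exit arm).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .geometry import chip_domain, rot90ccw
from .library import (
    CoverageError,
    IntersectionLibrary,
    MatchResult,
    UnitIntersectionSpec,
    apply_transform,
)
from .netlist import (
    ARM_DIR,
    ARMS,
    LIBRARY_ARM_REACH,
    LIBRARY_WIDTH,
    ChipNetlist,
    ChannelSegment,
    NodeSpec,
)
from .network import FlowSolution, solve_network
from .stokes import solve_full_chip
from .tracing import (
    ParticleSpec,
    StagnationError,
    flow_fraction,
    inverse_flow_fraction,
    trace_particle,
)

__all__ = [
    "EnvelopeError",
    "ParticleRelease",
    "IntersectionVisit",
    "ChipTrajectory",
    "SimulationReport",
    "simulate_chip",
    "propagate_channel",
    "traverse_intersection",
    "intersection_spec",
    "compare_with_direct",
]

#: Library validity envelope: terminal drive speeds (m/s) and channel width.
ENVELOPE_MAX_SPEED = 2e-2


class EnvelopeError(ValueError):
    """The chip operates outside the pre-simulated library envelope."""


@dataclass(frozen=True)
class ParticleRelease:
    """One particle to simulate: entry terminal, diameter, entry flow fraction."""

    terminal: str
    diameter: float
    q: float = 0.5


@dataclass(frozen=True)
class IntersectionVisit:
    intersection_id: str
    record_id: str
    distance: float
    mode: str
    entry_arm: str
    exit_arm: str | None
    q_in: float
    q_out: float | None
    note: str = ""


@dataclass
class ChipTrajectory:
    release: ParticleRelease
    points: np.ndarray
    fate: str  # "exited" | "frozen"
    exit_terminal: str | None
    q_exit: float | None
    visits: list[IntersectionVisit] = dc_field(default_factory=list)
    channel_q: list[tuple[str, float]] = dc_field(default_factory=list)
    #: indices into ``points`` where one stitched piece ends and the next begins
    piece_breaks: tuple[int, ...] = ()

    def junction_gaps(self) -> np.ndarray:
        """Distances between consecutive stitched pieces (continuity check)."""
        if not self.piece_breaks:
            return np.zeros(0)
        b = np.asarray(self.piece_breaks)
        return np.hypot(*(self.points[b] - self.points[b - 1]).T)


@dataclass
class SimulationReport:
    trajectories: list[ChipTrajectory]
    solution: FlowSolution
    wall_clock: float
    max_match_distance: float
    provenance: dict = dc_field(default_factory=dict)


# ---------------------------------------------------------------------------
# Channel propagation


def _offset_polyline(waypoints, offset: float) -> np.ndarray:
    """Polyline displaced ``offset`` to the left of the travel direction.

    For 90-degree corners the displaced corner is the intersection of the two
    displaced leg lines, which for axis-aligned legs is
    ``corner + offset * (left1 + left2)``.
    """
    pts = [np.asarray(p, dtype=float) for p in waypoints]
    lefts = []
    for a, b in zip(pts[:-1], pts[1:]):
        d = b - a
        d = d / np.hypot(*d)
        lefts.append(np.asarray(rot90ccw((d[0], d[1]))))
    out = [pts[0] + offset * lefts[0]]
    for i in range(1, len(pts) - 1):
        out.append(pts[i] + offset * (lefts[i - 1] + lefts[i]))
    out.append(pts[-1] + offset * lefts[-1])
    return np.asarray(out)


def _trimmed_waypoints(seg: ChannelSegment, from_node: str,
                       trim_start: float, trim_end: float):
    """Segment centerline, oriented from ``from_node``, trimmed at the ends.

    Trimming shortens the first/last leg (the part buried inside an
    intersection footprint); each trimmed leg must be at least that long.
    """
    pts = [np.asarray(p, dtype=float) for p in seg.waypoints]
    if seg.nodes[0] != from_node:
        pts = pts[::-1]
    for trim, idx, nb in ((trim_start, 0, 1), (trim_end, -1, -2)):
        if trim <= 0:
            continue
        d = pts[nb] - pts[idx]
        leg = np.hypot(*d)
        if leg + 1e-12 < trim:
            raise EnvelopeError(
                f"segment {seg.id!r}: end leg ({leg * 1e6:.0f} um) shorter than the "
                f"intersection half-footprint ({trim * 1e6:.0f} um); cannot stitch")
        pts[idx] = pts[idx] + d / leg * min(trim, leg)
    # trimming can consume an entire leg (adjacent footprints touching)
    out = [pts[0]]
    for p in pts[1:]:
        if np.hypot(*(p - out[-1])) > 1e-12:
            out.append(p)
    return [tuple(p) for p in out]


def propagate_channel(q_in: float, channel: ChannelSegment,
                      from_node: str | None = None,
                      trim_start: float = 0.0,
                      trim_end: float = 0.0) -> tuple[float, np.ndarray]:
    """Carry a particle through a channel at constant flow fraction.

    Returns ``(q_out, polyline)``: ``q_out == q_in`` (straight channels and
    90-degree turns preserve the cumulative-flow coordinate), and the
    polyline is the streamline path offset from the centerline at the
    transverse position with flow fraction ``q_in``.
    """
    if not 0.0 <= q_in <= 1.0:
        raise ValueError("flow fraction must lie in [0, 1]")
    t = inverse_flow_fraction(q_in, channel.width)
    wp = _trimmed_waypoints(channel, from_node or channel.nodes[0],
                            trim_start, trim_end)
    if len(wp) < 2:  # fully buried between touching footprints
        return q_in, np.empty((0, 2))
    return q_in, _offset_polyline(wp, t - channel.width / 2.0)


# ---------------------------------------------------------------------------
# Intersection traversal


def intersection_spec(sol: FlowSolution, intersection_id: str) -> UnitIntersectionSpec:
    """Unit-intersection boundary spec of a chip intersection, from the network."""
    node = sol.netlist.node_map[intersection_id]
    vels = sol.arm_velocities(intersection_id)
    arm_map = node.arm_map
    roles = []
    clean = []
    for arm in ARMS:
        v = vels[arm]
        if arm not in arm_map or abs(v) < 1e-15:
            roles.append("unused")
            clean.append(0.0)
        else:
            roles.append("inlet" if v > 0 else "outlet")
            clean.append(v)
    resid = sum(clean)
    if resid != 0.0:  # re-zero solver round-off on the largest outlet
        k = int(np.argmin(clean))
        clean[k] -= resid
    return UnitIntersectionSpec(tuple(roles), tuple(clean))


def traverse_intersection(
    q_in: float,
    entry_arm: str,
    spec: UnitIntersectionSpec,
    library: IntersectionLibrary,
    diameter: float,
    mode: str = "A",
):
    """Carry a particle through one intersection via the library.

    Returns ``(exit_arm, q_out, local_points, match, note)`` where
    ``local_points`` is the particle path in the intersection's local frame
    (footprint coordinates, chip orientation) and ``exit_arm`` is ``None``
    if the particle froze inside.  Raises :class:`CoverageError` if the
    library lacks the configuration.
    """
    if mode not in ("A", "B"):
        raise ValueError("mode must be 'A' or 'B'")
    match = library.query(spec)
    T = match.transform  # record frame -> query/chip frame
    Tinv = T.inverse()
    arm_r = Tinv.map_arm(entry_arm)
    q_r = Tinv.map_q(q_in)
    center = (spec.footprint / 2.0, spec.footprint / 2.0)
    note = ""

    if mode == "A":
        fld = library.get_field(match.record_id)
        mouth = fld.domain.mouths[arm_r]
        t = inverse_flow_fraction(q_r, mouth.width)
        start = mouth.point_at(t, "in")
        traj = trace_particle(fld, ParticleSpec(diameter=diameter, start=start))
        pts_r = traj.points
        exit_arm_r = traj.exit_name
        q_out_r = traj.q_exit
    else:
        bank = library.get_trajectories(match.record_id, diameter, arm_r)
        usable = [t for t in bank if t.fate in ("exited", "frozen")]
        if not usable:
            raise CoverageError(
                f"record {match.record_id} has no usable releases on arm {arm_r}")
        below = [t for t in usable if t.entry_q <= q_r]
        above = [t for t in usable if t.entry_q >= q_r]
        lo = max(below, key=lambda t: t.entry_q) if below else None
        hi = min(above, key=lambda t: t.entry_q) if above else None
        if lo is None or hi is None:
            pick = hi if lo is None else lo
            note = "outside stored release span; snapped to extreme release"
            exit_arm_r, q_out_r, pts_r = pick.exit_arm, pick.exit_q, pick.points
        elif (lo.fate == hi.fate == "exited" and lo.exit_arm == hi.exit_arm):
            span = hi.entry_q - lo.entry_q
            f = 0.0 if span == 0 else (q_r - lo.entry_q) / span
            q_out_r = lo.exit_q + f * (hi.exit_q - lo.exit_q)
            exit_arm_r = lo.exit_arm
            pts_r = (lo if f <= 0.5 else hi).points
            note = "interpolated between bracketing releases"
        else:
            # bracketing releases disagree (exit arm or fate): snap to nearer,
            # ties toward the smaller entry position for determinism
            d_lo, d_hi = q_r - lo.entry_q, hi.entry_q - q_r
            pick = lo if d_lo <= d_hi else hi
            exit_arm_r, q_out_r, pts_r = pick.exit_arm, pick.exit_q, pick.points
            note = (f"bracketing releases disagree "
                    f"({lo.exit_arm or lo.fate} vs {hi.exit_arm or hi.fate}); "
                    f"snapped to entry_q={pick.entry_q:.3f}")
        if exit_arm_r is None:
            pts_local = np.asarray([T.map_point(p, center) for p in pts_r])
            return None, None, pts_local, match, note or "frozen release"

    pts_local = np.asarray([T.map_point(p, center) for p in pts_r])
    if exit_arm_r is None:
        return None, None, pts_local, match, note or "frozen in intersection"
    return T.map_arm(exit_arm_r), T.map_q(q_out_r), pts_local, match, note


# ---------------------------------------------------------------------------
# Whole-chip simulation


def _check_envelope(netlist: ChipNetlist) -> None:
    for seg in netlist.segments:
        if abs(seg.width - LIBRARY_WIDTH) > 1e-12:
            raise EnvelopeError(
                f"segment {seg.id!r} width {seg.width * 1e6:.0f} um outside the "
                f"library envelope (only {LIBRARY_WIDTH * 1e6:.0f} um channels "
                "are pre-simulated)")
    for tid, bc in netlist.bc_map.items():
        if bc.kind == "velocity" and abs(bc.value) > ENVELOPE_MAX_SPEED * (1 + 1e-9):
            raise EnvelopeError(
                f"terminal {tid!r} drive speed {abs(bc.value) * 100:.2f} cm/s exceeds "
                "the library envelope of 2 cm/s")


def simulate_chip(
    netlist: ChipNetlist,
    particles,
    library: IntersectionLibrary,
    mode: str = "A",
    solution: FlowSolution | None = None,
) -> SimulationReport:
    """Instantaneous chip simulation: network solve + library stitching.

    ``particles`` is an iterable of :class:`ParticleRelease`.  For each one:
    solve the resistor network once, convert the release into an entry flow
    fraction, then alternate channel propagation (constant ``q``) and
    intersection traversal (library retrieval) until the particle reaches a
    terminal or freezes.  Deterministic for identical inputs.
    """
    t0 = time.perf_counter()
    _check_envelope(netlist)
    sol = solution or solve_network(netlist)
    node_map = netlist.node_map
    seg_map = netlist.segment_map
    specs = {n.id: intersection_spec(sol, n.id) for n in netlist.intersections()}

    trajectories = []
    max_dist = 0.0
    for rel in particles:
        term = node_map.get(rel.terminal)
        if term is None or term.kind != "terminal":
            raise KeyError(f"no terminal named {rel.terminal!r}")
        seg = netlist.segments_at(rel.terminal)[0]
        if rel.diameter >= seg.width:
            raise EnvelopeError("particle does not fit in the entry channel")
        q = rel.q
        visits: list[IntersectionVisit] = []
        channel_q: list[tuple[str, float]] = []
        pieces: list[np.ndarray] = []
        from_node = rel.terminal
        fate, exit_terminal, q_exit = None, None, None

        # flow must enter at the release terminal
        if sol.flow_into(rel.terminal, seg) > 0:
            raise EnvelopeError(
                f"terminal {rel.terminal!r} is an outlet; cannot release there")

        while fate is None:
            to_node = seg.nodes[1] if seg.nodes[0] == from_node else seg.nodes[0]
            nd = node_map[to_node]
            trim_s = LIBRARY_ARM_REACH if node_map[from_node].kind == "intersection" else 0.0
            trim_e = LIBRARY_ARM_REACH if nd.kind == "intersection" else 0.0
            q, poly = propagate_channel(q, seg, from_node, trim_s, trim_e)
            channel_q.append((seg.id, q))
            pieces.append(poly)
            if nd.kind == "terminal":
                fate, exit_terminal, q_exit = "exited", to_node, q
            elif nd.kind == "turn":
                nxt = [s for s in netlist.segments_at(to_node) if s.id != seg.id][0]
                seg, from_node = nxt, to_node
            else:
                entry_arm = next(a for a, sid in nd.arms if sid == seg.id)
                ispec = specs[to_node]
                exit_arm, q_out, local, match, note = traverse_intersection(
                    q, entry_arm, ispec, library, rel.diameter, mode)
                max_dist = max(max_dist, match.distance)
                visits.append(IntersectionVisit(
                    intersection_id=to_node, record_id=match.record_id,
                    distance=match.distance, mode=mode, entry_arm=entry_arm,
                    exit_arm=exit_arm, q_in=q, q_out=q_out, note=note))
                center = (ispec.footprint / 2.0, ispec.footprint / 2.0)
                shift = (np.asarray(nd.position) - np.asarray(center))
                pieces.append(local + shift)
                if exit_arm is None:
                    fate = "frozen"
                else:
                    q = q_out
                    seg = seg_map[nd.arm_map[exit_arm]]
                    from_node = to_node

        kept = [p for p in pieces if len(p)]
        pts = np.vstack(kept)
        breaks = tuple(np.cumsum([len(p) for p in kept[:-1]]))
        trajectories.append(ChipTrajectory(
            release=rel, points=pts, fate=fate,
            exit_terminal=exit_terminal, q_exit=q_exit,
            visits=visits, channel_q=channel_q, piece_breaks=breaks))

    return SimulationReport(
        trajectories=trajectories,
        solution=sol,
        wall_clock=time.perf_counter() - t0,
        max_match_distance=max_dist,
        provenance={"mode": mode, "n_particles": len(trajectories),
                    "library_records": len(library)},
    )


# ---------------------------------------------------------------------------
# Validation against direct whole-chip simulation


def compare_with_direct(
    netlist: ChipNetlist,
    particles,
    library: IntersectionLibrary,
    spacing: float,
    mode: str = "A",
) -> pd.DataFrame:
    """Decomposed-vs-direct discrepancy table.

    Runs :func:`simulate_chip` and, independently, traces the same particles
    on a direct whole-chip viscous-flow solve at the given grid spacing; the
    table reports each particle's lateral exit position under both methods
    and their absolute difference (``discrepancy_m``).
    """
    particles = list(particles)
    rep = simulate_chip(netlist, particles, library, mode=mode)
    fld = solve_full_chip(netlist, spacing)
    dom = fld.domain
    rows = []
    for rel, traj in zip(particles, rep.trajectories):
        entry = dom.mouths[rel.terminal]
        start = entry.point_at(inverse_flow_fraction(rel.q, entry.width), "in")
        direct = trace_particle(fld, ParticleSpec(rel.diameter, start))
        t_direct = (None if direct.exit_name is None else
                    dom.mouths[direct.exit_name].coord_of(direct.points[-1], "out"))
        t_dec = (None if traj.q_exit is None else
                 inverse_flow_fraction(traj.q_exit,
                                       dom.mouths[traj.exit_terminal].width))
        rows.append({
            "terminal_in": rel.terminal,
            "q_in": rel.q,
            "diameter_m": rel.diameter,
            "exit_decomposed": traj.exit_terminal,
            "exit_direct": direct.exit_name,
            "lateral_decomposed_m": t_dec,
            "lateral_direct_m": t_direct,
            "discrepancy_m": (abs(t_dec - t_direct)
                              if None not in (t_dec, t_direct)
                              and traj.exit_terminal == direct.exit_name else np.nan),
        })
    return pd.DataFrame(rows)
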