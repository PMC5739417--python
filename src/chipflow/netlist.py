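"""Chip netlists: the user-supplied decomposition of a microfluidic chip.

A chip is described as a planar graph of *nodes* (terminals, turns and
channel intersections) joined by rectangular *channel segments*.  This is the
input format of the whole package: the network solver computes flows on the
graph, the Stokes solver rasterizes it, and the chip simulator stitches
particle paths along it.

Conventions
-----------
* The chip plane is x-y, SI meters; y increases northward.  Intersection arms
  are named by the compass direction (``N``, ``E``, ``S``, ``W``) of the
  channel leaving the intersection center.
* Three-arm (T) intersections are four-arm intersections with one arm absent;
  the absent arm behaves as a 0 m/s inlet.
* Boundary conditions are given per terminal, either as an absolute pressure
  (Pa) or a mean velocity (m/s, positive into the chip).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

ARMS = ("N", "E", "S", "W")
ARM_DIR = {
    "N": (0.0, 1.0),
    "E": (1.0, 0.0),
    "S": (0.0, -1.0),
    "W": (-1.0, 0.0),
}

#: Channel width of the pre-simulated intersection library (m).
LIBRARY_WIDTH = 200e-6
#: Side length of the unit-intersection footprint (m).
LIBRARY_FOOTPRINT = 1.6e-3
#: Half-footprint: how far an intersection extends along each arm (m).
LIBRARY_ARM_REACH = LIBRARY_FOOTPRINT / 2.0

_UNIT_SCALES = {"m": 1.0, "mm": 1e-3, "um": 1e-6}


class NetlistError(ValueError):
    """Base class for netlist problems."""


class SchemaError(NetlistError):
    """The file does not conform to the netlist JSON schema."""


class ValidationError(NetlistError):
    """The netlist is well-formed but semantically invalid."""


@dataclass(frozen=True)
class FluidProps:
    """Newtonian fluid properties.

    Defaults are water at room temperature, the working fluid of the
    pre-simulated library.
    """

    viscosity: float = 1.0e-3  # dynamic viscosity, Pa*s
    density: float = 998.0  # kg/m^3

    def __post_init__(self) -> None:
        if not (self.viscosity > 0 and self.density > 0):
            raise ValidationError("fluid viscosity and density must be positive")


@dataclass(frozen=True)
class ChannelSegment:
    """A rectangular-cross-section channel between two nodes.

    ``waypoints`` is the full centerline polyline, starting at the position of
    ``nodes[0]`` and ending at ``nodes[1]``.  Interior waypoints encode 90
    degree turns; every leg must be axis-aligned.
    """

    id: str
    nodes: tuple[str, str]
    width: float
    height: float
    waypoints: tuple[tuple[float, float], ...]

    @property
    def length(self) -> float:
        """Centerline length (m), summed over legs."""
        pts = np.asarray(self.waypoints)
        return float(np.sum(np.hypot(*(pts[1:] - pts[:-1]).T)))

    def legs(self) -> list[tuple[tuple[float, float], tuple[float, float]]]:
        return [
            (tuple(self.waypoints[i]), tuple(self.waypoints[i + 1]))
            for i in range(len(self.waypoints) - 1)
        ]


@dataclass(frozen=True)
class NodeSpec:
    """A terminal (degree 1), turn/joint (degree 2) or intersection (3-4)."""

    id: str
    kind: str  # "terminal" | "turn" | "intersection"
    position: tuple[float, float]
    arms: tuple[tuple[str, str], ...] = ()  # (arm letter, segment id), intersections only

    @property
    def arm_map(self) -> dict[str, str]:
        return dict(self.arms)


@dataclass(frozen=True)
class BoundaryCondition:
    """Terminal boundary condition.

    ``kind`` is ``"pressure"`` (value in Pa) or ``"velocity"`` (mean velocity
    in m/s, positive for flow *into* the chip).
    """

    kind: str
    value: float


@dataclass(frozen=True)
class ChipNetlist:
    nodes: tuple[NodeSpec, ...]
    segments: tuple[ChannelSegment, ...]
    fluid: FluidProps = FluidProps()
    boundary_conditions: tuple[tuple[str, BoundaryCondition], ...] = ()

    # -- lookups -----------------------------------------------------------
    @property
    def node_map(self) -> dict[str, NodeSpec]:
        return {n.id: n for n in self.nodes}

    @property
    def segment_map(self) -> dict[str, ChannelSegment]:
        return {s.id: s for s in self.segments}

    @property
    def bc_map(self) -> dict[str, BoundaryCondition]:
        return dict(self.boundary_conditions)

    def terminals(self) -> list[NodeSpec]:
        return [n for n in self.nodes if n.kind == "terminal"]

    def intersections(self) -> list[NodeSpec]:
        return [n for n in self.nodes if n.kind == "intersection"]

    def segments_at(self, node_id: str) -> list[ChannelSegment]:
        return [s for s in self.segments if node_id in s.nodes]

    def n_units(self) -> int:
        """Number of decomposition units: channel segments + intersections."""
        return len(self.segments) + len(self.intersections())

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ValidationError` if any structural invariant fails."""
        node_map = self.node_map
        if len(node_map) != len(self.nodes):
            raise ValidationError("duplicate node ids")
        if len(self.segment_map) != len(self.segments):
            raise ValidationError("duplicate segment ids")

        for seg in self.segments:
            if not (seg.width > 0 and seg.height > 0):
                raise ValidationError(f"segment {seg.id!r}: width/height must be positive")
            for nid in seg.nodes:
                if nid not in node_map:
                    raise ValidationError(f"segment {seg.id!r}: unknown endpoint {nid!r}")
            if len(seg.waypoints) < 2:
                raise ValidationError(f"segment {seg.id!r}: needs at least two waypoints")
            _check_polyline(seg)
            for end, nid in zip((seg.waypoints[0], seg.waypoints[-1]), seg.nodes):
                pos = node_map[nid].position
                if math.hypot(end[0] - pos[0], end[1] - pos[1]) > 1e-12:
                    raise ValidationError(
                        f"segment {seg.id!r}: waypoint {end} does not touch node {nid!r}"
                    )

        degree = {nid: 0 for nid in node_map}
        for seg in self.segments:
            for nid in seg.nodes:
                degree[nid] += 1
        for node in self.nodes:
            want = {"terminal": (1,), "turn": (2,), "intersection": (3, 4)}.get(node.kind)
            if want is None:
                raise ValidationError(f"node {node.id!r}: unknown kind {node.kind!r}")
            if degree[node.id] not in want:
                raise ValidationError(
                    f"node {node.id!r} ({node.kind}): has {degree[node.id]} attached "
                    f"segments, expected one of {want}"
                )
            if node.kind == "intersection":
                self._validate_arms(node)

        self._validate_connected()
        self._validate_bcs()

    def _validate_arms(self, node: NodeSpec) -> None:
        arm_map = node.arm_map
        if len(arm_map) != len(node.arms):
            raise ValidationError(f"intersection {node.id!r}: duplicate arm letters")
        attached = {s.id for s in self.segments_at(node.id)}
        if set(arm_map.values()) != attached or len(set(arm_map.values())) != len(arm_map):
            raise ValidationError(
                f"intersection {node.id!r}: arms {sorted(arm_map.values())} must map "
                f"one-to-one onto attached segments {sorted(attached)}"
            )
        seg_map = self.segment_map
        for arm, seg_id in arm_map.items():
            if arm not in ARMS:
                raise ValidationError(
                    f"intersection {node.id!r}: arm {arm!r} is not one of {ARMS}"
                )
            d = _leg_direction_from(seg_map[seg_id], node)
            if d != ARM_DIR[arm]:
                raise ValidationError(
                    f"intersection {node.id!r}: segment {seg_id!r} leaves toward {d}, "
                    f"not along arm {arm!r}"
                )

    def _validate_connected(self) -> None:
        if not self.nodes:
            raise ValidationError("empty netlist")
        adj: dict[str, set[str]] = {n.id: set() for n in self.nodes}
        for seg in self.segments:
            a, b = seg.nodes
            adj[a].add(b)
            adj[b].add(a)
        seen = {self.nodes[0].id}
        stack = [self.nodes[0].id]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if len(seen) != len(self.nodes):
            missing = sorted(set(adj) - seen)
            raise ValidationError(f"netlist graph is disconnected; unreachable: {missing}")

    def _validate_bcs(self) -> None:
        bcs = self.bc_map
        term_ids = {t.id for t in self.terminals()}
        for tid, bc in bcs.items():
            if tid not in term_ids:
                raise ValidationError(f"boundary condition on non-terminal node {tid!r}")
            if bc.kind not in ("pressure", "velocity"):
                raise ValidationError(f"terminal {tid!r}: unknown BC kind {bc.kind!r}")
        missing = term_ids - set(bcs)
        if missing:
            raise ValidationError(f"terminals without boundary conditions: {sorted(missing)}")
        if not any(bc.kind == "pressure" for bc in bcs.values()):
            # velocity-only drive: fluxes must balance for the network to be solvable
            net = 0.0
            tot = 0.0
            for tid, bc in bcs.items():
                seg = self.segments_at(tid)[0]
                q = bc.value * seg.width * seg.height
                net += q
                tot += abs(q)
            if tot == 0.0 or abs(net) > 1e-9 * tot:
                raise ValidationError(
                    "no pressure reference terminal and velocity sources do not balance"
                )

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "units": "m",
            "fluid": {"viscosity": self.fluid.viscosity, "density": self.fluid.density},
            "nodes": [
                {
                    "id": n.id,
                    "kind": n.kind,
                    "position": list(n.position),
                    **({"arms": {a: s for a, s in n.arms}} if n.arms else {}),
                }
                for n in self.nodes
            ],
            "segments": [
                {
                    "id": s.id,
                    "nodes": list(s.nodes),
                    "width": s.width,
                    "height": s.height,
                    "waypoints": [list(p) for p in s.waypoints],
                }
                for s in self.segments
            ],
            "boundary_conditions": {
                tid: {"kind": bc.kind, "value": bc.value}
                for tid, bc in self.boundary_conditions
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ChipNetlist":
        try:
            scale = _UNIT_SCALES[data.get("units", "m")]
        except KeyError:
            raise SchemaError(f"unknown 'units' value {data.get('units')!r}") from None
        for key in ("nodes", "segments"):
            if key not in data:
                raise SchemaError(f"missing top-level key {key!r}")
        fl = data.get("fluid", {})
        fluid = FluidProps(
            viscosity=float(fl.get("viscosity", 1.0e-3)),
            density=float(fl.get("density", 998.0)),
        )
        nodes = []
        for nd in data["nodes"]:
            try:
                nodes.append(
                    NodeSpec(
                        id=str(nd["id"]),
                        kind=str(nd["kind"]),
                        position=(scale * float(nd["position"][0]),
                                  scale * float(nd["position"][1])),
                        arms=tuple(sorted((str(a), str(s))
                                          for a, s in nd.get("arms", {}).items())),
                    )
                )
            except (KeyError, IndexError, TypeError) as exc:
                raise SchemaError(f"malformed node entry {nd!r}: missing {exc}") from None
        segments = []
        for sd in data["segments"]:
            try:
                segments.append(
                    ChannelSegment(
                        id=str(sd["id"]),
                        nodes=(str(sd["nodes"][0]), str(sd["nodes"][1])),
                        width=scale * float(sd["width"]),
                        height=scale * float(sd["height"]),
                        waypoints=tuple(
                            (scale * float(p[0]), scale * float(p[1]))
                            for p in sd["waypoints"]
                        ),
                    )
                )
            except (KeyError, IndexError, TypeError) as exc:
                raise SchemaError(f"malformed segment entry {sd!r}: missing {exc}") from None
        bcs = []
        for tid, bd in data.get("boundary_conditions", {}).items():
            try:
                bcs.append((str(tid), BoundaryCondition(str(bd["kind"]), float(bd["value"]))))
            except (KeyError, TypeError) as exc:
                raise SchemaError(
                    f"malformed boundary condition for {tid!r}: missing {exc}"
                ) from None
        net = cls(
            nodes=tuple(nodes),
            segments=tuple(segments),
            fluid=fluid,
            boundary_conditions=tuple(sorted(bcs)),
        )
        return net


def _check_polyline(seg: ChannelSegment) -> None:
    prev = None
    for (p, q) in seg.legs():
        dx, dy = q[0] - p[0], q[1] - p[1]
        if (dx != 0.0) == (dy != 0.0):  # diagonal or zero-length
            raise ValidationError(
                f"segment {seg.id!r}: leg {p}->{q} is not axis-aligned and nonzero"
            )
        d = (np.sign(dx), np.sign(dy))
        if prev is not None and abs(prev[0] * d[0] + prev[1] * d[1]) > 0.5:
            raise ValidationError(
                f"segment {seg.id!r}: consecutive legs must meet at 90 degrees"
            )
        prev = d


def _leg_direction_from(seg: ChannelSegment, node: NodeSpec) -> tuple[float, float]:
    """Unit direction of the segment's first leg leaving ``node``."""
    if seg.nodes[0] == node.id:
        p, q = seg.waypoints[0], seg.waypoints[1]
    else:
        p, q = seg.waypoints[-1], seg.waypoints[-2]
    dx, dy = q[0] - p[0], q[1] - p[1]
    n = math.hypot(dx, dy)
    return (round(dx / n), round(dy / n))


def arm_of_segment(netlist: ChipNetlist, node_id: str, seg_id: str) -> str:
    """The compass arm under which ``seg_id`` attaches to intersection ``node_id``."""
    node = netlist.node_map[node_id]
    for arm, sid in node.arms:
        if sid == seg_id:
            return arm
    raise KeyError(f"segment {seg_id!r} is not an arm of intersection {node_id!r}")


# ---------------------------------------------------------------------------
# I/O


def load_netlist(path) -> ChipNetlist:
    """Read and validate a netlist JSON file.

    Lengths are converted to SI meters according to the file's ``units`` key
    (``m``, ``mm`` or ``um``); velocities are always m/s and pressures Pa.
    """
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"not valid JSON: {exc}") from None
    if not isinstance(data, dict):
        raise SchemaError("top level must be a JSON object")
    net = ChipNetlist.from_dict(data)
    net.validate()
    return net


def save_netlist(netlist: ChipNetlist, path) -> None:
    """Write a netlist as JSON (SI meters)."""
    with open(path, "w") as fh:
        json.dump(netlist.to_dict(), fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Programmatic fixtures


def _straight(a: tuple[float, float], b: tuple[float, float]):
    return (a, b)


def make_h_chip(
    arm_length: float = 1.2e-3,
    w: float = LIBRARY_WIDTH,
    h: float = 100e-6,
    crossbar_leg: float = 0.8e-3,
    inflow_north: float = 0.01,
    inflow_south: float = 0.02,
    fluid: FluidProps = FluidProps(),
) -> ChipNetlist:
    """The basic "H" chip: two T-intersections joined by a crossbar.

    The left intersection ``b`` receives flow from the top (``inflow_north``,
    default 1 cm/s) and bottom (``inflow_south``, default 2 cm/s) terminals
    and sends it east along the crossbar; the mirror-image intersection ``h``
    splits it toward the two right-hand terminals (pressure outlets).  The
    crossbar is subdivided into three collinear segments (joined at plain
    degree-2 nodes), so the decomposition has 7 channel units and 2
    intersection units.
    """
    if not (arm_length > 0 and w > 0 and h > 0 and crossbar_leg > 0):
        raise ValidationError("all dimensions must be positive")
    L = arm_length
    cl = crossbar_leg
    xb, xh = 0.0, 3 * cl
    pos = {
        "b": (xb, 0.0),
        "h": (xh, 0.0),
        "j1": (cl, 0.0),
        "j2": (2 * cl, 0.0),
        "TNW": (xb, L),
        "TSW": (xb, -L),
        "TNE": (xh, L),
        "TSE": (xh, -L),
    }

    def seg(sid, na, nb):
        return ChannelSegment(sid, (na, nb), w, h, _straight(pos[na], pos[nb]))

    segments = (
        seg("a", "TNW", "b"),
        seg("c", "TSW", "b"),
        seg("d", "b", "j1"),
        seg("e", "j1", "j2"),
        seg("f", "j2", "h"),
        seg("g", "h", "TNE"),
        seg("i", "h", "TSE"),
    )
    nodes = (
        NodeSpec("b", "intersection", pos["b"],
                 arms=(("E", "d"), ("N", "a"), ("S", "c"))),
        NodeSpec("h", "intersection", pos["h"],
                 arms=(("N", "g"), ("S", "i"), ("W", "f"))),
        NodeSpec("j1", "turn", pos["j1"]),
        NodeSpec("j2", "turn", pos["j2"]),
        NodeSpec("TNW", "terminal", pos["TNW"]),
        NodeSpec("TSW", "terminal", pos["TSW"]),
        NodeSpec("TNE", "terminal", pos["TNE"]),
        NodeSpec("TSE", "terminal", pos["TSE"]),
    )
    bcs = (
        ("TNE", BoundaryCondition("pressure", 0.0)),
        ("TNW", BoundaryCondition("velocity", inflow_north)),
        ("TSE", BoundaryCondition("pressure", 0.0)),
        ("TSW", BoundaryCondition("velocity", inflow_south)),
    )
    net = ChipNetlist(nodes=nodes, segments=segments, fluid=fluid,
                      boundary_conditions=bcs)
    net.validate()
    return net


def make_cascade_chip(
    n_inlets: int = 3,
    n_outlets: int = 2,
    seg_length: float = 1.6e-3,
    terminal_length: float = 1.0e-3,
    w: float = LIBRARY_WIDTH,
    h: float = 100e-6,
    inflow: float = 3.5e-3,
    outflow: float = 3.0e-3,
    fluid: FluidProps = FluidProps(),
) -> ChipNetlist:
    """A cascade of T-intersections along a vertical main channel.

    The topmost intersection ``a`` has West and East inlet terminals; each
    further inlet adds a T with an East inlet, each outlet beyond the final
    South terminal adds a T with an East outlet.  With the defaults (3 inlets,
    2 outlets) this is the three-intersection sorter layout with inflows of
    3.5 mm/s at every inlet, a specified 3 mm/s East outlet and a pressure
    reference at the final South terminal.
    """
    if n_inlets < 2 or n_outlets < 1:
        raise ValidationError("need n_inlets >= 2 and n_outlets >= 1")
    n_x = 1 + (n_inlets - 2) + (n_outlets - 1)
    names = [chr(ord("a") + i) for i in range(n_x)]
    nodes: list[NodeSpec] = []
    segments: list[ChannelSegment] = []
    bcs: list[tuple[str, BoundaryCondition]] = []

    def xpos(i):
        return (0.0, -i * seg_length)

    for i, nm in enumerate(names):
        px = xpos(i)
        arms: list[tuple[str, str]] = []
        if i == 0:
            for arm, sgn in (("W", -1.0), ("E", 1.0)):
                tid, sid = f"T{nm}{arm}", f"S{nm}{arm}"
                tp = (px[0] + sgn * terminal_length, px[1])
                nodes.append(NodeSpec(tid, "terminal", tp))
                segments.append(ChannelSegment(sid, (tid, nm), w, h, _straight(tp, px)))
                bcs.append((tid, BoundaryCondition("velocity", inflow)))
                arms.append((arm, sid))
        else:
            # main-channel link from the previous intersection
            sid = f"M{names[i - 1]}{nm}"
            segments.append(
                ChannelSegment(sid, (names[i - 1], nm), w, h,
                               _straight(xpos(i - 1), px))
            )
            arms.append(("N", sid))
            is_inlet = i <= n_inlets - 2
            tid, side = f"T{nm}E", f"S{nm}E"
            tp = (px[0] + terminal_length, px[1])
            nodes.append(NodeSpec(tid, "terminal", tp))
            segments.append(ChannelSegment(side, (tid, nm), w, h, _straight(tp, px)))
            bcs.append((tid, BoundaryCondition(
                "velocity", inflow if is_inlet else -outflow)))
            arms.append(("E", side))
        if i < n_x - 1:
            arms.append(("S", f"M{nm}{names[i + 1]}"))
        else:
            tid, sid = f"T{nm}S", f"S{nm}S"
            tp = (px[0], px[1] - terminal_length)
            nodes.append(NodeSpec(tid, "terminal", tp))
            segments.append(ChannelSegment(sid, (tid, nm), w, h, _straight(tp, px)))
            bcs.append((tid, BoundaryCondition("pressure", 0.0)))
            arms.append(("S", sid))
        nodes.append(NodeSpec(nm, "intersection", px, arms=tuple(sorted(arms))))

    net = ChipNetlist(
        nodes=tuple(nodes), segments=tuple(segments), fluid=fluid,
        boundary_conditions=tuple(sorted(bcs)),
    )
    net.validate()
    return net


def make_random_grid_chip(
    seed: int,
    rows: int = 3,
    cols: int = 3,
    pitch: float = 1.6e-3,
    w: float = LIBRARY_WIDTH,
    h: float = 100e-6,
    extra_edge_prob: float = 0.35,
    fluid: FluidProps = FluidProps(),
) -> ChipNetlist:
    """A random connected grid chip (simplified random-design stand-in).

    Nodes sit on a ``rows`` x ``cols`` lattice; a random spanning tree keeps
    the chip connected and further lattice edges are retained with probability
    ``extra_edge_prob``.  Degree-1 nodes become terminals (the first gets a
    0 Pa pressure reference, the rest random pressure or inflow boundary
    conditions), degree-2 nodes turns, higher degrees intersections.
    Deterministic for a fixed seed.
    """
    if rows < 2 or cols < 2:
        raise ValidationError("need rows, cols >= 2")
    rng = np.random.default_rng(seed)
    ids = {(r, c): f"n{r}_{c}" for r in range(rows) for c in range(cols)}
    pos = {(r, c): (c * pitch, -r * pitch) for r in range(rows) for c in range(cols)}
    edges = []
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                edges.append(((r, c), (r, c + 1)))
            if r + 1 < rows:
                edges.append(((r, c), (r + 1, c)))
    order = rng.permutation(len(edges))
    parent = {k: k for k in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree = []
    extras = []
    for i in order:
        a, b = edges[i]
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            tree.append(edges[i])
        elif rng.random() < extra_edge_prob:
            extras.append(edges[i])
    # keep at least two tree leaves untouched so the chip has terminals
    tdeg = {k: 0 for k in ids}
    for a, b in tree:
        tdeg[a] += 1
        tdeg[b] += 1
    protected = set(sorted(k for k in ids if tdeg[k] == 1)[:2])
    keep = tree + [e for e in extras if not (set(e) & protected)]
    keep.sort()

    degree = {k: 0 for k in ids}
    for a, b in keep:
        degree[a] += 1
        degree[b] += 1
    used = {k for k in ids if degree[k] > 0}

    segments = []
    for a, b in keep:
        segments.append(
            ChannelSegment(f"e_{ids[a]}_{ids[b]}", (ids[a], ids[b]), w, h,
                           _straight(pos[a], pos[b]))
        )
    nodes = []
    arm_of = {(0, 1): "E", (0, -1): "W", (1, 0): "S", (-1, 0): "N"}
    for k in sorted(used):
        deg = degree[k]
        kind = "terminal" if deg == 1 else ("turn" if deg == 2 else "intersection")
        arms: tuple[tuple[str, str], ...] = ()
        if kind == "intersection":
            lst = []
            for a, b in keep:
                if k in (a, b):
                    other = b if a == k else a
                    d = (other[0] - k[0], other[1] - k[1])
                    lst.append((arm_of[d], f"e_{ids[a]}_{ids[b]}"))
            arms = tuple(sorted(lst))
        nodes.append(NodeSpec(ids[k], kind, pos[k], arms=arms))

    terms = [n for n in nodes if n.kind == "terminal"]
    bcs = []
    for i, t in enumerate(sorted(terms, key=lambda n: n.id)):
        if i == 0:
            bcs.append((t.id, BoundaryCondition("pressure", 0.0)))
        elif rng.random() < 0.5:
            bcs.append((t.id, BoundaryCondition("pressure", float(rng.uniform(1.0, 10.0)))))
        else:
            bcs.append((t.id, BoundaryCondition("velocity", float(rng.uniform(1e-3, 5e-3)))))

    net = ChipNetlist(
        nodes=tuple(nodes), segments=tuple(segments), fluid=fluid,
        boundary_conditions=tuple(sorted(bcs)),
    )
    net.validate()
    return net
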