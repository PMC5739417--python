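"""Hydraulic network solver: the electrical-circuit analogy for channel flow.

Channels behave like resistors: the volumetric flow ``Q`` through a channel
equals the pressure drop divided by the hydraulic resistance (the fluidic
Ohm's law), resistances add in series, and reciprocals add in parallel.  For
a rectangular channel of length ``L``, width ``w`` and height ``h`` filled
with fluid of viscosity ``eta``::

    Rh = 12 * eta * L / (w * h**3 * F)

where ``F`` is the dimensionless rectangular-duct form factor.  Flow rates
and pressures over a whole chip follow from nodal analysis with the fluidic
analogs of Kirchhoff's laws: signed flows sum to zero at every node, and
pressure drops sum to zero around every loop (identically, since we solve
for a single-valued pressure potential).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .netlist import ARMS, ChannelSegment, ChipNetlist, FluidProps, NetlistError


class SolvabilityError(NetlistError):
    """The network has no unique flow solution."""


def form_factor(h: float, w: float, n_max: int = 99) -> float:
    """Rectangular-duct geometric form factor ``F`` in ``(0, 1]``.

    Standard series solution for pressure-driven flow in a rectangular duct,

        F = 1 - (192/pi^5) (a/b) sum_{n odd} n^-5 tanh(n pi b / (2 a)),

    evaluated with ``a = min(h, w)`` and ``b = max(h, w)`` so the series is
    in its convergent regime.  Truncation at ``n_max = 99`` changes the
    result by less than 2e-9.  ``F -> 1`` in the parallel-plate limit
    ``h/w -> 0`` and ``F ~ 0.4217`` for a square duct.
    """
    if not (h > 0 and w > 0):
        raise ValueError("h and w must be positive")
    a, b = (h, w) if h <= w else (w, h)
    n = np.arange(1, n_max + 1, 2, dtype=float)
    s = np.sum(np.tanh(n * math.pi * b / (2 * a)) / n**5)
    return float(1.0 - (192.0 / math.pi**5) * (a / b) * s)


def hydraulic_resistance(seg: ChannelSegment, fluid: FluidProps) -> float:
    """Hydraulic resistance of a rectangular channel, Pa*s/m^3.

    Uses the shorter cross-section side as the "height" of the duct formula,
    which keeps the result invariant under swapping width and height (the
    physics does not care which side is called which).
    """
    a, b = sorted((seg.height, seg.width))  # a = short side
    F = form_factor(a, b)
    return 12.0 * fluid.viscosity * seg.length / (b * a**3 * F)


def series_resistance(values) -> float:
    """Equivalent resistance of resistances in series (their sum)."""
    values = list(values)
    if not values:
        raise ValueError("series_resistance of an empty list")
    if any(v <= 0 for v in values):
        raise ValueError("resistances must be positive")
    return float(sum(values))


def parallel_resistance(values) -> float:
    """Equivalent resistance of resistances in parallel."""
    values = list(values)
    if not values:
        raise ValueError("parallel_resistance of an empty list")
    if any(v <= 0 for v in values):
        raise ValueError("resistances must be positive")
    return float(1.0 / sum(1.0 / v for v in values))


@dataclass(frozen=True)
class FlowSolution:
    """Pressures, flows and intersection boundary conditions for one chip.

    ``segment_flow[sid]`` is the signed volumetric flow (m^3/s) in the
    direction from ``segment.nodes[0]`` to ``nodes[1]``;
    ``segment_velocity`` the corresponding mean velocity Q/(w*h).
    """

    netlist: ChipNetlist
    node_pressure: dict[str, float]
    segment_flow: dict[str, float]
    segment_velocity: dict[str, float]

    def flow_into(self, node_id: str, seg: ChannelSegment) -> float:
        """Signed flow (m^3/s) through ``seg`` toward ``node_id``."""
        q = self.segment_flow[seg.id]
        return q if seg.nodes[1] == node_id else -q

    def kcl_residual(self) -> float:
        """Max node flow imbalance relative to the largest segment flow."""
        qmax = max((abs(q) for q in self.segment_flow.values()), default=0.0)
        if qmax == 0.0:
            return 0.0
        worst = 0.0
        bcs = self.netlist.bc_map
        for node in self.netlist.nodes:
            if node.kind == "terminal" and bcs[node.id].kind == "pressure":
                continue  # terminals exchange flow with the outside
            net = sum(self.flow_into(node.id, s)
                      for s in self.netlist.segments_at(node.id))
            if node.kind == "terminal":  # velocity-driven source
                seg = self.netlist.segments_at(node.id)[0]
                net += bcs[node.id].value * seg.width * seg.height
            worst = max(worst, abs(net))
        return worst / qmax

    def arm_velocities(self, intersection_id: str) -> dict[str, float]:
        """Signed mean arm velocities (m/s, positive *into* the intersection).

        Arms absent from a T-intersection report exactly 0.
        """
        node = self.netlist.node_map.get(intersection_id)
        if node is None or node.kind != "intersection":
            raise KeyError(f"no intersection named {intersection_id!r}")
        seg_map = self.netlist.segment_map
        out = {arm: 0.0 for arm in ARMS}
        for arm, sid in node.arms:
            seg = seg_map[sid]
            out[arm] = self.flow_into(intersection_id, seg) / (seg.width * seg.height)
        return out


def solve_network(netlist: ChipNetlist) -> FlowSolution:
    """Nodal analysis of the chip's hydraulic resistor network.

    Pressure-specified terminals are Dirichlet nodes; velocity-specified
    terminals inject ``Q = u * w * h`` as flow sources.  If no pressure
    reference exists, the (balanced) sources determine flows up to a pressure
    offset and the first node is pinned to 0 Pa.
    """
    netlist.validate()
    bcs = netlist.bc_map
    node_ids = [n.id for n in netlist.nodes]
    fixed = {
        tid: bc.value for tid, bc in bcs.items() if bc.kind == "pressure"
    }
    unknown = [nid for nid in node_ids if nid not in fixed]
    pinned = None
    if not fixed:
        pinned = unknown[0]
        fixed = {pinned: 0.0}
        unknown = unknown[1:]
    idx = {nid: i for i, nid in enumerate(unknown)}

    n = len(unknown)
    rows, cols, vals = [], [], []
    rhs = np.zeros(n)
    conduct = {}
    for seg in netlist.segments:
        conduct[seg.id] = 1.0 / hydraulic_resistance(seg, netlist.fluid)
        a, b = seg.nodes
        g = conduct[seg.id]
        for p, q in ((a, b), (b, a)):
            if p in idx:
                rows.append(idx[p]); cols.append(idx[p]); vals.append(g)
                if q in idx:
                    rows.append(idx[p]); cols.append(idx[q]); vals.append(-g)
                else:
                    rhs[idx[p]] += g * fixed[q]
    for tid, bc in bcs.items():
        if bc.kind == "velocity" and tid in idx:
            seg = netlist.segments_at(tid)[0]
            rhs[idx[tid]] += bc.value * seg.width * seg.height

    pressures = dict(fixed)
    if n:
        G = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        try:
            p = spla.spsolve(G.tocsc(), rhs)
        except RuntimeError as exc:  # pragma: no cover - scipy failure path
            raise SolvabilityError(f"sparse solve failed: {exc}") from None
        if not np.all(np.isfinite(p)):
            bad = [unknown[i] for i in np.nonzero(~np.isfinite(p))[0][:5]]
            raise SolvabilityError(
                f"singular network (no pressure reference reaches nodes {bad})"
            )
        pressures.update({nid: float(p[idx[nid]]) for nid in unknown})

    seg_flow = {}
    seg_vel = {}
    for seg in netlist.segments:
        a, b = seg.nodes
        q = conduct[seg.id] * (pressures[a] - pressures[b])
        seg_flow[seg.id] = q
        seg_vel[seg.id] = q / (seg.width * seg.height)
    return FlowSolution(
        netlist=netlist,
        node_pressure=pressures,
        segment_flow=seg_flow,
        segment_velocity=seg_vel,
    )


def arm_boundary_conditions(sol: FlowSolution, intersection_id: str) -> dict[str, float]:
    """Per-arm signed mean velocities of one intersection (m/s, + = inflow)."""
    return sol.arm_velocities(intersection_id)
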