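"""Circuit-analogy solver: form factor, resistances, nodal analysis."""

import math

import numpy as np
import pytest

from chipflow import (
    BoundaryCondition,
    ChannelSegment,
    ChipNetlist,
    FluidProps,
    NodeSpec,
    arm_boundary_conditions,
    form_factor,
    hydraulic_resistance,
    make_h_chip,
    make_random_grid_chip,
    parallel_resistance,
    series_resistance,
    solve_network,
)
from chipflow.network import SolvabilityError


def form_factor_oracle(h, w, n_max=9999):
    """Independent long-series evaluation of the rectangular-duct factor."""
    a, b = min(h, w), max(h, w)
    s = sum(math.tanh(n * math.pi * b / (2 * a)) / n**5
            for n in range(1, n_max + 1, 2))
    return 1.0 - (192.0 / math.pi**5) * (a / b) * s


def test_form_factor_matches_long_series_oracle():
    for h, w in [(1.0, 1.0), (1e-4, 2e-4), (5e-5, 2e-4), (1e-5, 2e-4)]:
        assert form_factor(h, w) == pytest.approx(form_factor_oracle(h, w), abs=1e-8)
    assert form_factor(1.0, 1.0) == pytest.approx(0.4217, abs=5e-5)


def test_form_factor_limits_and_monotonicity():
    # parallel-plate limit and monotone decrease with aspect ratio
    assert form_factor(1e-6, 1.0) == pytest.approx(1.0, abs=1e-3)
    ratios = np.linspace(0.01, 1.0, 50)
    values = [form_factor(r, 1.0) for r in ratios]
    assert all(a > b for a, b in zip(values, values[1:]))
    assert 0 < values[-1] <= 1
    # symmetric in the two sides
    assert form_factor(2e-4, 1e-4) == form_factor(1e-4, 2e-4)


def _seg(length, w=200e-6, h=100e-6, sid="s"):
    return ChannelSegment(sid, ("a", "b"), w, h, ((0.0, 0.0), (length, 0.0)))


def test_hydraulic_resistance_hand_evaluated():
    fluid = FluidProps()
    seg = _seg(1e-3)
    F = form_factor_oracle(1e-4, 2e-4)
    expected = 12.0 * 1e-3 * 1e-3 / (2e-4 * (1e-4) ** 3 * F)
    assert hydraulic_resistance(seg, fluid) == pytest.approx(expected, rel=1e-9)


def test_hydraulic_resistance_scaling_in_length_and_height():
    fluid = FluidProps()
    assert hydraulic_resistance(_seg(2e-3), fluid) == pytest.approx(
        2 * hydraulic_resistance(_seg(1e-3), fluid), rel=1e-12)
    # taller channels always conduct better
    heights = [50e-6, 100e-6, 200e-6, 400e-6, 1e-3]
    rs = [hydraulic_resistance(_seg(1e-3, h=h), fluid) for h in heights]
    assert all(a > b for a, b in zip(rs, rs[1:]))


def test_series_parallel_reduction_rules():
    assert series_resistance([1.0, 2.0, 3.0]) == 6.0
    assert series_resistance([7.5]) == 7.5
    assert series_resistance([3.0, 1.0, 2.0]) == series_resistance([1.0, 2.0, 3.0])
    assert parallel_resistance([2.0, 2.0]) == pytest.approx(1.0)
    assert parallel_resistance([7.5]) == 7.5
    assert parallel_resistance([1.0, 1e12]) == pytest.approx(1.0, rel=1e-9)
    assert parallel_resistance([5.0, 3.0]) <= 3.0
    with pytest.raises(ValueError):
        series_resistance([])
    with pytest.raises(ValueError):
        parallel_resistance([])


def _two_terminal(segments, nodes, bcs):
    return ChipNetlist(nodes=tuple(nodes), segments=tuple(segments),
                       boundary_conditions=tuple(bcs))


def test_series_chain_midpoint_pressure():
    nodes = [NodeSpec("t1", "terminal", (0.0, 0.0)),
             NodeSpec("m", "turn", (1e-3, 0.0)),
             NodeSpec("t2", "terminal", (2e-3, 0.0))]
    segs = [ChannelSegment("s1", ("t1", "m"), 2e-4, 1e-4, ((0.0, 0.0), (1e-3, 0.0))),
            ChannelSegment("s2", ("m", "t2"), 2e-4, 1e-4, ((1e-3, 0.0), (2e-3, 0.0)))]
    net = _two_terminal(segs, nodes, [("t1", BoundaryCondition("pressure", 10.0)),
                                      ("t2", BoundaryCondition("pressure", 0.0))])
    sol = solve_network(net)
    assert sol.node_pressure["m"] == pytest.approx(5.0, rel=1e-12)


def test_single_segment_is_ohms_law():
    nodes = [NodeSpec("t1", "terminal", (0.0, 0.0)),
             NodeSpec("t2", "terminal", (1e-3, 0.0))]
    seg = ChannelSegment("s", ("t1", "t2"), 2e-4, 1e-4, ((0.0, 0.0), (1e-3, 0.0)))
    net = _two_terminal([seg], nodes, [("t1", BoundaryCondition("pressure", 10.0)),
                                       ("t2", BoundaryCondition("pressure", 0.0))])
    sol = solve_network(net)
    rh = hydraulic_resistance(seg, net.fluid)
    assert sol.segment_flow["s"] == pytest.approx(10.0 / rh, rel=1e-12)


def _ladder_netlist():
    """One series resistor feeding two parallel branches of unequal length."""
    w, h = 2e-4, 1e-4
    x, y = (0.0, 0.0), (1.6e-3, 0.0)
    t1, t2 = (-1.2e-3, 0.0), (2.8e-3, 0.0)
    up = ((0.0, 0.0), (0.0, 0.4e-3), (1.6e-3, 0.4e-3), (1.6e-3, 0.0))
    dn = ((0.0, 0.0), (0.0, -0.8e-3), (1.6e-3, -0.8e-3), (1.6e-3, 0.0))
    nodes = [NodeSpec("t1", "terminal", t1),
             NodeSpec("x", "intersection", x,
                      arms=(("N", "s2"), ("S", "s3"), ("W", "s1"))),
             NodeSpec("y", "intersection", y,
                      arms=(("E", "s4"), ("N", "s2"), ("S", "s3"))),
             NodeSpec("t2", "terminal", t2)]
    segs = [ChannelSegment("s1", ("t1", "x"), w, h, (t1, x)),
            ChannelSegment("s2", ("x", "y"), w, h, up),
            ChannelSegment("s3", ("x", "y"), w, h, dn),
            ChannelSegment("s4", ("y", "t2"), w, h, (y, t2))]
    return _two_terminal(segs, nodes, [("t1", BoundaryCondition("pressure", 10.0)),
                                       ("t2", BoundaryCondition("pressure", 0.0))])


def test_ladder_reduction_equals_full_solve():
    net = _ladder_netlist()
    sol = solve_network(net)
    fluid = net.fluid
    smap = net.segment_map
    r_eq = series_resistance([
        hydraulic_resistance(smap["s1"], fluid),
        parallel_resistance([hydraulic_resistance(smap["s2"], fluid),
                             hydraulic_resistance(smap["s3"], fluid)]),
        hydraulic_resistance(smap["s4"], fluid),
    ])
    assert sol.segment_flow["s1"] == pytest.approx(10.0 / r_eq, rel=1e-10)
    # and the parallel branches share flow inversely to their resistance
    assert (sol.segment_flow["s2"] / sol.segment_flow["s3"]
            == pytest.approx(smap["s3"].length / smap["s2"].length, rel=1e-9))


def test_h_chip_mirror_segments_carry_equal_flow():
    sol = solve_network(make_h_chip(inflow_north=0.01, inflow_south=0.01))
    # a, c are oriented terminal->intersection; their mirrors g, i are
    # oriented intersection->terminal, so mirrored flows keep their sign
    q = sol.segment_flow
    assert q["a"] == pytest.approx(q["g"], rel=1e-9)
    assert q["c"] == pytest.approx(q["i"], rel=1e-9)


def test_linearity_in_boundary_pressures():
    net = _ladder_netlist()
    base = solve_network(net)
    import dataclasses
    scaled_bcs = tuple((tid, BoundaryCondition(bc.kind, 3.0 * bc.value))
                       for tid, bc in net.boundary_conditions)
    tripled = solve_network(dataclasses.replace(net, boundary_conditions=scaled_bcs))
    for sid in net.segment_map:
        assert tripled.segment_flow[sid] == pytest.approx(
            3.0 * base.segment_flow[sid], rel=1e-10)


def test_arm_velocities_reproduce_worked_examples():
    """Printed junction balances: merged outflow equals the inflow sum."""
    # two 1 and 2 cm/s inlets merging to a 3 cm/s outlet
    sol = solve_network(make_h_chip(inflow_north=0.01, inflow_south=0.02))
    arms = arm_boundary_conditions(sol, "b")
    assert arms["E"] == pytest.approx(-0.03, rel=1e-9)
    assert arms["W"] == 0.0  # absent arm reports exactly zero
    assert sum(arms.values()) == pytest.approx(0.0, abs=1e-15)


def test_unknown_intersection_raises():
    sol = solve_network(make_h_chip())
    with pytest.raises(KeyError):
        sol.arm_velocities("nope")


def test_no_pressure_reference_balanced_sources_solvable():
    nodes = [NodeSpec("t1", "terminal", (0.0, 0.0)),
             NodeSpec("t2", "terminal", (1e-3, 0.0))]
    seg = ChannelSegment("s", ("t1", "t2"), 2e-4, 1e-4, ((0.0, 0.0), (1e-3, 0.0)))
    net = _two_terminal([seg], nodes, [("t1", BoundaryCondition("velocity", 0.01)),
                                       ("t2", BoundaryCondition("velocity", -0.01))])
    sol = solve_network(net)
    assert sol.segment_velocity["s"] == pytest.approx(0.01, rel=1e-12)


def test_kcl_residual_small_over_random_chips():
    worst = max(solve_network(make_random_grid_chip(seed)).kcl_residual()
                for seed in range(40))
    assert worst < 1e-12
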