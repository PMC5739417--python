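"""Shared fixtures: small pre-solved fields and exact-match libraries.

Expensive viscous-flow solves are session-scoped; unit tests run on coarse
grids (10-25 um) where the solver is fast, while the acceptance suite builds
its own fine-grid artifacts.
"""

import numpy as np
import pytest

from chipflow import (
    IntersectionLibrary,
    UnitIntersectionSpec,
    build_library,
    intersection_spec,
    make_cascade_chip,
    make_h_chip,
    solve_network,
    solve_stokes,
    unit_intersection_domain,
)

COARSE = 20e-6
MEDIUM = 10e-6
WIDTH = 200e-6


@pytest.fixture(scope="session")
def straight_field():
    """N-to-S straight channel through the unit footprint, 1 cm/s, 10 um grid."""
    dom = unit_intersection_domain(["N", "S"], MEDIUM)
    return solve_stokes(dom, {"N": 0.01, "S": -0.01})


@pytest.fixture(scope="session")
def cross_field():
    """Symmetric cross: N and S inflows split equally to E and W, 10 um grid."""
    dom = unit_intersection_domain("NESW", MEDIUM)
    return solve_stokes(dom, {"N": 0.01, "S": 0.01, "E": -0.01, "W": -0.01})


@pytest.fixture(scope="session")
def splitter_field():
    """Asymmetric T splitter: N inflow 2 cm/s, E takes 25%, S takes 75%."""
    dom = unit_intersection_domain(["N", "E", "S"], COARSE)
    return solve_stokes(dom, {"N": 0.02, "E": -0.005, "S": -0.015})


@pytest.fixture(scope="session")
def cascade_setup(tmp_path_factory):
    """Cascade chip + flow solution + exact-match library at 10 um."""
    net = make_cascade_chip()
    sol = solve_network(net)
    specs = [intersection_spec(sol, nid) for nid in ("a", "b", "c")]
    path = tmp_path_factory.mktemp("lib") / "cascade.h5"
    build_library(path, 0, seed=11, specs=specs, spacing=MEDIUM, diameters=(1e-6,))
    lib = IntersectionLibrary(path, "r")
    yield net, sol, lib
    lib.close()


@pytest.fixture(scope="session")
def h_setup(tmp_path_factory):
    """H chip (1 and 2 cm/s inlets) + exact-match library at 20 um."""
    net = make_h_chip()
    sol = solve_network(net)
    specs = [intersection_spec(sol, nid) for nid in ("b", "h")]
    path = tmp_path_factory.mktemp("lib") / "h.h5"
    build_library(path, 0, seed=7, specs=specs, spacing=COARSE, diameters=(1e-6,))
    lib = IntersectionLibrary(path, "r")
    yield net, sol, lib
    lib.close()
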