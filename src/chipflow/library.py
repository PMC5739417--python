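"""The pre-simulated unit-intersection library.

The expensive part of chip simulation is the junction flow.  This module
generates random *unit intersections* (a four-arm prototype junction: 200 um
channels crossing in a 1.6 x 1.6 mm footprint, each arm an inlet, outlet or
unused), solves each once with the viscous-flow solver, traces a bank of
particle trajectories through it, stores everything in an embedded HDF5
database, and answers closest-match queries so chip simulations can reuse
the stored results instead of re-solving.

Matching works on canonical forms: each spec is reduced under the 8
symmetries of the square and its velocities are normalized by the total
inflow (valid because Stokes flow is linear, so scaling every boundary
velocity scales the whole field without moving any streamline).  A query
therefore matches any stored record that is a rotation/reflection and/or a
uniform speed-scaling of it; the returned transform says how to map the
record's geometry back onto the query.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import h5py
import numpy as np

from .geometry import (
    D4,
    arm_image,
    preserves_orientation,
    transform_point,
    unit_intersection_domain,
)
from .netlist import ARMS, LIBRARY_FOOTPRINT, LIBRARY_WIDTH
from .stokes import VelocityField, check_divergence, solve_stokes
from .tracing import (
    ParticleSpec,
    StagnationError,
    Trajectory,
    flow_fraction,
    release_positions,
    trace_particle,
)

__all__ = [
    "UnitIntersectionSpec",
    "Transform",
    "MatchResult",
    "CoverageError",
    "IntersectionLibrary",
    "enumerate_configurations",
    "sample_instance",
    "canonicalize",
    "apply_transform",
    "build_library",
    "MAX_INFLOW",
]

#: Upper end of the random inflow range used to populate the library (m/s).
MAX_INFLOW = 2e-2

_ROLE_CODE = {"inlet": "i", "outlet": "o", "unused": "u"}
_CODE_ROLE = {v: k for k, v in _ROLE_CODE.items()}


class CoverageError(LookupError):
    """The library holds no record with the queried arm configuration."""


@dataclass(frozen=True)
class UnitIntersectionSpec:
    """Arm roles and signed mean velocities of one unit intersection.

    ``roles`` and ``velocities`` are indexed (N, E, S, W); velocities are
    m/s, positive *into* the junction, exactly zero on unused arms.
    """

    roles: tuple[str, str, str, str]
    velocities: tuple[float, float, float, float]
    width: float = LIBRARY_WIDTH
    footprint: float = LIBRARY_FOOTPRINT

    def __post_init__(self):
        if len(self.roles) != 4 or len(self.velocities) != 4:
            raise ValueError("roles and velocities must have 4 entries (N, E, S, W)")
        for role, vel in zip(self.roles, self.velocities):
            if role not in _ROLE_CODE:
                raise ValueError(f"unknown arm role {role!r}")
            if role == "unused" and vel != 0.0:
                raise ValueError("unused arms must carry exactly zero velocity")
            if role == "inlet" and not vel > 0.0:
                raise ValueError("inlet arms need positive (inward) velocity")
            if role == "outlet" and not vel < 0.0:
                raise ValueError("outlet arms need negative (outward) velocity")
        if "inlet" not in self.roles or "outlet" not in self.roles:
            raise ValueError("need at least one inlet and one outlet")
        if abs(sum(self.velocities)) > 1e-9:
            raise ValueError(
                f"signed arm velocities must sum to zero, got {sum(self.velocities):.3e}")

    @property
    def arm_velocities(self) -> dict[str, float]:
        return dict(zip(ARMS, self.velocities))

    @property
    def active_arms(self) -> tuple[str, ...]:
        return tuple(a for a, r in zip(ARMS, self.roles) if r != "unused")

    @property
    def total_inflow(self) -> float:
        return sum(v for v in self.velocities if v > 0)

    @property
    def role_string(self) -> str:
        return "".join(_ROLE_CODE[r] for r in self.roles)

    def domain(self, spacing: float):
        return unit_intersection_domain(self.active_arms, spacing,
                                        width=self.width, footprint=self.footprint)


@dataclass(frozen=True)
class Transform:
    """A square symmetry plus a uniform velocity scale.

    ``apply_transform(t, spec)`` sends arm ``a`` of ``spec`` to arm
    ``image(matrix, a)`` and multiplies all velocities by ``scale``.
    """

    m_index: int  # index into geometry.D4
    scale: float = 1.0

    @property
    def matrix(self) -> np.ndarray:
        return D4[self.m_index]

    @property
    def orientation_preserving(self) -> bool:
        return preserves_orientation(self.matrix)

    def inverse(self) -> "Transform":
        inv = np.linalg.inv(self.matrix).round().astype(int)
        return Transform(_d4_index(inv), 1.0 / self.scale)

    def compose(self, other: "Transform") -> "Transform":
        """Composition ``(self o other)(x) = self(other(x))``."""
        m = (self.matrix @ other.matrix).round().astype(int)
        return Transform(_d4_index(m), self.scale * other.scale)

    def map_arm(self, arm: str) -> str:
        return arm_image(self.matrix, arm)

    def map_q(self, q: float) -> float:
        return q if self.orientation_preserving else 1.0 - q

    def map_point(self, point, center):
        return transform_point(self.matrix, point, center)


def _d4_index(matrix: np.ndarray) -> int:
    for i, m in enumerate(D4):
        if np.array_equal(m, matrix):
            return i
    raise ValueError("matrix not in the square symmetry group")


def apply_transform(t: Transform, spec: UnitIntersectionSpec) -> UnitIntersectionSpec:
    roles = ["unused"] * 4
    vels = [0.0] * 4
    for i, arm in enumerate(ARMS):
        j = ARMS.index(t.map_arm(arm))
        roles[j] = spec.roles[i]
        vels[j] = spec.velocities[i] * t.scale
    # tiny conservation drift from scaling is re-zeroed on the last outlet
    resid = sum(vels)
    if resid != 0.0:
        k = max(range(4), key=lambda i: -vels[i])
        vels[k] -= resid
    return UnitIntersectionSpec(tuple(roles), tuple(vels),
                                spec.width, spec.footprint)


def enumerate_configurations() -> list[tuple[str, str, str, str]]:
    """All feasible inlet/outlet assignments of the four arms.

    Of the 2^4 = 16 assignments, conservation of mass forbids all-inlets and
    all-outlets, leaving 14.  Patterns containing unused arms are expressed
    at the spec level (role ``unused``), not enumerated here.
    """
    out = []
    for bits in range(16):
        roles = tuple("inlet" if bits & (1 << k) else "outlet" for k in range(4))
        if len(set(roles)) == 1:
            continue
        out.append(roles)
    return out


def sample_instance(
    seed_or_rng,
    p_unused: float = 0.0,
    max_attempts: int = 1000,
) -> UnitIntersectionSpec:
    """Draw one random unit intersection the way the library is populated.

    The configuration is uniform over the 14 feasible inlet/outlet patterns
    (arms optionally degraded to unused with probability ``p_unused``).
    Inflow rates are uniform on (0, 2] cm/s; for N outlets, N-1 outflow
    rates are uniform on (0, 2] cm/s and the last outlet balances the total.
    Draws that cannot balance with a positive outflow are rejected and
    redrawn, up to ``max_attempts``.
    """
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    patterns = enumerate_configurations()
    for _ in range(max_attempts):
        roles = list(patterns[rng.integers(len(patterns))])
        if p_unused > 0.0:
            for i in range(4):
                if rng.random() < p_unused:
                    roles[i] = "unused"
            if "inlet" not in roles or "outlet" not in roles:
                continue
        vels = [0.0] * 4
        for i, r in enumerate(roles):
            if r == "inlet":
                u = float(rng.uniform(0.0, MAX_INFLOW))
                if u == 0.0:
                    u = MAX_INFLOW  # the range is open at 0
                vels[i] = u
        outlets = [i for i, r in enumerate(roles) if r == "outlet"]
        for i in outlets[:-1]:
            u = float(rng.uniform(0.0, MAX_INFLOW))
            if u == 0.0:
                u = MAX_INFLOW
            vels[i] = -u
        last = outlets[-1]
        balance = -sum(vels)
        if balance >= 0.0:  # the last outlet must carry flow out
            continue
        vels[last] = balance
        return UnitIntersectionSpec(tuple(roles), tuple(vels))
    raise RuntimeError(f"could not sample a balanced instance in {max_attempts} draws")


def canonicalize(spec: UnitIntersectionSpec) -> tuple[UnitIntersectionSpec, Transform]:
    """Reduce a spec modulo square symmetry and velocity scale.

    Returns ``(canonical, transform)`` with
    ``apply_transform(transform, canonical) == spec``; the canonical form is
    normalized to unit total inflow and is the lexicographically smallest
    (role string, velocity tuple) over the 8 symmetries.
    """
    total = spec.total_inflow
    best = None
    for gi in range(len(D4)):
        g = Transform(gi, 1.0 / total)
        cand = apply_transform(g, spec)
        key = (cand.role_string, cand.velocities)
        if best is None or key < best[0]:
            best = (key, cand, g)
    _, canon, g = best
    # spec = g^-1(canon) with the scale re-inflated
    return canon, g.inverse()


@dataclass(frozen=True)
class MatchResult:
    """Outcome of a library query.

    ``transform`` maps the stored record onto the query:
    ``apply_transform(transform, record_spec) ~= query_spec``.
    ``distance`` is the L2 distance between inflow-normalized canonical
    velocity 4-vectors (dimensionless, 0 for an exact match).
    """

    record_id: str
    distance: float
    transform: Transform
    provenance: dict


@dataclass(frozen=True)
class StoredTrajectory:
    points: np.ndarray
    entry_q: float
    exit_q: float | None
    exit_arm: str | None
    fate: str


class IntersectionLibrary:
    """Embedded single-file (HDF5) database of pre-simulated intersections.

    Schema (version 1): group ``records/<id>`` holds the arm spec and solver
    provenance as attributes, the compressed velocity/pressure arrays, and a
    ``traj/<diameter-nm>/<arm>/<k>`` tree of release trajectories.
    """

    SCHEMA = 1

    def __init__(self, path, mode: str = "a"):
        self.file = h5py.File(path, mode)
        root = self.file.require_group("/")
        if "schema" not in root.attrs:
            root.attrs["schema"] = self.SCHEMA
            root.attrs["width"] = LIBRARY_WIDTH
            root.attrs["footprint"] = LIBRARY_FOOTPRINT
        elif int(root.attrs["schema"]) != self.SCHEMA:
            raise RuntimeError(f"unsupported library schema {root.attrs['schema']}")
        self.file.require_group("records")

    # -- context management -------------------------------------------
    def close(self):
        self.file.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    # -- writing -------------------------------------------------------
    def __len__(self):
        return len(self.file["records"])

    def record_ids(self) -> list[str]:
        return sorted(self.file["records"], key=lambda s: (len(s), s))

    def add_record(
        self,
        spec: UnitIntersectionSpec,
        spacing: float = 4e-6,
        diameters=(1e-6,),
        n_release: int = 10,
        record_id: str | None = None,
        viscosity: float = 1.0e-3,
        seed=None,
    ) -> str:
        """Solve and trace one unit intersection and store it."""
        if record_id is None:
            record_id = f"r{len(self):05d}"
        fld = solve_stokes(spec.domain(spacing), spec.arm_velocities,
                           viscosity=viscosity)
        canon, tr = canonicalize(spec)
        g = self.file["records"].create_group(record_id)
        g.attrs.update({
            "roles": spec.role_string,
            "velocities": np.asarray(spec.velocities),
            "spacing": spacing,
            "viscosity": viscosity,
            "n_release": n_release,
            "canon_roles": canon.role_string,
            "canon_velocities": np.asarray(canon.velocities),
            "canon_m_index": tr.m_index,
            "canon_scale": tr.scale,
            "reference_outlet": fld.provenance["reference_outlet"],
            "max_divergence": check_divergence(fld),
            "seed": -1 if seed is None else int(seed),
        })
        for name, arr in (("u", fld.u), ("v", fld.v), ("p", fld.p)):
            g.create_dataset(name, data=arr, compression="gzip", compression_opts=4)
        tg = g.create_group("traj")
        inlet_arms = [a for a, r in zip(ARMS, spec.roles) if r == "inlet"]
        for d in diameters:
            dg = tg.create_group(f"{round(d * 1e9)}")
            for arm in inlet_arms:
                ag = dg.create_group(arm)
                mouth = fld.domain.mouths[arm]
                for k, t in enumerate(release_positions(spec.width, n_release, d)):
                    p = ParticleSpec(diameter=d, start=mouth.point_at(float(t), "in"))
                    try:
                        traj = trace_particle(fld, p)
                    except StagnationError as exc:
                        ds = ag.create_dataset(str(k), data=np.asarray(
                            [p.start, exc.last_position]))
                        ds.attrs.update({"fate": "error", "entry_q":
                                         flow_fraction(float(t), spec.width)})
                        continue
                    ds = ag.create_dataset(str(k), data=traj.points,
                                           compression="gzip", compression_opts=4)
                    ds.attrs.update({
                        "fate": traj.fate,
                        "entry_q": traj.q_entry,
                        "exit_q": math.nan if traj.q_exit is None else traj.q_exit,
                        "exit_arm": traj.exit_name or "",
                    })
        self.file.flush()
        return record_id

    # -- reading -------------------------------------------------------
    def get_spec(self, record_id: str) -> UnitIntersectionSpec:
        g = self.file["records"][record_id]
        roles = tuple(_CODE_ROLE[c] for c in g.attrs["roles"])
        return UnitIntersectionSpec(roles, tuple(float(v) for v in g.attrs["velocities"]))

    def get_field(self, record_id: str) -> VelocityField:
        g = self.file["records"][record_id]
        spec = self.get_spec(record_id)
        dom = spec.domain(float(g.attrs["spacing"]))
        return VelocityField(
            domain=dom, u=g["u"][()], v=g["v"][()], p=g["p"][()],
            provenance={"record_id": record_id,
                        "reference_outlet": str(g.attrs["reference_outlet"])},
        )

    def diameters(self, record_id: str) -> list[float]:
        g = self.file["records"][record_id]["traj"]
        return sorted(int(k) * 1e-9 for k in g)

    def get_trajectories(self, record_id: str, diameter: float,
                         arm: str) -> list[StoredTrajectory]:
        g = self.file["records"][record_id]["traj"]
        key = f"{round(diameter * 1e9)}"
        if key not in g:
            raise KeyError(
                f"record {record_id} holds no trajectories for diameter {diameter}")
        ag = g[key][arm]
        out = []
        for k in sorted(ag, key=int):
            ds = ag[k]
            q_exit = float(ds.attrs.get("exit_q", math.nan))
            out.append(StoredTrajectory(
                points=ds[()],
                entry_q=float(ds.attrs["entry_q"]),
                exit_q=None if math.isnan(q_exit) else q_exit,
                exit_arm=str(ds.attrs.get("exit_arm", "")) or None,
                fate=str(ds.attrs["fate"]),
            ))
        out.sort(key=lambda t: t.entry_q)
        return out

    # -- querying ------------------------------------------------------
    def query(self, spec: UnitIntersectionSpec, normalize: bool = True) -> MatchResult:
        """Closest pre-simulated intersection for the given boundary spec.

        Candidates must share the query's canonical arm configuration
        (role pattern up to square symmetry); among them the record with the
        smallest L2 distance between normalized velocity 4-vectors wins,
        ties broken by record id.  ``normalize=False`` disables both the
        symmetry reduction and the inflow normalization (magnitude-keyed
        lookup compatible with a much larger stored ensemble).
        """
        if normalize:
            canon_q, t_q = canonicalize(spec)
            want = canon_q.role_string
            vec_q = np.asarray(canon_q.velocities)
        else:
            want = spec.role_string
            vec_q = np.asarray(spec.velocities)
        best = None
        for rid in self.record_ids():
            g = self.file["records"][rid]
            if normalize:
                if str(g.attrs["canon_roles"]) != want:
                    continue
                d = float(np.linalg.norm(
                    np.asarray(g.attrs["canon_velocities"]) - vec_q))
                t_r = Transform(int(g.attrs["canon_m_index"]),
                                float(g.attrs["canon_scale"]))
                transform = t_q.compose(t_r.inverse())
            else:
                if str(g.attrs["roles"]) != want:
                    continue
                d = float(np.linalg.norm(np.asarray(g.attrs["velocities"]) - vec_q))
                transform = Transform(0, 1.0)
            if best is None or (d, rid) < (best.distance, best.record_id):
                best = MatchResult(
                    record_id=rid, distance=d, transform=transform,
                    provenance={
                        "normalized": normalize,
                        "metric": "L2 on inflow-normalized canonical velocities"
                        if normalize else "L2 on raw velocities",
                        "configuration_rule": "exact canonical arm-role equality",
                    },
                )
        if best is None:
            raise CoverageError(
                f"library has no record with arm configuration {want!r}; "
                "augment the library (build more instances or add this spec)")
        return best


def build_library(
    path,
    n: int,
    seed: int,
    diameters=(1e-6,),
    spacing: float = 4e-6,
    n_release: int = 10,
    p_unused: float = 0.0,
    specs=None,
    log=None,
) -> dict:
    """Populate a library file with ``n`` random instances (or given specs).

    Deterministic for fixed ``seed``: instance ``k`` is drawn with the child
    seed ``seed + k``.  Per-record failures are caught and summarized so one
    bad solve cannot abort a long build.  Returns a summary dict.
    """
    failures = []
    built = []
    with IntersectionLibrary(path, "a") as lib:
        todo = (list(specs) if specs is not None
                else [None] * n)
        for k, item in enumerate(todo):
            child = seed + k
            spec = item if item is not None else sample_instance(child, p_unused)
            try:
                rid = lib.add_record(spec, spacing=spacing, diameters=diameters,
                                     n_release=n_release, seed=child)
                built.append(rid)
            except Exception as exc:  # noqa: BLE001 - summarized, not hidden
                failures.append((k, repr(exc)))
            if log is not None:
                log(f"[{k + 1}/{len(todo)}] {'FAIL' if failures and failures[-1][0] == k else 'ok'}")
    return {"built": built, "failures": failures, "path": str(path),
            "seed": seed, "spacing": spacing, "diameters": tuple(diameters)}
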