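"""Masked-grid geometry shared by the Stokes solver, tracer and simulator.

Chips and unit intersections are unions of axis-aligned rectangles of channel
rasterized onto a uniform cell grid.  Open boundaries where fluid enters or
leaves (channel ends at chip terminals, arm ends of a unit-intersection
footprint) are represented as :class:`Mouth` objects.

Transverse mouth coordinates
----------------------------
Particle stitching uses a cumulative-flow coordinate across each channel
cross section.  Its geometric anchor is the transverse position ``t`` in
``[0, width]`` across a mouth, measured from the *right-hand* wall looking
along the direction of travel.  Because the right-hand wall stays the
right-hand wall through straight channels and 90-degree turns, a streamline
keeps its ``t``-rank (and its flow fraction) throughout a channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy import ndimage

from .netlist import (
    ARM_DIR,
    ARMS,
    LIBRARY_FOOTPRINT,
    LIBRARY_WIDTH,
    ChipNetlist,
    NetlistError,
)


class GridError(NetlistError):
    """Geometry does not align with the requested grid spacing."""


def rot90ccw(d: tuple[float, float]) -> tuple[float, float]:
    return (-d[1], d[0])


@dataclass(frozen=True)
class Mouth:
    """An open (inflow/outflow) boundary line of a masked domain."""

    name: str  # arm letter (unit intersection) or terminal id (chip)
    center: tuple[float, float]
    outward: tuple[float, float]  # unit outward normal, axis-aligned
    width: float

    def travel(self, role: str) -> tuple[float, float]:
        """Direction of particle travel: ``"in"`` enters, ``"out"`` leaves."""
        s = -1.0 if role == "in" else 1.0
        return (s * self.outward[0], s * self.outward[1])

    def point_at(self, t: float, role: str) -> tuple[float, float]:
        """Chip-frame point at transverse coordinate ``t in [0, width]``."""
        left = rot90ccw(self.travel(role))
        o = t - self.width / 2.0
        return (self.center[0] + o * left[0], self.center[1] + o * left[1])

    def coord_of(self, point, role: str) -> float:
        left = rot90ccw(self.travel(role))
        o = (point[0] - self.center[0]) * left[0] + (point[1] - self.center[1]) * left[1]
        return o + self.width / 2.0


@dataclass(frozen=True)
class Rect:
    x0: float
    x1: float
    y0: float
    y1: float

    def contains(self, x: float, y: float, tol: float) -> bool:
        return (self.x0 - tol <= x <= self.x1 + tol
                and self.y0 - tol <= y <= self.y1 + tol)


@dataclass
class Domain:
    """A rasterized fluid region: boolean cell mask plus open mouths.

    Cell ``(ix, iy)`` has its center at ``origin + ((ix+0.5)h, (iy+0.5)h)``
    with ``h = spacing``; faces lie on grid lines.
    """

    mask: np.ndarray
    spacing: float
    origin: tuple[float, float]
    mouths: dict[str, Mouth]

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def cell_of(self, point) -> tuple[int, int]:
        h = self.spacing
        return (int(math.floor((point[0] - self.origin[0]) / h)),
                int(math.floor((point[1] - self.origin[1]) / h)))

    def is_fluid(self, point) -> bool:
        ix, iy = self.cell_of(point)
        nx, ny = self.mask.shape
        return 0 <= ix < nx and 0 <= iy < ny and bool(self.mask[ix, iy])

    @cached_property
    def _wall_dist(self) -> np.ndarray:
        # distance (m) from each fluid cell center to the nearest wall,
        # approximated from the Euclidean distance transform of the mask;
        # open mouths are padded as fluid so they do not count as walls.
        padded = np.pad(self.mask, 1, constant_values=False)
        for m in self.mouths.values():
            ax, face, lo, hi, sign = mouth_faces(self, m)
            if ax == 0:
                ix = 0 if sign < 0 else self.mask.shape[0] + 1
                padded[ix, lo + 1:hi + 1] = True
            else:
                iy = 0 if sign < 0 else self.mask.shape[1] + 1
                padded[lo + 1:hi + 1, iy] = True
        d = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
        return (d - 0.5) * self.spacing

    def wall_distance(self, point) -> float:
        """Approximate distance to the nearest channel wall (m), bilinear."""
        h = self.spacing
        gx = (point[0] - self.origin[0]) / h - 0.5
        gy = (point[1] - self.origin[1]) / h - 0.5
        return _bilinear(self._wall_dist, gx, gy)

    def mouth_hit(self, point):
        """The mouth whose plane ``point`` lies on/behind (outside), if any."""
        for m in self.mouths.values():
            d = ((point[0] - m.center[0]) * m.outward[0]
                 + (point[1] - m.center[1]) * m.outward[1])
            if d >= 0.0 and abs(m.coord_of(point, "out") - m.width / 2) <= m.width / 2:
                return m
        return None


def _bilinear(arr: np.ndarray, gx: float, gy: float) -> float:
    nx, ny = arr.shape
    x0 = min(max(int(math.floor(gx)), 0), nx - 2) if nx > 1 else 0
    y0 = min(max(int(math.floor(gy)), 0), ny - 2) if ny > 1 else 0
    fx = min(max(gx - x0, 0.0), 1.0)
    fy = min(max(gy - y0, 0.0), 1.0)
    return float(
        arr[x0, y0] * (1 - fx) * (1 - fy)
        + arr[min(x0 + 1, nx - 1), y0] * fx * (1 - fy)
        + arr[x0, min(y0 + 1, ny - 1)] * (1 - fx) * fy
        + arr[min(x0 + 1, nx - 1), min(y0 + 1, ny - 1)] * fx * fy
    )


def _snap(x: float, h: float, what: str) -> int:
    k = round(x / h)
    if abs(x - k * h) > 1e-6 * h:
        raise GridError(f"{what} = {x} is not a multiple of the grid spacing {h}")
    return int(k)


def domain_from_rects(rects, spacing, mouths, bounds=None, pad_check=True) -> Domain:
    """Rasterize a union of axis-aligned rectangles onto a cell grid.

    ``bounds = (x0, x1, y0, y1)`` fixes the grid frame explicitly (e.g. the
    full unit-intersection footprint); by default the bounding box is used.
    """
    h = spacing
    if bounds is not None:
        x0, x1, y0, y1 = bounds
    else:
        x0 = min(r.x0 for r in rects)
        y0 = min(r.y0 for r in rects)
        x1 = max(r.x1 for r in rects)
        y1 = max(r.y1 for r in rects)
    for r in rects:
        for v, nm in ((r.x0, "rect x0"), (r.x1, "rect x1"), (r.y0, "rect y0"), (r.y1, "rect y1")):
            _snap(v - (x0 if "x" in nm else y0), h, nm)
    nx = _snap(x1 - x0, h, "domain width")
    ny = _snap(y1 - y0, h, "domain height")
    mask = np.zeros((nx, ny), dtype=bool)
    tol = 1e-9 * h
    for r in rects:
        ix0 = max(_snap(r.x0 - x0, h, "x0"), 0)
        ix1 = min(_snap(r.x1 - x0, h, "x1"), nx)
        iy0 = max(_snap(r.y0 - y0, h, "y0"), 0)
        iy1 = min(_snap(r.y1 - y0, h, "y1"), ny)
        mask[ix0:ix1, iy0:iy1] = True
    dom = Domain(mask=mask, spacing=h, origin=(x0, y0),
                 mouths={m.name: m for m in mouths})
    if pad_check:
        for m in dom.mouths.values():
            mouth_faces(dom, m)  # raises GridError if misaligned
    return dom


def mouth_faces(domain: Domain, mouth: Mouth):
    """Locate a mouth on the staggered grid.

    Returns ``(axis, face_index, cell_lo, cell_hi, sign)`` where ``axis`` is
    0 for an x-normal mouth (u faces) and 1 for y-normal, ``face_index`` the
    grid-line index, ``cell_lo:cell_hi`` the transverse cell range, and
    ``sign`` +1 if the outward normal points along the positive axis.
    """
    h = domain.spacing
    ox, oy = domain.origin
    if abs(mouth.outward[0]) == 1:
        axis, sign = 0, int(mouth.outward[0])
        face = _snap(mouth.center[0] - ox, h, f"mouth {mouth.name} x")
        lo = _snap(mouth.center[1] - mouth.width / 2 - oy, h, f"mouth {mouth.name} lo")
        hi = _snap(mouth.center[1] + mouth.width / 2 - oy, h, f"mouth {mouth.name} hi")
    else:
        axis, sign = 1, int(mouth.outward[1])
        face = _snap(mouth.center[1] - oy, h, f"mouth {mouth.name} y")
        lo = _snap(mouth.center[0] - mouth.width / 2 - ox, h, f"mouth {mouth.name} lo")
        hi = _snap(mouth.center[0] + mouth.width / 2 - ox, h, f"mouth {mouth.name} hi")
    return axis, face, lo, hi, sign


# ---------------------------------------------------------------------------
# Canonical domains


def unit_intersection_domain(
    active_arms,
    spacing: float,
    width: float = LIBRARY_WIDTH,
    footprint: float = LIBRARY_FOOTPRINT,
) -> Domain:
    """Cross- or T-shaped unit-intersection domain with arm mouths.

    The footprint is a ``footprint x footprint`` square with the junction at
    its center; each active arm is a ``width``-wide strip reaching the
    footprint edge, where its mouth sits.  Unused arms are omitted (solid
    wall), matching how a T-junction appears in a real chip.
    """
    active = list(active_arms)
    if not active:
        raise ValueError("need at least one active arm")
    c = footprint / 2.0
    w2 = width / 2.0
    rects = [Rect(c - w2, c + w2, c - w2, c + w2)]
    mouths = []
    for arm in active:
        dx, dy = ARM_DIR[arm]
        if dx:
            x0, x1 = (c + w2, footprint) if dx > 0 else (0.0, c - w2)
            rects.append(Rect(x0, x1, c - w2, c + w2))
        else:
            y0, y1 = (c + w2, footprint) if dy > 0 else (0.0, c - w2)
            rects.append(Rect(c - w2, c + w2, y0, y1))
        mouths.append(Mouth(arm, (c + dx * c, c + dy * c), (float(dx), float(dy)), width))
    return domain_from_rects(rects, spacing, mouths,
                             bounds=(0.0, footprint, 0.0, footprint))


def chip_domain(netlist: ChipNetlist, spacing: float) -> Domain:
    """Rasterize a whole chip netlist; mouths are the terminal channel ends."""
    rects = []
    for seg in netlist.segments:
        w2 = seg.width / 2.0
        for (p, q) in seg.legs():
            rects.append(Rect(min(p[0], q[0]) - (w2 if p[0] == q[0] else 0.0),
                              max(p[0], q[0]) + (w2 if p[0] == q[0] else 0.0),
                              min(p[1], q[1]) - (w2 if p[1] == q[1] else 0.0),
                              max(p[1], q[1]) + (w2 if p[1] == q[1] else 0.0)))
        # square pads over interior waypoint corners
        for p in seg.waypoints[1:-1]:
            rects.append(Rect(p[0] - w2, p[0] + w2, p[1] - w2, p[1] + w2))
    for node in netlist.nodes:
        if node.kind == "terminal":
            continue
        w2 = max(s.width for s in netlist.segments_at(node.id)) / 2.0
        x, y = node.position
        rects.append(Rect(x - w2, x + w2, y - w2, y + w2))
    mouths = []
    for t in netlist.terminals():
        seg = netlist.segments_at(t.id)[0]
        if seg.nodes[0] == t.id:
            p, q = seg.waypoints[0], seg.waypoints[1]
        else:
            p, q = seg.waypoints[-1], seg.waypoints[-2]
        n = math.hypot(q[0] - p[0], q[1] - p[1])
        outward = (round((p[0] - q[0]) / n), round((p[1] - q[1]) / n))
        mouths.append(Mouth(t.id, t.position, outward, seg.width))
    return domain_from_rects(rects, spacing, mouths)


# ---------------------------------------------------------------------------
# Square-symmetry (dihedral) transforms

_R90 = np.array([[0, -1], [1, 0]])
_REFL = np.array([[1, 0], [0, -1]])  # reflection across the x axis

#: The 8 symmetries of the square: rotations by k*90 degrees, then the same
#: composed with a reflection.  Index in this tuple is the group element id.
D4 = tuple(
    np.linalg.matrix_power(_R90, k) @ m
    for m in (np.eye(2, dtype=int), _REFL)
    for k in range(4)
)


def arm_image(matrix: np.ndarray, arm: str) -> str:
    """Image of a compass arm under a square symmetry."""
    d = matrix @ np.array(ARM_DIR[arm], dtype=int)
    for a in ARMS:
        if tuple(d) == ARM_DIR[a]:
            return a
    raise ValueError("matrix is not a signed permutation")  # pragma: no cover


def preserves_orientation(matrix: np.ndarray) -> bool:
    return round(float(np.linalg.det(matrix))) == 1


def transform_point(matrix: np.ndarray, point, center) -> tuple[float, float]:
    """Apply a square symmetry about ``center`` to a point."""
    v = np.asarray(point, dtype=float) - np.asarray(center, dtype=float)
    out = matrix @ v + np.asarray(center, dtype=float)
    return (float(out[0]), float(out[1]))
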