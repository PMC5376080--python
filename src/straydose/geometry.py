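"""Constructive solid geometry over quadric surfaces for photon tracking.

Space is partitioned into cells, each defined by a boolean expression over
signed half-spaces of general quadrics

    f(x, y, z) = A x^2 + B y^2 + C z^2 + D xy + E yz + F zx + G x + H y + I z + J = 0.

The sense of a point with respect to a surface is the sign of ``f``; a cell
region is a tree of intersections/unions/complements of half-spaces.  The
engine supports point location, nearest-boundary queries along a ray and full
ray tracing, which is all a photon random walk needs.

Conventions: right-handed frame, origin at the treatment isocenter, z vertical
(the beam travels toward -z), lengths in cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

#: Distance (cm) a particle is nudged past a crossed surface before relocating.
SURFACE_NUDGE = 1e-6

#: Roots of the ray/quadric equation closer than this are treated as "behind"
#: the particle (it is sitting on, or has just crossed, that surface).
ROOT_EPS = 1e-9

#: Hard cap on segments in a single trace; trips on geometry definition bugs.
MAX_SEGMENTS = 10_000


class GeometryError(Exception):
    """Raised for ill-posed geometry definitions (ambiguous/uncovered points)."""


class TrackingError(Exception):
    """Raised when a particle cannot be advanced (lost particle)."""


# ---------------------------------------------------------------------------
# Surfaces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuadricSurface:
    """A general quadric surface with labelled coefficients A..J."""

    id: str
    coefficients: tuple  # (A, B, C, D, E, F, G, H, I, J)
    kind: str = "general"

    def __post_init__(self):
        c = tuple(float(v) for v in self.coefficients)
        if len(c) != 10:
            raise GeometryError(f"surface {self.id}: need 10 coefficients, got {len(c)}")
        if not all(math.isfinite(v) for v in c):
            raise GeometryError(f"surface {self.id}: non-finite coefficient")
        if not any(v != 0.0 for v in c[:9]):
            raise GeometryError(f"surface {self.id}: all of A..I are zero")
        object.__setattr__(self, "coefficients", c)

    # -- evaluation ---------------------------------------------------------

    def evaluate(self, p) -> float:
        A, B, C, D, E, F, G, H, I, J = self.coefficients
        x, y, z = p
        return (A * x * x + B * y * y + C * z * z
                + D * x * y + E * y * z + F * z * x
                + G * x + H * y + I * z + J)

    def evaluate_many(self, pts: np.ndarray) -> np.ndarray:
        """Vectorised ``evaluate`` over an (n, 3) array of points."""
        A, B, C, D, E, F, G, H, I, J = self.coefficients
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        return (A * x * x + B * y * y + C * z * z
                + D * x * y + E * y * z + F * z * x
                + G * x + H * y + I * z + J)

    def sense(self, p) -> int:
        return 1 if self.evaluate(p) > 0.0 else -1

    # -- ray intersection ---------------------------------------------------

    def ray_coefficients(self, p, u):
        """Quadratic (a, b, c) of f(p + t u) = a t^2 + b t + c."""
        A, B, C, D, E, F, G, H, I, J = self.coefficients
        px, py, pz = p
        ux, uy, uz = u
        a = (A * ux * ux + B * uy * uy + C * uz * uz
             + D * ux * uy + E * uy * uz + F * uz * ux)
        b = (2.0 * (A * px * ux + B * py * uy + C * pz * uz)
             + D * (px * uy + py * ux) + E * (py * uz + pz * uy)
             + F * (pz * ux + px * uz)
             + G * ux + H * uy + I * uz)
        c = self.evaluate(p)
        return a, b, c

    def distance_along_ray(self, p, u) -> float:
        """Smallest root t > ROOT_EPS of the surface along p + t u, else inf."""
        a, b, c = self.ray_coefficients(p, u)
        if a == 0.0:
            if b == 0.0:
                return math.inf
            t = -c / b
            return t if t > ROOT_EPS else math.inf
        disc = b * b - 4.0 * a * c
        if disc < 0.0:
            return math.inf
        sq = math.sqrt(disc)
        # stable quadratic roots
        q = -0.5 * (b + math.copysign(sq, b))
        roots = []
        if a != 0.0:
            roots.append(q / a)
        if q != 0.0:
            roots.append(c / q)
        best = math.inf
        for t in roots:
            if ROOT_EPS < t < best:
                best = t
        return best

    def translated(self, d, new_id: Optional[str] = None) -> "QuadricSurface":
        """The same surface rigidly shifted by vector ``d`` (f'(p) = f(p - d))."""
        A, B, C, D, E, F, G, H, I, J = self.coefficients
        dx, dy, dz = d
        G2 = G - 2.0 * A * dx - D * dy - F * dz
        H2 = H - 2.0 * B * dy - D * dx - E * dz
        I2 = I - 2.0 * C * dz - E * dy - F * dx
        J2 = (A * dx * dx + B * dy * dy + C * dz * dz
              + D * dx * dy + E * dy * dz + F * dz * dx
              - G * dx - H * dy - I * dz + J)
        return QuadricSurface(new_id or self.id, (A, B, C, D, E, F, G2, H2, I2, J2),
                              self.kind)


# convenience constructors ---------------------------------------------------


def plane_x(c: float, id: str) -> QuadricSurface:
    return QuadricSurface(id, (0, 0, 0, 0, 0, 0, 1, 0, 0, -c), "plane")


def plane_y(c: float, id: str) -> QuadricSurface:
    return QuadricSurface(id, (0, 0, 0, 0, 0, 0, 0, 1, 0, -c), "plane")


def plane_z(c: float, id: str) -> QuadricSurface:
    return QuadricSurface(id, (0, 0, 0, 0, 0, 0, 0, 0, 1, -c), "plane")


def sphere(center, r: float, id: str) -> QuadricSurface:
    cx, cy, cz = center
    return QuadricSurface(
        id, (1, 1, 1, 0, 0, 0, -2 * cx, -2 * cy, -2 * cz,
             cx * cx + cy * cy + cz * cz - r * r), "sphere")


def ellipsoid(center, semi, id: str) -> QuadricSurface:
    """(x-cx)^2/a^2 + (y-cy)^2/b^2 + (z-cz)^2/c^2 - 1 = 0."""
    cx, cy, cz = center
    a, b, c = semi
    A, B, C = 1 / a**2, 1 / b**2, 1 / c**2
    return QuadricSurface(
        id, (A, B, C, 0, 0, 0, -2 * A * cx, -2 * B * cy, -2 * C * cz,
             A * cx**2 + B * cy**2 + C * cz**2 - 1.0), "ellipsoid")


def cylinder_y(cx: float, cz: float, r: float, id: str) -> QuadricSurface:
    """Circular cylinder with axis parallel to y."""
    return QuadricSurface(
        id, (1, 0, 1, 0, 0, 0, -2 * cx, 0, -2 * cz, cx * cx + cz * cz - r * r),
        "cylinder-axis")


def cylinder_x(cy: float, cz: float, r: float, id: str) -> QuadricSurface:
    return QuadricSurface(
        id, (0, 1, 1, 0, 0, 0, 0, -2 * cy, -2 * cz, cy * cy + cz * cz - r * r),
        "cylinder-axis")


def cylinder_z(cx: float, cy: float, r: float, id: str) -> QuadricSurface:
    return QuadricSurface(
        id, (1, 1, 0, 0, 0, 0, -2 * cx, -2 * cy, 0, cx * cx + cy * cy - r * r),
        "cylinder-axis")


def elliptic_cylinder_y(cx: float, cz: float, a: float, c: float, id: str) -> QuadricSurface:
    """Elliptic cylinder, axis parallel to y, semi-axes a (x) and c (z)."""
    A, C = 1 / a**2, 1 / c**2
    return QuadricSurface(
        id, (A, 0, C, 0, 0, 0, -2 * A * cx, 0, -2 * C * cz,
             A * cx**2 + C * cz**2 - 1.0), "cylinder-axis")


def cone_z(apex, slope: float, id: str) -> QuadricSurface:
    """Cone about the z axis: x^2 + y^2 - slope^2 (z - z0)^2 = 0, apex at ``apex``."""
    ax, ay, az = apex
    s2 = slope * slope
    return QuadricSurface(
        id, (1, 1, -s2, 0, 0, 0, -2 * ax, -2 * ay, 2 * s2 * az,
             ax * ax + ay * ay - s2 * az * az), "cone")


# ---------------------------------------------------------------------------
# Regions (boolean expression trees over signed surfaces)
# ---------------------------------------------------------------------------


class Region:
    """Base node of a cell's boolean region expression."""

    def __and__(self, other: "Region") -> "Region":
        return Intersection((self, other))

    def __or__(self, other: "Region") -> "Region":
        return Union((self, other))

    def __invert__(self) -> "Region":
        return Complement(self)

    def contains(self, p, surfaces) -> bool:  # pragma: no cover - abstract
        raise NotImplementedError

    def contains_many(self, pts, surfaces) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def surface_ids(self) -> frozenset:  # pragma: no cover - abstract
        raise NotImplementedError

    def translated(self, d) -> "Region":  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass(frozen=True)
class Halfspace(Region):
    """Signed side of a surface: sign=-1 is f(p) < 0 (inside a sphere), +1 is f(p) > 0."""

    surface_id: str
    sign: int

    def contains(self, p, surfaces) -> bool:
        v = surfaces[self.surface_id].evaluate(p)
        return v < 0.0 if self.sign < 0 else v > 0.0

    def contains_many(self, pts, surfaces) -> np.ndarray:
        v = surfaces[self.surface_id].evaluate_many(pts)
        return v < 0.0 if self.sign < 0 else v > 0.0

    def surface_ids(self) -> frozenset:
        return frozenset((self.surface_id,))

    def translated(self, d) -> "Region":
        return self


@dataclass(frozen=True)
class Intersection(Region):
    parts: tuple

    def contains(self, p, surfaces) -> bool:
        return all(r.contains(p, surfaces) for r in self.parts)

    def contains_many(self, pts, surfaces) -> np.ndarray:
        out = self.parts[0].contains_many(pts, surfaces)
        for r in self.parts[1:]:
            out = out & r.contains_many(pts, surfaces)
        return out

    def surface_ids(self) -> frozenset:
        return frozenset().union(*(r.surface_ids() for r in self.parts))

    def translated(self, d) -> "Region":
        return Intersection(tuple(r.translated(d) for r in self.parts))


@dataclass(frozen=True)
class Union(Region):
    parts: tuple

    def contains(self, p, surfaces) -> bool:
        return any(r.contains(p, surfaces) for r in self.parts)

    def contains_many(self, pts, surfaces) -> np.ndarray:
        out = self.parts[0].contains_many(pts, surfaces)
        for r in self.parts[1:]:
            out = out | r.contains_many(pts, surfaces)
        return out

    def surface_ids(self) -> frozenset:
        return frozenset().union(*(r.surface_ids() for r in self.parts))

    def translated(self, d) -> "Region":
        return Union(tuple(r.translated(d) for r in self.parts))


@dataclass(frozen=True)
class Complement(Region):
    inner: Region

    def contains(self, p, surfaces) -> bool:
        return not self.inner.contains(p, surfaces)

    def contains_many(self, pts, surfaces) -> np.ndarray:
        return ~self.inner.contains_many(pts, surfaces)

    def surface_ids(self) -> frozenset:
        return self.inner.surface_ids()

    def translated(self, d) -> "Region":
        return Complement(self.inner.translated(d))


def inside(surface: QuadricSurface) -> Halfspace:
    return Halfspace(surface.id, -1)


def outside(surface: QuadricSurface) -> Halfspace:
    return Halfspace(surface.id, +1)


def box_region(xlo, xhi, ylo, yhi, zlo, zhi) -> Region:
    """Axis-aligned box built from six half-space planes (surfaces included)."""
    return Intersection(tuple(
        Halfspace(s.id, sgn) for s, sgn in (
            (xlo, +1), (xhi, -1), (ylo, +1), (yhi, -1), (zlo, +1), (zhi, -1))))


# ---------------------------------------------------------------------------
# Cells and the assembled model
# ---------------------------------------------------------------------------


@dataclass
class Cell:
    id: str
    region: Region
    material_id: str
    density_override: Optional[float] = None     # g/cm3
    is_tally_region: bool = False
    organ_label: Optional[str] = None
    is_world: bool = False
    volume: Optional[float] = None               # cm3, analytic where known


class GeometryModel:
    """Surfaces + space-filling, non-overlapping cells, one flagged as world."""

    def __init__(self, surfaces: Iterable[QuadricSurface], cells: Iterable[Cell],
                 bounding_box: Optional[tuple] = None):
        self.surfaces = {}
        for s in surfaces:
            if s.id in self.surfaces:
                raise GeometryError(f"duplicate surface id {s.id!r}")
            self.surfaces[s.id] = s
        self.cells = list(cells)
        ids = [c.id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise GeometryError("duplicate cell ids")
        worlds = [c for c in self.cells if c.is_world]
        if len(worlds) != 1:
            raise GeometryError(f"exactly one world cell required, found {len(worlds)}")
        self.world = worlds[0]
        for c in self.cells:
            missing = c.region.surface_ids() - self.surfaces.keys()
            if missing:
                raise GeometryError(f"cell {c.id}: unknown surfaces {sorted(missing)}")
        self._by_id = {c.id: c for c in self.cells}
        # per-cell bounding surface list (objects, for the hot tracking loop)
        self._cell_surfaces = {
            c.id: [self.surfaces[sid] for sid in sorted(c.region.surface_ids())]
            for c in self.cells}
        # surface -> cells touching it, used as neighbour candidates on crossing
        self._neighbours: dict = {}
        for c in self.cells:
            for sid in c.region.surface_ids():
                self._neighbours.setdefault(sid, []).append(c)
        # bounding box (cm): ((xlo, xhi), (ylo, yhi), (zlo, zhi))
        self.bounding_box = bounding_box

    # -- lookup -------------------------------------------------------------

    def cell(self, cell_id: str) -> Cell:
        return self._by_id[cell_id]

    def locate_point(self, p, strict: bool = False) -> Cell:
        """Cell containing p.  With strict=True every cell is tested and a
        multiple claim raises; the default returns the first match (cells are
        defined mutually exclusive by construction)."""
        if not all(math.isfinite(v) for v in p):
            raise GeometryError(f"non-finite point {p}")
        matches = []
        for c in self.cells:
            if c.region.contains(p, self.surfaces):
                if not strict:
                    return c
                matches.append(c)
        if not matches:
            raise GeometryError(f"point {p} is in no cell (space not filled)")
        if len(matches) > 1:
            raise GeometryError(
                "ambiguous location at %s: cells %s" % (p, [c.id for c in matches]))
        return matches[0]

    def locate_points(self, pts: np.ndarray) -> np.ndarray:
        """Vectorised location audit: returns the number of cells claiming each
        of the (n, 3) points.  Space-filling, non-overlapping geometry gives
        an all-ones result."""
        counts = np.zeros(len(pts), dtype=np.int64)
        for c in self.cells:
            counts += c.region.contains_many(pts, self.surfaces)
        return counts

    # -- tracking -----------------------------------------------------------

    def distance_to_boundary(self, p, u, cell: Cell):
        """(distance, surface id) of the nearest bounding-surface crossing of
        ``cell`` along p + t u; (inf, None) for an unbounded direction."""
        best = math.inf
        hit = None
        for s in self._cell_surfaces[cell.id]:
            t = s.distance_along_ray(p, u)
            if t < best:
                best = t
                hit = s.id
        return best, hit

    def relocate(self, p, crossed_surface_id: Optional[str], exclude: Optional[str] = None) -> Cell:
        """Find the cell containing p after a surface crossing, trying the
        cells adjacent to the crossed surface first."""
        if crossed_surface_id is not None:
            for c in self._neighbours.get(crossed_surface_id, ()):
                if c.id != exclude and c.region.contains(p, self.surfaces):
                    return c
            if exclude is not None:
                c = self._by_id[exclude]
                if c.region.contains(p, self.surfaces):
                    return c
        return self.locate_point(p)

    def ray_trace(self, p, u) -> list:
        """Ordered (cell id, chord length cm) segments from p to escape into
        the world cell.  Consecutive identical cells are merged."""
        norm = math.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
        if abs(norm - 1.0) > 1e-12:
            raise TrackingError(f"direction not unit (|u| = {norm})")
        cell = self.locate_point(p)
        x, y, z = p
        segments = []
        carry = 0.0      # nudge distance crossed into the current cell
        all_surfaces = list(self.surfaces.values())
        for _ in range(MAX_SEGMENTS):
            if cell.is_world:
                if segments:
                    break            # escaped the geometry
                # starting outside: march to the first entry into the model
                best = math.inf
                hit = None
                for s in all_surfaces:
                    t = s.distance_along_ray((x, y, z), u)
                    if t < best:
                        best, hit = t, s.id
                if not math.isfinite(best):
                    break            # never enters the geometry
                x += (best + SURFACE_NUDGE) * u[0]
                y += (best + SURFACE_NUDGE) * u[1]
                z += (best + SURFACE_NUDGE) * u[2]
                cell = self.relocate((x, y, z), hit, exclude=cell.id)
                carry = SURFACE_NUDGE
                continue
            d, sid = self.distance_to_boundary((x, y, z), u, cell)
            if not math.isfinite(d):
                raise TrackingError(
                    f"particle lost in bounded cell {cell.id} at {(x, y, z)} dir {u}")
            chord = d + carry
            if segments and segments[-1][0] == cell.id:
                segments[-1] = (cell.id, segments[-1][1] + chord)
            else:
                segments.append((cell.id, chord))
            x += (d + SURFACE_NUDGE) * u[0]
            y += (d + SURFACE_NUDGE) * u[1]
            z += (d + SURFACE_NUDGE) * u[2]
            carry = SURFACE_NUDGE
            cell = self.relocate((x, y, z), sid, exclude=cell.id)
        else:
            raise TrackingError("segment count exceeded MAX_SEGMENTS (geometry loop?)")
        return segments

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def region_to_obj(r: Region):
            if isinstance(r, Halfspace):
                return {"surface": r.surface_id, "sign": r.sign}
            if isinstance(r, Intersection):
                return {"and": [region_to_obj(x) for x in r.parts]}
            if isinstance(r, Union):
                return {"or": [region_to_obj(x) for x in r.parts]}
            if isinstance(r, Complement):
                return {"not": region_to_obj(r.inner)}
            raise TypeError(type(r))

        return {
            "surfaces": [
                {"id": s.id, "kind": s.kind, "coefficients": list(s.coefficients)}
                for s in self.surfaces.values()],
            "cells": [
                {"id": c.id, "region": region_to_obj(c.region),
                 "material": c.material_id, "density_override": c.density_override,
                 "is_tally_region": c.is_tally_region, "organ_label": c.organ_label,
                 "is_world": c.is_world, "volume": c.volume}
                for c in self.cells],
            "bounding_box": self.bounding_box,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "GeometryModel":
        def obj_to_region(o) -> Region:
            if "surface" in o:
                return Halfspace(o["surface"], int(o["sign"]))
            if "and" in o:
                return Intersection(tuple(obj_to_region(x) for x in o["and"]))
            if "or" in o:
                return Union(tuple(obj_to_region(x) for x in o["or"]))
            if "not" in o:
                return Complement(obj_to_region(o["not"]))
            raise GeometryError(f"bad region object {o}")

        surfaces = [QuadricSurface(s["id"], tuple(s["coefficients"]), s.get("kind", "general"))
                    for s in obj["surfaces"]]
        cells = [Cell(c["id"], obj_to_region(c["region"]), c["material"],
                      c.get("density_override"), c.get("is_tally_region", False),
                      c.get("organ_label"), c.get("is_world", False), c.get("volume"))
                 for c in obj["cells"]]
        bb = obj.get("bounding_box")
        if bb is not None:
            bb = tuple(tuple(v) for v in bb)
        return cls(surfaces, cells, bb)
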