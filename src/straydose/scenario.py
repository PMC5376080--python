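"""Scenario builders: stylized adult male phantom, shielded treatment room,
linac head, beam sources, and the water-phantom depth-dose benchmark.

The treatment world reproduces the published scenario defaults: a 13.7 x 9 x
4 m room shielded with ordinary concrete (2.35 g/cm3), a maze 2.2 m high and
2 m wide, an adjacent 9.9 x 2 x 4 m control room with a door, air fill at
0.00129 g/cm3, and a 6 MV accelerator with a source-to-isocenter distance of
100 cm.  The patient is a stylized phantom in the MIRD/ORNL tradition:
quadric organs (ellipsoidal brain, heart, lungs, liver and testes, cylindrical
trunk, spine, esophagus and colon, a 0.2 cm skin shell and a bone skeleton
surrogate).  The shapes, sizes and tissue assignments are this package's own
documented parameterisation.

Frame: origin at the isocenter, z vertical, beam travelling toward -z; the
phantom lies supine along y.  All lengths cm.

Irradiation targets P1..P5 are the testes, colon, liver, left lung and brain;
aiming the beam translates the phantom (with its couch) so the chosen organ
point sits at the isocenter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .geometry import (Cell, GeometryModel, Halfspace, Region, Union,
                       box_region, cone_z, cylinder_x, cylinder_y, cylinder_z,
                       ellipsoid, elliptic_cylinder_y, inside, outside,
                       plane_x, plane_y, plane_z)
from .physics import MATERIALS

SAD = 100.0          # source-to-isocenter distance, cm
ORGANS = ("skin", "skeleton", "spine", "brain", "esophagus", "heart",
          "left_lung", "right_lung", "liver", "colon", "testes",
          "residual_tissue")

#: irradiation position -> targeted organ
TARGET_ORGAN = {"P1": "testes", "P2": "colon", "P3": "liver",
                "P4": "left_lung", "P5": "brain"}


class ScenarioError(Exception):
    pass


# ---------------------------------------------------------------------------
# Sources
# ---------------------------------------------------------------------------


@dataclass
class BeamSource:
    """Photon source: collimated spectrum beam or monoenergetic isotropic point.

    In beam mode photons start at ``position`` and are aimed at a point drawn
    uniformly from the ``field_size`` rectangle in the isocenter plane z = 0,
    so the fluence fills the jaw aperture.  Energies are drawn from the
    tabulated line spectrum.
    """

    mode: str                      # "spectrum-beam" | "monoenergetic-point"
    position: tuple
    energies: np.ndarray           # MeV
    probabilities: np.ndarray
    field_size: tuple = (10.0, 10.0)   # cm at the isocenter plane (beam mode)

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        p = np.asarray(self.probabilities, dtype=float)
        if e.ndim != 1 or e.shape != p.shape or not len(e):
            raise ScenarioError("spectrum arrays must be equal-length 1-D")
        if np.any(p < 0) or p.sum() <= 0:
            raise ScenarioError("spectrum probabilities must be >= 0, sum > 0")
        if np.any(e <= 0):
            raise ScenarioError("spectrum energies must be positive")
        self.energies = e
        self.probabilities = p / p.sum()
        self._cdf = np.cumsum(self.probabilities)
        if self.mode not in ("spectrum-beam", "monoenergetic-point"):
            raise ScenarioError(f"unknown source mode {self.mode!r}")

    @property
    def mean_energy(self) -> float:
        return float(np.sum(self.energies * self.probabilities))

    def sample_energy(self, rng) -> float:
        i = int(np.searchsorted(self._cdf, rng.random(), side="right"))
        return float(self.energies[min(i, len(self.energies) - 1)])

    def sample(self, rng):
        """(position, unit direction, energy MeV) of one primary photon."""
        E = self.sample_energy(rng)
        px, py, pz = self.position
        if self.mode == "monoenergetic-point":
            mu = 2.0 * rng.random() - 1.0
            phi = 2.0 * math.pi * rng.random()
            s = math.sqrt(max(0.0, 1.0 - mu * mu))
            return self.position, (s * math.cos(phi), s * math.sin(phi), mu), E
        wx, wy = self.field_size
        qx = (rng.random() - 0.5) * wx
        qy = (rng.random() - 0.5) * wy
        dx, dy, dz = qx - px, qy - py, -pz
        norm = math.sqrt(dx * dx + dy * dy + dz * dz)
        return self.position, (dx / norm, dy / norm, dz / norm), E


def cs137_source(position=(0.0, 0.0, SAD)) -> BeamSource:
    """The monoenergetic 137Cs comparison source, E = 0.6616 MeV, isotropic."""
    return BeamSource("monoenergetic-point", position,
                      np.array([0.6616]), np.array([1.0]), (0.0, 0.0))


def synthetic_6mv_spectrum(n_bins: int = 24, e_max: float = 6.0,
                           filter_cm_water: float = 11.0):
    """A SYNTHETIC generic 6 MV photon line spectrum (energies MeV, probabilities).

    Stand-in for a measured accelerator spectrum: a thin-target bremsstrahlung
    shape p(E) ~ (1/E)(1 - E/E_max) hardened by a water-equivalent filter,
    binned to ``n_bins`` lines.  The default filtration gives a mean energy
    near 1.7 MeV, typical of a flattened 6 MV beam in air.
    """
    water = MATERIALS["water"]
    edges = np.linspace(0.05, e_max, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = (1.0 / centers) * (1.0 - centers / (e_max + 0.05))
    atten = np.array([math.exp(-water.mu_total(float(E)) * filter_cm_water)
                      for E in centers])
    p = p * atten * np.diff(edges)
    return centers, p / p.sum()


def load_spectrum(path) -> tuple:
    """Two-column text spectrum (energy MeV, probability); '#' comments allowed."""
    arr = np.loadtxt(path, comments="#", ndmin=2)
    if arr.shape[1] < 2:
        raise ScenarioError(f"{path}: need two columns (energy, probability)")
    return arr[:, 0], arr[:, 1]


# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------


@dataclass
class PhantomModel:
    organ_cells: dict            # organ -> Cell
    points: dict                 # "P1".."P5" -> (x, y, z) in the model frame
    masses: dict                 # organ -> g
    shift: tuple
    scale: float
    body_region: Region          # outer envelope (skin included), for exclusions
    surfaces: list
    cells: list


def _phantom_geometry(shift=(0.0, 0.0, 0.0), scale: float = 1.0):
    """All phantom surfaces/regions in the room frame (phantom frame scaled
    then shifted).  Returns (surfaces, organ regions, body region, volumes,
    P-points)."""
    if scale <= 0:
        raise ScenarioError("phantom scale must be positive")
    s = scale
    sx, sy, sz = shift

    def pt(x, y, z):
        return (s * x + sx, s * y + sy, s * z + sz)

    surfaces: list = []

    def add(srf):
        surfaces.append(srf)
        return srf

    # body envelope: elliptic cylinder along y, semi-axes 18 (x) x 9 (z),
    # length 170; skin is the outer 0.2 cm shell including end caps
    A, C, HL, T = 18.0, 9.0, 85.0, 0.2
    outer_cyl = add(elliptic_cylinder_y(sx, sz, s * A, s * C, "ph_body_outer"))
    inner_cyl = add(elliptic_cylinder_y(sx, sz, s * (A - T), s * (C - T),
                                        "ph_body_inner"))
    y_lo = add(plane_y(sy - s * HL, "ph_y_lo"))
    y_hi = add(plane_y(sy + s * HL, "ph_y_hi"))
    y_lo_i = add(plane_y(sy - s * (HL - T), "ph_y_lo_i"))
    y_hi_i = add(plane_y(sy + s * (HL - T), "ph_y_hi_i"))

    body = inside(outer_cyl) & outside(y_lo) & ~outside(y_hi)
    interior = inside(inner_cyl) & outside(y_lo_i) & ~outside(y_hi_i)
    skin = body & ~interior
    v_body = math.pi * (s * A) * (s * C) * (2 * s * HL)
    v_interior = math.pi * (s * (A - T)) * (s * (C - T)) * (2 * s * (HL - T))
    v_skin = v_body - v_interior

    def ell(name, center, semi):
        srf = add(ellipsoid(pt(*center), tuple(s * v for v in semi), name))
        vol = 4.0 / 3.0 * math.pi * (s ** 3) * semi[0] * semi[1] * semi[2]
        return inside(srf), vol

    def cyl_along_y(name, cx, cz, r, y0, y1):
        srf = add(cylinder_y(s * cx + sx, s * cz + sz, s * r, name))
        p0 = add(plane_y(s * y0 + sy, name + "_lo"))
        p1 = add(plane_y(s * y1 + sy, name + "_hi"))
        vol = math.pi * (s * r) ** 2 * (s * (y1 - y0))
        return inside(srf) & outside(p0) & ~outside(p1), vol

    regions: dict = {}
    volumes: dict = {}

    regions["brain"], volumes["brain"] = ell("ph_brain", (0, 75, 0), (6, 8, 5.5))
    # skeleton = skull shell around the brain + two femur surrogates
    sk_out, v_sk_out = ell("ph_skull_out", (0, 75, 0), (7.5, 9.5, 7.0))
    sk_in, v_sk_in = ell("ph_skull_in", (0, 75, 0), (6.4, 8.4, 5.9))
    fem_l, v_fem = cyl_along_y("ph_femur_l", 8, -2, 2.0, -80, -45)
    fem_r, _ = cyl_along_y("ph_femur_r", -8, -2, 2.0, -80, -45)
    regions["skeleton"] = (sk_out & ~sk_in) | fem_l | fem_r
    volumes["skeleton"] = (v_sk_out - v_sk_in) + 2 * v_fem
    regions["spine"], volumes["spine"] = cyl_along_y("ph_spine", 0, -6, 1.8, -40, 60)
    regions["esophagus"], volumes["esophagus"] = cyl_along_y(
        "ph_esoph", 0, -3.2, 0.8, 12, 55)
    regions["heart"], volumes["heart"] = ell("ph_heart", (0.5, 8, 2.5),
                                             (3.4, 4.5, 4.0))
    regions["left_lung"], volumes["left_lung"] = ell("ph_lung_l", (8.5, 18, 0),
                                                     (4.5, 12, 6))
    regions["right_lung"], volumes["right_lung"] = ell("ph_lung_r",
                                                       (-8.5, 18, 0),
                                                       (4.5, 12, 6))
    regions["liver"], volumes["liver"] = ell("ph_liver", (-6, -18, 1), (9, 7, 5))
    # colon surrogate: transverse tube across the lower abdomen
    col = add(cylinder_x(s * (-35) + sy, s * 1 + sz, s * 2.5, "ph_colon"))
    cx0 = add(plane_x(s * (-8) + sx, "ph_colon_lo"))
    cx1 = add(plane_x(s * 8 + sx, "ph_colon_hi"))
    regions["colon"] = inside(col) & outside(cx0) & ~outside(cx1)
    volumes["colon"] = math.pi * (s * 2.5) ** 2 * (s * 16)
    t_l, v_t = ell("ph_testis_l", (2.0, -82, 0), (1.5, 1.5, 1.5))
    t_r, _ = ell("ph_testis_r", (-2.0, -82, 0), (1.5, 1.5, 1.5))
    regions["testes"] = t_l | t_r
    volumes["testes"] = 2 * v_t

    regions["skin"] = skin
    volumes["skin"] = v_skin

    organ_union = Union(tuple(regions[o] for o in ORGANS
                              if o not in ("skin", "residual_tissue")))
    regions["residual_tissue"] = interior & ~organ_union
    volumes["residual_tissue"] = v_interior - sum(
        volumes[o] for o in ORGANS if o not in ("skin", "residual_tissue"))

    points = {"P1": pt(2.0, -82, 0), "P2": pt(0, -35, 1), "P3": pt(-6, -18, 1),
              "P4": pt(8.5, 18, 0), "P5": pt(0, 75, 0)}
    return surfaces, regions, body, volumes, points


ORGAN_MATERIAL = {
    "skin": "skin_tissue", "skeleton": "bone", "spine": "bone",
    "brain": "soft_tissue", "esophagus": "soft_tissue", "heart": "soft_tissue",
    "left_lung": "lung_tissue", "right_lung": "lung_tissue",
    "liver": "soft_tissue", "colon": "soft_tissue", "testes": "soft_tissue",
    "residual_tissue": "soft_tissue",
}


def build_phantom(shift=(0.0, 0.0, 0.0), scale: float = 1.0) -> PhantomModel:
    """Assemble the stylized phantom (12 labelled tissue cells) at ``shift``."""
    surfaces, regions, body, volumes, points = _phantom_geometry(shift, scale)
    cells = []
    organ_cells = {}
    masses = {}
    for organ in ORGANS:
        mat = ORGAN_MATERIAL[organ]
        cell = Cell(f"organ_{organ}", regions[organ], mat,
                    is_tally_region=True, organ_label=organ,
                    volume=volumes[organ])
        cells.append(cell)
        organ_cells[organ] = cell
        masses[organ] = volumes[organ] * MATERIALS[mat].density
        if masses[organ] <= 0:
            raise ScenarioError(f"organ {organ} has non-positive mass")
    return PhantomModel(organ_cells, points, masses, tuple(shift), scale,
                        body, surfaces, cells)


# ---------------------------------------------------------------------------
# Treatment room
# ---------------------------------------------------------------------------


@dataclass
class TreatmentRoom:
    surfaces: list
    cells: list                 # concrete, maze air, control air, door
    main_air_box: Region        # to be intersected with exclusions at assembly
    world_region: Region
    inner_volume_m3: float
    control_volume_m3: float
    air_density: float


def build_room(wall_thickness: float = 100.0) -> TreatmentRoom:
    """The shielded treatment room with maze, control room and door.

    Inner room 13.7 x 9 x 4 m (x, y, z); floor 130 cm below the isocenter.
    The maze is a 2 m wide x 2.2 m high corridor through the -x wall at the
    +y end, leading to the 9.9 x 2 x 4 m control room behind that wall.
    """
    if wall_thickness <= 0:
        raise ScenarioError("wall thickness must be positive")
    t = wall_thickness
    X, Y = 685.0, 450.0          # inner half-extents, cm
    Z0, Z1 = -130.0, 270.0       # floor/ceiling
    surfaces = []

    def P(ctor, c, name):
        srf = ctor(c, name)
        surfaces.append(srf)
        return srf

    # main room box
    mx0, mx1 = P(plane_x, -X, "rm_x0"), P(plane_x, X, "rm_x1")
    my0, my1 = P(plane_y, -Y, "rm_y0"), P(plane_y, Y, "rm_y1")
    mz0, mz1 = P(plane_z, Z0, "rm_z0"), P(plane_z, Z1, "rm_z1")
    main_box = box_region(mx0, mx1, my0, my1, mz0, mz1)

    # maze corridor through the -x wall: 2 m wide (y), 2.2 m high (z)
    zx0 = P(plane_x, -X - t, "mz_x0")
    zy0 = P(plane_y, Y - 200.0, "mz_y0")
    zz1 = P(plane_z, Z0 + 220.0, "mz_z1")
    maze_box = (Halfspace(zx0.id, +1) & Halfspace(mx0.id, -1)
                & Halfspace(zy0.id, +1) & Halfspace(my1.id, -1)
                & Halfspace(mz0.id, +1) & Halfspace(zz1.id, -1))

    # control room behind the -x wall: 2 m (x) x 9.9 m (y) x 4 m (z)
    cx0 = P(plane_x, -X - t - 200.0, "cr_x0")
    cy0 = P(plane_y, Y - 990.0, "cr_y0")
    control_box = (Halfspace(cx0.id, +1) & Halfspace(zx0.id, -1)
                   & Halfspace(cy0.id, +1) & Halfspace(my1.id, -1)
                   & Halfspace(mz0.id, +1) & Halfspace(mz1.id, -1))

    # door: a thin slab closing the maze where it meets the control room
    dx0 = P(plane_x, -X - t - 3.0, "dr_x0")
    door_box = (Halfspace(dx0.id, +1) & Halfspace(zx0.id, -1)
                & Halfspace(zy0.id, +1) & Halfspace(my1.id, -1)
                & Halfspace(mz0.id, +1) & Halfspace(zz1.id, -1))

    # concrete envelope encloses main room, maze and control room
    ex0 = P(plane_x, -X - t - 200.0 - t, "ev_x0")
    ex1 = P(plane_x, X + t, "ev_x1")
    ey0, ey1 = P(plane_y, -Y - t, "ev_y0"), P(plane_y, Y + t, "ev_y1")
    ez0, ez1 = P(plane_z, Z0 - t, "ev_z0"), P(plane_z, Z1 + t, "ev_z1")
    envelope = box_region(ex0, ex1, ey0, ey1, ez0, ez1)

    concrete = envelope & ~main_box & ~maze_box & ~control_box
    cells = [
        Cell("room_concrete", concrete, "concrete"),
        Cell("maze_air", maze_box & ~door_box, "air"),
        Cell("door", door_box, "carbon_fiber"),
        Cell("control_air", control_box & ~maze_box & ~door_box, "air"),
    ]
    from .geometry import Complement
    return TreatmentRoom(
        surfaces, cells, main_box, Complement(envelope),
        inner_volume_m3=(2 * X) * (2 * Y) * (Z1 - Z0) / 1e6,
        control_volume_m3=200.0 * 990.0 * (Z1 - Z0) / 1e6,
        air_density=MATERIALS["air"].density)


# ---------------------------------------------------------------------------
# Linac head
# ---------------------------------------------------------------------------


@dataclass
class BeamlineModel:
    surfaces: list
    cells: list
    shapes: list                # regions to exclude from the room air
    source_position: tuple
    field_size: tuple
    scoring_plane_z: float


def build_beamline(field_size: float = 10.0) -> BeamlineModel:
    """Parameterised accelerator head stacked above the isocenter.

    Component dimensions are this package's documented defaults (they are not
    published for the modelled machine): tungsten primary collimator with a
    conical channel, beryllium vacuum window, copper scattering foil, ceramic
    and aluminium-alloy spacers and tungsten upper X-jaws whose opening
    projects to ``field_size`` cm at the isocenter plane.
    """
    if field_size <= 0:
        raise ScenarioError("field size must be positive")
    surfaces, cells, shapes = [], [], []

    def slab(name, material, r, z0, z1, hole=None):
        cyl = cylinder_z(0.0, 0.0, r, f"{name}_cyl")
        p0, p1 = plane_z(z0, f"{name}_z0"), plane_z(z1, f"{name}_z1")
        surfaces.extend((cyl, p0, p1))
        shape = inside(cyl) & outside(p0) & ~outside(p1)
        region = shape if hole is None else shape & ~hole
        cells.append(Cell(name, region, material))
        shapes.append(shape)

    # x-ray target disc (the photon source point sits just below it)
    slab("head_target", "tungsten", 1.5, 100.1, 100.6)
    # primary collimator: W cylinder with a conical channel opening downward
    cone = cone_z((0.0, 0.0, 100.0), 0.10, "head_pc_cone")
    pc_zcap = plane_z(100.0, "head_pc_zcap")
    surfaces.extend((cone, pc_zcap))
    cone_channel = inside(cone) & ~outside(pc_zcap)   # below the apex
    slab("head_primary_collimator", "tungsten", 8.0, 95.0, 99.5,
         hole=cone_channel)
    # the conical channel itself is air (the slab shape excludes it from the
    # room air cell, so it needs its own cell to keep space filled)
    pc_cyl = inside(cylinder_z(0.0, 0.0, 8.0, "head_primary_collimator_cyl"))
    channel = (cone_channel
               & Halfspace("head_primary_collimator_z0", +1)
               & Halfspace("head_primary_collimator_z1", -1)
               & pc_cyl)
    cells.append(Cell("head_pc_channel", channel, "air"))
    slab("head_vacuum_window", "beryllium", 6.0, 94.0, 94.2)
    slab("head_scattering_foil", "copper", 3.0, 92.0, 92.1)
    slab("head_ceramic_spacer", "ceramic", 6.0, 88.0, 88.5)
    slab("head_alloy_spacer", "aluminium", 6.0, 86.0, 86.5)

    # upper X-jaws: paired tungsten blocks, aperture projecting to the field
    half_at_bottom = 0.5 * field_size * (100.0 - 60.0) / 100.0
    jx_in_p = plane_x(half_at_bottom, "jaw_xp_in")
    jx_in_m = plane_x(-half_at_bottom, "jaw_xm_in")
    jx_out_p, jx_out_m = plane_x(15.0, "jaw_xp_out"), plane_x(-15.0, "jaw_xm_out")
    jy0, jy1 = plane_y(-15.0, "jaw_y0"), plane_y(15.0, "jaw_y1")
    jz0, jz1 = plane_z(60.0, "jaw_z0"), plane_z(68.0, "jaw_z1")
    surfaces.extend((jx_in_p, jx_in_m, jx_out_p, jx_out_m, jy0, jy1, jz0, jz1))
    for name, lo, hi in (("head_jaw_xp", jx_in_p, jx_out_p),
                         ("head_jaw_xm", jx_out_m, jx_in_m)):
        region = (Halfspace(lo.id, +1) & Halfspace(hi.id, -1)
                  & Halfspace(jy0.id, +1) & Halfspace(jy1.id, -1)
                  & Halfspace(jz0.id, +1) & Halfspace(jz1.id, -1))
        cells.append(Cell(name, region, "tungsten"))
        shapes.append(region)

    return BeamlineModel(surfaces, cells, shapes, (0.0, 0.0, SAD),
                         (field_size, field_size), scoring_plane_z=50.0)


# ---------------------------------------------------------------------------
# Scenario assembly
# ---------------------------------------------------------------------------


@dataclass
class Scenario:
    """A complete, runnable world: geometry + source + tally plan."""

    model: GeometryModel
    source: BeamSource
    tally_cells: dict               # cell id -> mass g (energy-deposition tallies)
    label: str = "scenario"
    target: Optional[str] = None    # P1..P5 for treatment scenarios
    phantom: Optional[PhantomModel] = None
    scoring_planes: tuple = ()      # (label, z): photon-crossing spectrum tallies
    path_tally_cells: tuple = ()    # cell ids scoring track length (fluence)
    build_params: dict = field(default_factory=dict)
    pdd_depths: Optional[list] = None
    pdd_bin_ids: Optional[list] = None

    def organ_of(self, cell_id: str) -> Optional[str]:
        return self.model.cell(cell_id).organ_label

    def validate(self) -> "Scenario":
        for cid, mass in self.tally_cells.items():
            if mass <= 0:
                raise ScenarioError(f"tally cell {cid} has non-positive mass")
            self.model.cell(cid)
        if self.target is not None:
            organ = TARGET_ORGAN[self.target]
            segs = self.model.ray_trace(self.source.position, (0.0, 0.0, -1.0))
            cells = [cid for cid, _ in segs]
            if f"organ_{organ}" not in cells:
                raise ScenarioError(
                    f"beam axis does not intersect target organ {organ}")
        return self


def _assemble(phantom_shift, target, field_size, source_mode, spectrum,
              phantom_scale, wall_thickness, label):
    room = build_room(wall_thickness)
    head = build_beamline(field_size)
    phantom = build_phantom(phantom_shift, phantom_scale)

    # patient couch: carbon-fibre slab under the phantom, moving with it
    sx, sy, sz = phantom.shift
    s = phantom.scale
    couch_x0 = plane_x(sx - 25.0, "couch_x0")
    couch_x1 = plane_x(sx + 25.0, "couch_x1")
    couch_y0 = plane_y(sy - s * 90.0, "couch_y0")
    couch_y1 = plane_y(sy + s * 90.0, "couch_y1")
    couch_z0 = plane_z(sz - s * 9.0 - 0.7, "couch_z0")
    couch_z1 = plane_z(sz - s * 9.0 - 0.2, "couch_z1")
    couch_srf = [couch_x0, couch_x1, couch_y0, couch_y1, couch_z0, couch_z1]
    couch_box = box_region(couch_x0, couch_x1, couch_y0, couch_y1,
                           couch_z0, couch_z1)
    couch = Cell("couch", couch_box, "carbon_fiber")

    exclusions = list(head.shapes) + [phantom.body_region, couch_box]
    main_air = room.main_air_box
    for shape in exclusions:
        main_air = main_air & ~shape
    cells = ([Cell("main_air", main_air, "air")] + room.cells + head.cells
             + phantom.cells
             + [couch, Cell("world", room.world_region, "vacuum", is_world=True)])
    surfaces = room.surfaces + head.surfaces + phantom.surfaces + couch_srf
    model = GeometryModel(surfaces, cells,
                          bounding_box=((-1085, 785), (-550, 550), (-230, 370)))

    if source_mode == "monoenergetic-point":
        source = cs137_source()
    else:
        if spectrum is None:
            energies, probs = synthetic_6mv_spectrum()
        else:
            energies, probs = spectrum
        source = BeamSource("spectrum-beam", (0.0, 0.0, SAD), energies, probs,
                            (field_size, field_size))

    tally = {f"organ_{o}": phantom.masses[o] for o in ORGANS}
    return Scenario(model, source, tally, label=label, target=target,
                    phantom=phantom,
                    scoring_planes=(("head_exit", head.scoring_plane_z),),
                    build_params=dict(field_size=field_size,
                                      source_mode=source_mode,
                                      spectrum=spectrum,
                                      phantom_scale=phantom_scale,
                                      wall_thickness=wall_thickness))


def assemble_treatment_scenario(target: str = "P4", field_size: float = 10.0,
                                source_mode: str = "spectrum-beam",
                                spectrum=None, phantom_scale: float = 1.0,
                                wall_thickness: float = 100.0) -> Scenario:
    """Full treatment world aimed at irradiation position ``target`` (P1..P5):
    the phantom is translated so the target point is at the isocenter, 100 cm
    below the source."""
    if target not in TARGET_ORGAN:
        raise ScenarioError(f"unknown target {target!r} (expected P1..P5)")
    base_points = _phantom_geometry((0.0, 0.0, 0.0), phantom_scale)[4]
    p = base_points[target]
    shift = (-p[0], -p[1], -p[2])
    return _assemble(shift, target, field_size, source_mode, spectrum,
                     phantom_scale, wall_thickness, label=f"treatment_{target}")


def aim_beam(scenario: Scenario, target: str) -> Scenario:
    """Re-aim an assembled treatment scenario at another irradiation position."""
    bp = scenario.build_params
    if not bp:
        raise ScenarioError("scenario was not built by assemble_treatment_scenario")
    return assemble_treatment_scenario(target, bp["field_size"],
                                       bp["source_mode"], bp["spectrum"],
                                       bp["phantom_scale"], bp["wall_thickness"])


# ---------------------------------------------------------------------------
# Water-phantom PDD benchmark
# ---------------------------------------------------------------------------


def build_water_phantom_benchmark(depth: float = 30.0, bin_width: float = 0.5,
                                  field_size: float = 10.0, spectrum=None,
                                  lateral_half: float = 1.0) -> Scenario:
    """Water tank for the percent-depth-dose benchmark: SSD 100 cm, field
    10 x 10 cm^2, central-axis depth bins of ``bin_width`` down to ``depth``.

    The water surface is at z = 0 with the source 100 cm above it; depth bins
    are (2 * lateral_half)^2 cm^2 columns centred on the beam axis.
    """
    n_bins = int(round(depth / bin_width))
    if abs(n_bins * bin_width - depth) > 1e-9 or n_bins < 2:
        raise ScenarioError("depth must be >= 2 whole bins")
    surfaces, cells = [], []

    wx0, wx1 = plane_x(-20.0, "wt_x0"), plane_x(20.0, "wt_x1")
    wy0, wy1 = plane_y(-20.0, "wt_y0"), plane_y(20.0, "wt_y1")
    wz0, wz1 = plane_z(-depth, "wt_z0"), plane_z(0.0, "wt_z1")
    surfaces += [wx0, wx1, wy0, wy1, wz0, wz1]
    tank = box_region(wx0, wx1, wy0, wy1, wz0, wz1)

    cx0, cx1 = plane_x(-lateral_half, "col_x0"), plane_x(lateral_half, "col_x1")
    cy0, cy1 = plane_y(-lateral_half, "col_y0"), plane_y(lateral_half, "col_y1")
    surfaces += [cx0, cx1, cy0, cy1]
    column = (Halfspace(cx0.id, +1) & Halfspace(cx1.id, -1)
              & Halfspace(cy0.id, +1) & Halfspace(cy1.id, -1))

    z_edges = [wz1] + [plane_z(-bin_width * k, f"bin_z{k}")
                       for k in range(1, n_bins + 1)]
    surfaces += z_edges[1:]
    bin_vol = (2 * lateral_half) ** 2 * bin_width
    tally = {}
    depths = []
    bin_ids = []
    for k in range(n_bins):
        region = (column & Halfspace(z_edges[k + 1].id, +1)
                  & Halfspace(z_edges[k].id, -1))
        cid = f"pdd_bin_{k:03d}"
        cells.append(Cell(cid, region, "water", is_tally_region=True,
                          volume=bin_vol))
        tally[cid] = bin_vol * MATERIALS["water"].density
        depths.append((k + 0.5) * bin_width)
        bin_ids.append(cid)

    whole_column = (column & Halfspace(z_edges[n_bins].id, +1)
                    & Halfspace(wz1.id, -1))
    cells.append(Cell("water_bulk", tank & ~whole_column, "water"))

    # air above and around the tank, inside a vacuum world
    ax0, ax1 = plane_x(-60.0, "air_x0"), plane_x(60.0, "air_x1")
    ay0, ay1 = plane_y(-60.0, "air_y0"), plane_y(60.0, "air_y1")
    az0, az1 = plane_z(-depth - 10.0, "air_z0"), plane_z(110.0, "air_z1")
    surfaces += [ax0, ax1, ay0, ay1, az0, az1]
    air_box = box_region(ax0, ax1, ay0, ay1, az0, az1)
    from .geometry import Complement
    cells.append(Cell("air", air_box & ~tank, "air"))
    cells.append(Cell("world", Complement(air_box), "vacuum", is_world=True))

    if spectrum is None:
        energies, probs = synthetic_6mv_spectrum()
    else:
        energies, probs = spectrum
    source = BeamSource("spectrum-beam", (0.0, 0.0, SAD), energies, probs,
                        (field_size, field_size))
    return Scenario(GeometryModel(surfaces, cells,
                                  bounding_box=((-60, 60), (-60, 60),
                                                (-depth - 10, 110))),
                    source, tally, label="water_pdd",
                    pdd_depths=depths, pdd_bin_ids=bin_ids)
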