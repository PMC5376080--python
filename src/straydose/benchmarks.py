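"""Analytic oracle worlds and reduced-scale presets.

Every transport claim is testable against one of these self-contained cases
without external data: exponential slab attenuation, Klein-Nishina moment
quadrature, inverse-square fluence in vacuum, dual-estimator agreement in
homogeneous water, and a three-organ mini phantom (target sphere, near shell,
far sphere in a soft-tissue trunk) that exercises the full
conversion-coefficient workflow in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .geometry import (Cell, Complement, GeometryModel, Halfspace, box_region,
                       cylinder_y, inside, outside, plane_x, plane_y, plane_z,
                       sphere)
from .physics import (MATERIALS, kn_mean_cosine, kn_mean_scattered_fraction,
                      kn_total_by_quadrature, kn_total_cross_section,
                      sample_compton)
from .scenario import BeamSource, Scenario
from .transport import RunConfig, run


@dataclass
class OracleCase:
    """A named check: run() -> (observed, sigma); compare with ``expected``."""

    name: str
    expected: float
    formula: str
    tolerance_policy: str            # "exact" | "3sigma" | "relative:<x>"
    run: Callable                    # (seed, n) -> (observed, sigma)
    default_n: int = 100_000

    def evaluate(self, seed: int = 1, n: Optional[int] = None) -> dict:
        observed, sigma = self.run(seed, n or self.default_n)
        if self.tolerance_policy == "3sigma":
            passed = abs(observed - self.expected) <= 3.0 * sigma
        elif self.tolerance_policy.startswith("relative:"):
            tol = float(self.tolerance_policy.split(":", 1)[1])
            passed = abs(observed - self.expected) <= tol * abs(self.expected)
        else:  # exact
            passed = observed == self.expected
        return {"name": self.name, "observed": observed,
                "expected": self.expected, "sigma": sigma,
                "passed": bool(passed), "formula": self.formula}


# ---------------------------------------------------------------------------
# Slab attenuation
# ---------------------------------------------------------------------------


def build_slab_scenario(optical_thickness: float, energy: float = 1.0) -> Scenario:
    """Water slab of the requested optical thickness, pencil beam at normal
    incidence, exit-plane crossing tally.  World is vacuum."""
    if optical_thickness <= 0:
        raise ValueError("optical thickness must be positive")
    water = MATERIALS["water"]
    thickness = optical_thickness / water.mu_total(energy)
    top, bottom = plane_z(0.0, "slab_top"), plane_z(-thickness, "slab_bottom")
    zlo = plane_z(-thickness - 2.0, "slab_zlo")
    zhi = plane_z(101.0, "slab_zhi")
    x0, x1 = plane_x(-50.0, "slab_x0"), plane_x(50.0, "slab_x1")
    y0, y1 = plane_y(-50.0, "slab_y0"), plane_y(50.0, "slab_y1")
    slab = box_region(x0, x1, y0, y1, bottom, top)
    above = box_region(x0, x1, y0, y1, top, zhi)
    below = box_region(x0, x1, y0, y1, zlo, bottom)
    enclosure = box_region(x0, x1, y0, y1, zlo, zhi)
    cells = [Cell("slab", slab, "water"),
             Cell("above", above, "vacuum"),
             Cell("below", below, "vacuum"),
             Cell("world", Complement(enclosure), "vacuum", is_world=True)]
    source = BeamSource("spectrum-beam", (0.0, 0.0, 100.0),
                        np.array([energy]), np.array([1.0]),
                        field_size=(1e-9, 1e-9))
    return Scenario(GeometryModel([top, bottom, zlo, zhi, x0, x1, y0, y1],
                                  cells,
                                  bounding_box=((-50, 50), (-50, 50),
                                                (-thickness - 2, 101))),
                    source, tally_cells={}, label=f"slab_tau_{optical_thickness:g}",
                    scoring_planes=(("exit", -thickness - 1.0),))


def make_slab_oracle(optical_thicknesses=(0.5, 1.0, 5.0)) -> list:
    """Uncollided-transmission cases: expectation exp(-tau), binomial sigma."""
    cases = []
    for tau in optical_thicknesses:
        expected = math.exp(-tau)

        def _run(seed, n, tau=tau, expected=expected):
            sc = build_slab_scenario(tau)
            res = run(sc, RunConfig(n_histories=n, n_batches=10, seed=seed,
                                    analog=True))
            observed = res.planes["exit"].uncollided_per_photon
            sigma = math.sqrt(expected * (1.0 - expected) / n)
            return observed, sigma

        cases.append(OracleCase(f"slab_tau_{tau:g}", expected,
                                "exp(-tau), analytic attenuation law",
                                "3sigma", _run))
    return cases


# ---------------------------------------------------------------------------
# Klein-Nishina moments
# ---------------------------------------------------------------------------


def make_kn_moment_oracle(energies=(0.2, 0.5, 0.6616, 2.0, 6.0)) -> list:
    """Sampled mean scattered-energy fraction and mean cosine vs quadrature.

    The quadrature oracles integrate the Klein-Nishina differential cross
    section directly and are independent of the rejection sampler they check.
    A quadrature self-check case verifies the closed-form total against the
    angular integral to 1e-8 relative.
    """
    cases = []
    for E in energies:
        exp_frac = kn_mean_scattered_fraction(E)
        exp_cos = kn_mean_cosine(E)

        def _run_frac(seed, n, E=E):
            rng = np.random.default_rng(seed)
            e_s, _, _ = sample_compton(E, rng, size=n)
            frac = e_s / E
            return float(frac.mean()), float(frac.std(ddof=1) / math.sqrt(n))

        def _run_cos(seed, n, E=E):
            rng = np.random.default_rng(seed)
            _, ct, _ = sample_compton(E, rng, size=n)
            return float(ct.mean()), float(ct.std(ddof=1) / math.sqrt(n))

        cases.append(OracleCase(f"kn_fraction_{E:g}", exp_frac,
                                "KN mean E'/E by adaptive quadrature",
                                "3sigma", _run_frac, default_n=1_000_000))
        cases.append(OracleCase(f"kn_cosine_{E:g}", exp_cos,
                                "KN mean cos(theta) by adaptive quadrature",
                                "3sigma", _run_cos, default_n=1_000_000))

        def _run_self(seed, n, E=E):
            return kn_total_by_quadrature(E) / kn_total_cross_section(E), 0.0

        cases.append(OracleCase(f"kn_quadrature_selfcheck_{E:g}", 1.0,
                                "closed-form KN total vs angular quadrature",
                                "relative:1e-8", _run_self, default_n=1))
    return cases


# ---------------------------------------------------------------------------
# Inverse-square fluence in vacuum
# ---------------------------------------------------------------------------


INVERSE_SQUARE_COS_CUT = 0.8     # polar caps subtend (1 - 0.8)/2 of 4 pi


def build_inverse_square_scenario(radii=(50.0, 100.0), dr: float = 0.5) -> Scenario:
    """Point isotropic source at the origin of a vacuum world with thin
    spherical-shell polar-cap track-length tallies at the requested radii.

    The caps sit on alternating poles so the crossing events of the two
    tallies are disjoint (genuinely stochastic, not perfectly correlated).
    For a central source the expected track length collected by a shell cap
    of thickness dr and solid angle Omega is exactly n * Omega * dr / (4 pi)
    at ANY radius - the 1/r^2 law: fluence falls exactly as the cap volume
    grows with r^2."""
    surfaces, cells = [], []
    shell_ids = []
    bounds = []
    for i, r in enumerate(sorted(radii)):
        s_in = sphere((0, 0, 0), r - dr / 2, f"shell{i}_in")
        s_out = sphere((0, 0, 0), r + dr / 2, f"shell{i}_out")
        zc = INVERSE_SQUARE_COS_CUT * r
        sign = 1 if i % 2 == 0 else -1
        cap_plane = plane_z(sign * zc, f"shell{i}_cap")
        surfaces += [s_in, s_out, cap_plane]
        bounds.append((s_in, s_out, cap_plane, sign))
        shell_ids.append(f"shell_{i}")
    cells.append(Cell("core", inside(bounds[0][0]), "vacuum"))
    for i, (s_in, s_out, cap_plane, sign) in enumerate(bounds):
        shell = inside(s_out) & ~inside(s_in)
        cap = (Halfspace(cap_plane.id, +1) if sign > 0
               else Halfspace(cap_plane.id, -1))
        cells.append(Cell(f"shell_{i}", shell & cap, "vacuum"))
        cells.append(Cell(f"shell_{i}_rest", shell & ~cap, "vacuum"))
        if i + 1 < len(bounds):
            cells.append(Cell(f"gap_{i}",
                              inside(bounds[i + 1][0]) & ~inside(s_out),
                              "vacuum"))
    cells.append(Cell("world", Complement(inside(bounds[-1][1])), "vacuum",
                      is_world=True))
    source = BeamSource("monoenergetic-point", (0.0, 0.0, 0.0),
                        np.array([1.0]), np.array([1.0]))
    rmax = sorted(radii)[-1] + dr
    return Scenario(GeometryModel(surfaces, cells,
                                  bounding_box=((-rmax, rmax),) * 3),
                    source, tally_cells={}, label="inverse_square",
                    path_tally_cells=tuple(shell_ids))


def _cap_volume(r_in, r_out, cos_cut) -> float:
    """Volume of a spherical-shell polar cap above |z| = cos_cut * r_mid."""
    zc = cos_cut * 0.5 * (r_in + r_out)

    def sphere_cap(R):
        h = R - zc
        return math.pi * h * h * (3 * R - h) / 3.0 if h > 0 else 0.0

    return sphere_cap(r_out) - sphere_cap(r_in)


def shell_fluence(result, scenario, radii=(50.0, 100.0), dr: float = 0.5) -> dict:
    """shell id -> (fluence cm^-2 per photon, relative error, cap volume)."""
    out = {}
    for i, r in enumerate(sorted(radii)):
        vol = _cap_volume(r - dr / 2, r + dr / 2, INVERSE_SQUARE_COS_CUT)
        mean, re = result.path_fluence[f"shell_{i}"]
        out[f"shell_{i}"] = (mean / vol, re, vol)
    return out


# ---------------------------------------------------------------------------
# Homogeneous-medium estimator agreement
# ---------------------------------------------------------------------------


def build_water_sphere_scenario(radius: float = 25.0,
                                energy: float = 1.0) -> Scenario:
    """Isotropic monoenergetic point source at the centre of a water sphere;
    the whole sphere is one energy-deposition tally (collision vs track-length
    estimators must agree)."""
    s = sphere((0, 0, 0), radius, "ws_sphere")
    vol = 4.0 / 3.0 * math.pi * radius ** 3
    cells = [Cell("water_ball", inside(s), "water", is_tally_region=True,
                  volume=vol),
             Cell("world", Complement(inside(s)), "vacuum", is_world=True)]
    source = BeamSource("monoenergetic-point", (0.0, 0.0, 0.0),
                        np.array([energy]), np.array([1.0]))
    return Scenario(GeometryModel([s], cells,
                                  bounding_box=((-radius, radius),) * 3),
                    source, {"water_ball": vol * MATERIALS["water"].density},
                    label="water_sphere")


# ---------------------------------------------------------------------------
# Mini phantom
# ---------------------------------------------------------------------------

MINI_ORGANS = ("target", "near_shell", "far_sphere")


def make_mini_phantom_scenario(field_size: float = 3.0,
                               energy: float = 2.0) -> Scenario:
    """Three-organ cut-down phantom for fast checks: a target sphere at the
    isocenter, a concentric near shell, and a far sphere displaced along the
    trunk axis (out of the beam), all inside a soft-tissue cylinder.  The
    collimated beam enters from above (-z), so conversion coefficients must
    order F(target)=1 > F(near) > F(far)."""
    rho = MATERIALS["soft_tissue"].density
    trunk = cylinder_y(0.0, 0.0, 8.0, "mini_trunk")
    t_lo, t_hi = plane_y(-20.0, "mini_y0"), plane_y(20.0, "mini_y1")
    s_target = sphere((0, 0, 0), 2.0, "mini_target")
    s_near_in = sphere((0, 0, 0), 3.0, "mini_near_in")
    s_near_out = sphere((0, 0, 0), 4.5, "mini_near_out")
    s_far = sphere((0, 13.0, 0), 2.0, "mini_far")
    bx0, bx1 = plane_x(-10.0, "mini_bx0"), plane_x(10.0, "mini_bx1")
    by0, by1 = plane_y(-25.0, "mini_by0"), plane_y(25.0, "mini_by1")
    bz0, bz1 = plane_z(-10.0, "mini_bz0"), plane_z(101.0, "mini_bz1")
    surfaces = [trunk, t_lo, t_hi, s_target, s_near_in, s_near_out, s_far,
                bx0, bx1, by0, by1, bz0, bz1]

    trunk_region = inside(trunk) & outside(t_lo) & ~outside(t_hi)
    target = inside(s_target)
    near = inside(s_near_out) & ~inside(s_near_in)
    far = inside(s_far)
    v_sphere = 4.0 / 3.0 * math.pi * 2.0 ** 3
    v_near = 4.0 / 3.0 * math.pi * (4.5 ** 3 - 3.0 ** 3)
    cells = [
        Cell("target", target, "soft_tissue", is_tally_region=True,
             organ_label="target", volume=v_sphere),
        Cell("near_shell", near, "soft_tissue", is_tally_region=True,
             organ_label="near_shell", volume=v_near),
        Cell("far_sphere", far, "soft_tissue", is_tally_region=True,
             organ_label="far_sphere", volume=v_sphere),
        Cell("gap", inside(s_near_in) & ~target, "soft_tissue"),
        Cell("trunk", trunk_region & ~inside(s_near_out) & ~far, "soft_tissue"),
        Cell("void", box_region(bx0, bx1, by0, by1, bz0, bz1) & ~trunk_region,
             "vacuum"),
        Cell("world", Complement(box_region(bx0, bx1, by0, by1, bz0, bz1)),
             "vacuum", is_world=True),
    ]
    source = BeamSource("spectrum-beam", (0.0, 0.0, 100.0),
                        np.array([energy]), np.array([1.0]),
                        field_size=(field_size, field_size))
    tally = {"target": v_sphere * rho, "near_shell": v_near * rho,
             "far_sphere": v_sphere * rho}
    return Scenario(GeometryModel(surfaces, cells,
                                  bounding_box=((-8, 8), (-20, 20), (-8, 8))),
                    source, tally, label="mini_phantom", target=None)


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------


def all_cases() -> dict:
    cases = {}
    for c in make_slab_oracle():
        cases[c.name] = c
    for c in make_kn_moment_oracle():
        cases[c.name] = c

    def _run_inv(seed, n):
        sc = build_inverse_square_scenario()
        res = run(sc, RunConfig(n_histories=n, n_batches=10, seed=seed,
                                analog=True))
        fl = shell_fluence(res, sc)
        (f1, re1, _), (f2, re2, _) = fl["shell_0"], fl["shell_1"]
        # effective-radius fluence ratio; expectation 1
        v1 = fl["shell_0"][2]
        v2 = fl["shell_1"][2]
        ratio = (f1 * v1) / (f2 * v2)
        sigma = ratio * math.hypot(re1, re2)
        return ratio, sigma

    cases["inverse_square"] = OracleCase(
        "inverse_square", 1.0,
        "equal expected track length in equal-thickness shells (1/r^2 law)",
        "3sigma", _run_inv, default_n=20_000)

    def _run_est(seed, n):
        sc = build_water_sphere_scenario()
        res = run(sc, RunConfig(n_histories=n, n_batches=10, seed=seed,
                                analog=True))
        t = res.tallies["water_ball"]
        diff = t.mean - t.mean_tracklength
        sigma = math.hypot(t.mean * t.rel_error,
                           t.mean_tracklength * t.rel_error_tracklength)
        return diff / t.mean, sigma / t.mean

    cases["estimator_agreement"] = OracleCase(
        "estimator_agreement", 0.0,
        "collision vs track-length deposition in homogeneous water",
        "3sigma", _run_est, default_n=20_000)

    return cases


def list_benchmarks() -> list:
    return sorted(all_cases())


def run_benchmark(name: str, seed: int = 1, n: Optional[int] = None) -> dict:
    cases = all_cases()
    if name not in cases:
        raise KeyError(f"unknown benchmark {name!r}; see list_benchmarks()")
    return cases[name].evaluate(seed, n)
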