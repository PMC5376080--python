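"""Photon interaction physics: materials, photo-atomic cross sections, sampling.

Covers the 0.01-10 MeV range needed for a 6 MV therapy beam: photoelectric
absorption, incoherent (Compton) scattering on free electrons in the
Klein-Nishina model, and pair production.  Secondary electrons are not
transported; every interaction deposits the energy transferred to electrons
at the interaction site (collision-kerma approximation).

The embedded elemental mass-attenuation tables are generated from documented
analytic models (see ``generate_element_table``):

* incoherent - exact free-electron Klein-Nishina total cross section times Z;
* photoelectric - a two-term parameterisation, ``Z^4.23 eps^-3.2`` at low
  energy plus the relativistic K-shell asymptote ``~Z^5/eps``, calibrated to
  standard reference anchor values and held constant below the (Moseley
  estimate of the) K edge;
* pair - a Born-type universal reduced function of ``eps = E/m_e c^2`` scaled
  by ``Z(Z+1)`` to fold in triplet production.

Absorption edges and coherent (Rayleigh) scattering are not modelled; the
methods note discusses the consequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Optional

import numpy as np
from scipy import integrate

# -- constants ---------------------------------------------------------------

MEC2 = 0.511                 # electron rest energy, MeV
R_E = 2.8179403262e-13       # classical electron radius, cm
ALPHA_FS = 7.2973525693e-3   # fine-structure constant
N_A = 6.02214076e23          # Avogadro, 1/mol
PAIR_THRESHOLD = 2.0 * MEC2  # 1.022 MeV
MEV_PER_GRAM_TO_GY = 1.602176634e-10

#: (Z, atomic mass g/mol) for every element the embedded library ships.
ELEMENTS = {
    "H": (1, 1.008), "Be": (4, 9.012), "C": (6, 12.011), "N": (7, 14.007),
    "O": (8, 15.999), "Na": (11, 22.990), "Mg": (12, 24.305),
    "Al": (13, 26.982), "Si": (14, 28.085), "P": (15, 30.974),
    "S": (16, 32.06), "Cl": (17, 35.45), "Ar": (18, 39.948),
    "K": (19, 39.098), "Ca": (20, 40.078), "Fe": (26, 55.845),
    "Cu": (29, 63.546), "W": (74, 183.84), "Pb": (82, 207.2),
}

ENERGY_GRID = np.geomspace(0.01, 10.0, 60)


class PhysicsError(Exception):
    pass


# ---------------------------------------------------------------------------
# Klein-Nishina (free electron)
# ---------------------------------------------------------------------------


def kn_total_cross_section(E: float) -> float:
    """Total Klein-Nishina cross section per electron (cm^2) at photon energy E (MeV)."""
    e = E / MEC2
    if e < 1e-6:
        # Thomson limit with first-order correction, avoids cancellation
        return (8.0 / 3.0) * math.pi * R_E * R_E * (1.0 - 2.0 * e)
    l = math.log(1.0 + 2.0 * e)
    term = ((1.0 + e) / (e * e)) * (2.0 * (1.0 + e) / (1.0 + 2.0 * e) - l / e)
    return 2.0 * math.pi * R_E * R_E * (
        term + l / (2.0 * e) - (1.0 + 3.0 * e) / (1.0 + 2.0 * e) ** 2)


def kn_differential(E: float, mu):
    """Klein-Nishina dsigma/dmu (cm^2 per electron per unit scattering cosine)."""
    e = E / MEC2
    mu = np.asarray(mu, dtype=float)
    eps = 1.0 / (1.0 + e * (1.0 - mu))       # E'/E
    return math.pi * R_E * R_E * eps * eps * (eps + 1.0 / eps - (1.0 - mu * mu))


def kn_total_by_quadrature(E: float) -> float:
    """Angular integral of the differential cross section (independent check)."""
    val, _ = integrate.quad(lambda m: kn_differential(E, m), -1.0, 1.0,
                            epsabs=0.0, epsrel=1e-11)
    return val


@lru_cache(maxsize=4096)
def kn_mean_scattered_fraction(E: float) -> float:
    """Mean E'/E of a Compton scatter at energy E, by adaptive quadrature."""
    e = E / MEC2
    def integrand(m):
        eps = 1.0 / (1.0 + e * (1.0 - m))
        return eps * kn_differential(E, m)
    num, _ = integrate.quad(integrand, -1.0, 1.0, epsabs=0.0, epsrel=1e-10)
    return num / kn_total_cross_section(E)


_MEAN_FRAC_TABLE = None


def kn_mean_scattered_fraction_fast(E: float) -> float:
    """Interpolated ``kn_mean_scattered_fraction`` for the tracking hot path
    (log-energy grid built lazily from the quadrature values)."""
    global _MEAN_FRAC_TABLE
    if _MEAN_FRAC_TABLE is None:
        grid = np.geomspace(0.008, 12.0, 160)
        vals = np.array([kn_mean_scattered_fraction(float(e)) for e in grid])
        _MEAN_FRAC_TABLE = (np.log(grid), vals)
    return float(np.interp(math.log(E), *_MEAN_FRAC_TABLE))


@lru_cache(maxsize=4096)
def kn_mean_cosine(E: float) -> float:
    """Mean scattering cosine of a Compton scatter at energy E."""
    # absolute tolerance scaled to the cross section: the integrand is nearly
    # odd at low E, so a pure relative target is unattainable near zero
    num, _ = integrate.quad(lambda m: m * kn_differential(E, m), -1.0, 1.0,
                            epsabs=1e-8 * kn_total_cross_section(E),
                            epsrel=1e-10)
    return num / kn_total_cross_section(E)


def compton_scattered_energy(E: float, cos_theta: float) -> float:
    """Compton kinematics: scattered photon energy for incident E and angle."""
    return E / (1.0 + (E / MEC2) * (1.0 - cos_theta))


# ---------------------------------------------------------------------------
# Elemental cross-section models (table generators)
# ---------------------------------------------------------------------------

# photoelectric fit constants (cm^2 per atom, eps = E / MEC2)
_PE_LOW_C = 7.705e-32
_PE_LOW_ZEXP = 4.23
_PE_LOW_EEXP = 3.2
_PE_HIGH_C = 1.875 * (8.0 / 3.0) * math.pi * R_E * R_E * ALPHA_FS ** 4  # K-shell asymptote x shell factor


def k_edge_energy(Z: int) -> float:
    """Moseley estimate of the K-shell binding energy, MeV."""
    return 13.6e-6 * (Z - 0.3) ** 2  # 13.6 eV * (Z-0.3)^2, in MeV


def photoelectric_cross_section(Z: int, E: float) -> float:
    """Photoelectric cross section per atom (cm^2); smooth fit, no edges."""
    E_eff = max(E, k_edge_energy(Z))
    eps = E_eff / MEC2
    low = _PE_LOW_C * Z ** _PE_LOW_ZEXP * eps ** (-_PE_LOW_EEXP)
    high = _PE_HIGH_C * Z ** 5 / eps
    return low + high


def pair_cross_section(Z: int, E: float) -> float:
    """Pair (+ triplet) production cross section per atom (cm^2)."""
    eps = E / MEC2
    if eps <= 2.0:
        return 0.0
    reduced = 1.45 * ((eps - 2.0) / eps) ** 3 * (math.log(eps) + 0.2)
    return ALPHA_FS * R_E * R_E * Z * (Z + 1) * reduced


def generate_element_table(symbol: str, grid: Optional[np.ndarray] = None) -> np.ndarray:
    """(n, 4) array of energy (MeV) and mass-attenuation partials (cm^2/g):
    photoelectric, incoherent, pair.  This is the generator behind the shipped
    CSV resources; re-running it must reproduce them."""
    Z, A = ELEMENTS[symbol]
    grid = ENERGY_GRID if grid is None else grid
    atoms_per_gram = N_A / A
    out = np.empty((len(grid), 4))
    for i, E in enumerate(grid):
        out[i, 0] = E
        out[i, 1] = photoelectric_cross_section(Z, E) * atoms_per_gram
        out[i, 2] = kn_total_cross_section(E) * Z * atoms_per_gram
        out[i, 3] = pair_cross_section(Z, E) * atoms_per_gram
    return out


# ---------------------------------------------------------------------------
# Cross-section tables (loaded from the shipped CSV resources)
# ---------------------------------------------------------------------------

INTERACTIONS = ("photoelectric", "compton", "pair")


@dataclass
class CrossSectionTable:
    """Elemental mass-attenuation partials on an ascending energy grid."""

    element: str
    energy_grid: np.ndarray
    mu_over_rho_photoelectric: np.ndarray
    mu_over_rho_incoherent: np.ndarray
    mu_over_rho_pair: np.ndarray

    def __post_init__(self):
        g = self.energy_grid
        if not np.all(np.diff(g) > 0):
            raise PhysicsError(f"{self.element}: energy grid not strictly ascending")
        for arr in (self.mu_over_rho_photoelectric, self.mu_over_rho_incoherent,
                    self.mu_over_rho_pair):
            if np.any(arr < 0):
                raise PhysicsError(f"{self.element}: negative coefficient")
        self._log_e = np.log(g)
        self._log_pe = np.log(self.mu_over_rho_photoelectric)
        self._log_inc = np.log(self.mu_over_rho_incoherent)
        pos = self.mu_over_rho_pair > 0
        self._pair_log_e = np.log(g[pos]) if pos.any() else None
        self._pair_log = np.log(self.mu_over_rho_pair[pos]) if pos.any() else None

    @property
    def total(self) -> np.ndarray:
        return (self.mu_over_rho_photoelectric + self.mu_over_rho_incoherent
                + self.mu_over_rho_pair)

    def _check_range(self, E: float):
        if not (self.energy_grid[0] <= E <= self.energy_grid[-1]):
            raise PhysicsError(
                f"{self.element}: energy {E} MeV outside table range "
                f"[{self.energy_grid[0]}, {self.energy_grid[-1]}]")

    def mu_rho(self, E: float, interaction: str) -> float:
        """Log-log interpolated mass-attenuation partial, cm^2/g."""
        self._check_range(E)
        le = math.log(E)
        if interaction == "photoelectric":
            return math.exp(np.interp(le, self._log_e, self._log_pe))
        if interaction == "compton":
            return math.exp(np.interp(le, self._log_e, self._log_inc))
        if interaction == "pair":
            if E <= PAIR_THRESHOLD or self._pair_log_e is None or le < self._pair_log_e[0]:
                return 0.0
            return math.exp(np.interp(le, self._pair_log_e, self._pair_log))
        raise PhysicsError(f"unknown interaction {interaction!r}")

    @classmethod
    def from_array(cls, element: str, arr: np.ndarray) -> "CrossSectionTable":
        return cls(element, arr[:, 0].copy(), arr[:, 1].copy(), arr[:, 2].copy(),
                   arr[:, 3].copy())


@lru_cache(maxsize=None)
def load_table(element: str) -> CrossSectionTable:
    """Load the shipped CSV table for one element."""
    if element not in ELEMENTS:
        raise PhysicsError(f"element {element!r} not in the embedded library")
    ref = resources.files("straydose.data.xs").joinpath(f"{element}.csv")
    arr = np.loadtxt(str(ref), delimiter=",", skiprows=1)
    return CrossSectionTable.from_array(element, arr)


# ---------------------------------------------------------------------------
# Materials
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Material:
    name: str
    density: float                      # g/cm3
    composition: tuple                  # ((symbol, mass fraction), ...)

    def __post_init__(self):
        comp = tuple((s, float(w)) for s, w in self.composition)
        object.__setattr__(self, "composition", comp)
        if self.name == "vacuum":
            return
        if self.density <= 0:
            raise PhysicsError(f"{self.name}: density must be > 0")
        total = sum(w for _, w in comp)
        if abs(total - 1.0) > 1e-6:
            raise PhysicsError(f"{self.name}: mass fractions sum to {total}")
        for s, _ in comp:
            if s not in ELEMENTS:
                raise PhysicsError(f"{self.name}: element {s} not in library")

    @property
    def is_vacuum(self) -> bool:
        return self.name == "vacuum" or self.density == 0.0

    def mu_partial(self, E: float, interaction: str, density: Optional[float] = None) -> float:
        """Macroscopic partial attenuation coefficient, cm^-1."""
        if self.is_vacuum:
            return 0.0
        rho = self.density if density is None else density
        return rho * sum(w * load_table(s).mu_rho(E, interaction)
                         for s, w in self.composition)

    def mu_total(self, E: float, density: Optional[float] = None) -> float:
        """Total linear attenuation coefficient, cm^-1 (mixture rule)."""
        return sum(self.mu_partial(E, i, density) for i in INTERACTIONS)

    def mu_partials(self, E: float, density: Optional[float] = None):
        """(photoelectric, compton, pair) macroscopic coefficients at once."""
        return tuple(self.mu_partial(E, i, density) for i in INTERACTIONS)

    def mu_heating(self, E: float, density: Optional[float] = None) -> float:
        """Energy-absorption-style coefficient (cm^-1): each partial weighted
        by the mean fraction of E handed to electrons under the local-deposition
        model.  Used by the track-length heating estimator."""
        pe, co, pr = self.mu_partials(E, density)
        f_c = 1.0 - kn_mean_scattered_fraction_fast(float(E)) if co > 0 else 0.0
        f_p = max(0.0, (E - PAIR_THRESHOLD) / E) if pr > 0 else 0.0
        return pe * 1.0 + co * f_c + pr * f_p


VACUUM = Material("vacuum", 0.0, ())

_SOFT = (("H", 0.101), ("C", 0.111), ("N", 0.026), ("O", 0.762))

#: Built-in material library.  Densities in g/cm3; the concrete and air values
#: are the treatment-room defaults (ordinary concrete 2.35, air 0.00129).
MATERIALS = {
    "vacuum": VACUUM,
    "water": Material("water", 1.0, (("H", 0.1119), ("O", 0.8881))),
    "air": Material("air", 0.00129, (("N", 0.755), ("O", 0.232), ("Ar", 0.013))),
    "concrete": Material("concrete", 2.35, (
        ("H", 0.010), ("C", 0.001), ("O", 0.529), ("Na", 0.016), ("Mg", 0.002),
        ("Al", 0.034), ("Si", 0.337), ("K", 0.013), ("Ca", 0.044), ("Fe", 0.014))),
    "soft_tissue": Material("soft_tissue", 1.04, _SOFT),
    "lung_tissue": Material("lung_tissue", 0.296, _SOFT),
    "skin_tissue": Material("skin_tissue", 1.05, _SOFT),
    "bone": Material("bone", 1.4, (
        ("H", 0.034), ("C", 0.155), ("N", 0.042), ("O", 0.435), ("Na", 0.001),
        ("Mg", 0.002), ("P", 0.103), ("S", 0.003), ("Ca", 0.225))),
    "tungsten": Material("tungsten", 19.3, (("W", 1.0),)),
    "lead": Material("lead", 11.35, (("Pb", 1.0),)),
    "copper": Material("copper", 8.96, (("Cu", 1.0),)),
    "aluminium": Material("aluminium", 2.699, (("Al", 1.0),)),
    "beryllium": Material("beryllium", 1.848, (("Be", 1.0),)),
    "carbon_fiber": Material("carbon_fiber", 1.6, (("C", 1.0),)),
    "ceramic": Material("ceramic", 3.9, (("Al", 0.5293), ("O", 0.4707))),
}


# ---------------------------------------------------------------------------
# Photon state
# ---------------------------------------------------------------------------


@dataclass
class PhotonState:
    """Phase-space point of one photon history."""

    position: tuple          # cm
    direction: tuple         # unit vector
    energy: float            # MeV
    weight: float = 1.0
    alive: bool = True
    collided: bool = False


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def sample_free_path(mu: float, rng: np.random.Generator) -> float:
    """Exponential free path (cm) for total coefficient mu (cm^-1)."""
    if mu <= 0.0:
        raise PhysicsError("sample_free_path requires mu > 0")
    return -math.log(1.0 - rng.random()) / mu


def sample_interaction(material: Material, E: float, rng: np.random.Generator,
                       density: Optional[float] = None) -> str:
    """Draw 'photoelectric' | 'compton' | 'pair' proportional to the partials."""
    parts = material.mu_partials(E, density)
    total = sum(parts)
    if total <= 0.0:
        raise PhysicsError(f"no interaction possible in {material.name} at {E} MeV")
    r = rng.random() * total
    acc = 0.0
    for tag, p in zip(INTERACTIONS, parts):
        acc += p
        if r <= acc:
            return tag
    return INTERACTIONS[-1]


def sample_compton(E: float, rng: np.random.Generator, size: Optional[int] = None):
    """Klein-Nishina Compton scatter.

    Scalar call returns ``(E_scattered, cos_theta, E_deposited)``; with ``size``
    the three are arrays.  Sampling uses the standard mixture-rejection scheme
    on eps = E'/E in [1/(1+2a), 1] with a = E/MEC2: the bounding density is a
    mixture of 1/eps and eps terms, accepted with probability
    1 - eps sin^2(theta) / (1 + eps^2).
    """
    a = E / MEC2
    eps0 = 1.0 / (1.0 + 2.0 * a)
    w1 = -math.log(eps0)            # integral of 1/eps over [eps0, 1]
    w2 = 0.5 * (1.0 - eps0 * eps0)  # integral of eps

    scalar = size is None
    n = 1 if scalar else int(size)
    eps = np.empty(n)
    pending = np.arange(n)
    while pending.size:
        m = pending.size
        r1 = rng.random(m)
        r2 = rng.random(m)
        r3 = rng.random(m)
        cand = np.where(r1 < w1 / (w1 + w2),
                        eps0 * np.exp(w1 * r2),
                        np.sqrt(eps0 * eps0 + (1.0 - eps0 * eps0) * r2))
        t = (1.0 - cand) / (a * cand)
        sin2 = t * (2.0 - t)
        accept = r3 <= 1.0 - cand * sin2 / (1.0 + cand * cand)
        eps[pending[accept]] = cand[accept]
        pending = pending[~accept]

    cos_theta = 1.0 - (1.0 - eps) / (a * eps)
    e_scat = E * eps
    e_dep = E - e_scat
    if scalar:
        return float(e_scat[0]), float(cos_theta[0]), float(e_dep[0])
    return e_scat, cos_theta, e_dep


def sample_pair(E: float, rng: np.random.Generator):
    """Pair production with local electron/positron energy deposition.

    Returns ``(deposited, [(energy, direction), (energy, direction)])`` - the
    two annihilation quanta at MEC2 each, antiparallel with isotropic axis.
    """
    if E < PAIR_THRESHOLD:
        raise PhysicsError(f"pair production below threshold: {E} MeV")
    deposited = E - PAIR_THRESHOLD
    d = isotropic_direction(rng)
    return deposited, [(MEC2, d), (MEC2, (-d[0], -d[1], -d[2]))]


def isotropic_direction(rng: np.random.Generator):
    """Uniform direction on the unit sphere."""
    mu = 2.0 * rng.random() - 1.0
    phi = 2.0 * math.pi * rng.random()
    s = math.sqrt(max(0.0, 1.0 - mu * mu))
    return (s * math.cos(phi), s * math.sin(phi), mu)


def rotate_direction(u, cos_theta: float, phi: float):
    """Rotate unit vector u by polar angle (cosine given) about itself with
    azimuth phi, returning a unit vector."""
    ux, uy, uz = u
    sin_theta = math.sqrt(max(0.0, 1.0 - cos_theta * cos_theta))
    cp, sp = math.cos(phi), math.sin(phi)
    if abs(uz) < 0.99999:
        den = math.sqrt(1.0 - uz * uz)
        vx = (ux * uz * cp - uy * sp) / den
        vy = (uy * uz * cp + ux * sp) / den
        vz = -den * cp
        wx = ux * cos_theta + vx * sin_theta
        wy = uy * cos_theta + vy * sin_theta
        wz = uz * cos_theta + vz * sin_theta
    else:
        # beam along +/- z: rotate about x/y directly
        sign = 1.0 if uz > 0 else -1.0
        wx = sin_theta * cp
        wy = sign * sin_theta * sp
        wz = sign * cos_theta
    norm = math.sqrt(wx * wx + wy * wy + wz * wz)
    return (wx / norm, wy / norm, wz / norm)
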