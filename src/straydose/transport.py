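"""The Monte Carlo history loop: emit, track, interact, score.

Estimators
----------
* collision estimator (primary): the energy handed to electrons at each
  interaction is deposited at the interaction site and scored per tally cell
  in MeV/g per source photon;
* track-length heating estimator (cross-check): every chord in a tally cell
  scores ``w * L * mu_heat(E) * E / mass`` with the energy-absorption-style
  coefficient from the material tables.  Under the local-deposition model the
  two have the same expectation, which gives an internal consistency test.

Statistics are by batch means: the run is split into ``n_batches`` contiguous
blocks of histories and the relative error of a tally is the standard error
of the batch means divided by the grand mean (flagged converged at the
configured target, default 0.4%).

Reproducibility contract: each history draws from its own counter-based
random stream keyed by (seed, history index), and workers process whole
batches that are recombined in batch order - so results are bit-identical
for any worker count.
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import SURFACE_NUDGE, TrackingError
from .physics import (MATERIALS, PAIR_THRESHOLD, PhysicsError, isotropic_direction,
                      rotate_direction, sample_compton)

#: energy-bin edges (MeV) for surface-crossing spectrum tallies
PLANE_ENERGY_EDGES = np.linspace(0.0, 6.5, 131)

#: abort threshold on the lost-history fraction (geometry-bug tripwire)
LOST_FRACTION_LIMIT = 1e-6


class RunError(Exception):
    pass


@dataclass
class RunConfig:
    """Execution parameters for one Monte Carlo run."""

    n_histories: int
    n_batches: int = 20
    seed: int = 1
    cutoff: float = 0.01                 # MeV; below, energy is deposited locally
    roulette_threshold: float = 0.01     # weight
    roulette_survival: float = 0.1       # weight after surviving roulette
    workers: int = 1
    analog: bool = False                 # disable implicit capture / roulette
    target_relative_error: Optional[float] = 0.004
    track_histories: int = 0             # record segment tracks for first N histories

    def __post_init__(self):
        if self.n_batches < 2:
            raise RunError("need at least 2 batches for statistics")
        if self.n_histories < self.n_batches:
            raise RunError("n_histories must be >= n_batches")
        if self.cutoff < 0.01 - 1e-12:
            raise RunError("cutoff below the cross-section table minimum")
        if self.workers < 1:
            raise RunError("workers must be >= 1")


def history_rng(seed: int, index: int) -> np.random.Generator:
    """Counter-based stream for one history; independent of worker layout."""
    return np.random.Generator(np.random.Philox(key=(seed << 40) + index))


# ---------------------------------------------------------------------------
# Accumulators and results
# ---------------------------------------------------------------------------


class TallyAccumulator:
    """Per-batch sums of history scores."""

    def __init__(self, n_tally: int, n_path: int, plane_labels):
        self.dep = np.zeros(n_tally)          # MeV/g, collision estimator
        self.dep_tl = np.zeros(n_tally)       # MeV/g, track-length estimator
        self.path = np.zeros(n_path)          # cm (weighted track length)
        self.n = 0
        self.lost = 0
        self.emitted = 0.0                    # MeV
        self.deposited = 0.0                  # MeV, all cells
        self.escaped = 0.0                    # MeV
        self.rouletted = 0.0                  # MeV removed by roulette kills
        self.plane_w = {lbl: 0.0 for lbl in plane_labels}
        self.plane_w_uncollided = {lbl: 0.0 for lbl in plane_labels}
        self.plane_we = {lbl: 0.0 for lbl in plane_labels}
        self.plane_hist = {lbl: np.zeros(len(PLANE_ENERGY_EDGES) - 1)
                           for lbl in plane_labels}
        self.tracks = []                      # (history, x, y, z, cell, E)


def estimate_relative_error(batch_means) -> tuple:
    """(mean, relative error) from batch means: RE = SE(mean of batches)/mean.

    A zero mean has undefined relative error and reports ``nan``.
    """
    m = np.asarray(batch_means, dtype=float)
    if m.ndim != 1 or len(m) < 2:
        raise RunError("need >= 2 batch means")
    mean = m.mean()
    se = m.std(ddof=1) / math.sqrt(len(m))
    if mean == 0.0:
        return 0.0, float("nan")
    return float(mean), float(abs(se / mean))


@dataclass
class TallyResult:
    cell_id: str
    organ: Optional[str]
    mass: float                   # g
    mean: float                   # MeV/g per source photon (collision)
    rel_error: float
    mean_tracklength: float       # MeV/g per source photon (track length)
    rel_error_tracklength: float
    converged: bool


@dataclass
class PlaneTally:
    label: str
    crossings_per_photon: float
    uncollided_per_photon: float
    mean_energy: float            # MeV of crossing photons
    energy_edges: np.ndarray
    energy_counts: np.ndarray     # weight per bin, per source photon


@dataclass
class RunResult:
    label: str
    seed: int
    n_histories: int
    n_batches: int
    tallies: dict                 # cell id -> TallyResult
    planes: dict                  # label -> PlaneTally
    path_fluence: dict            # cell id -> (mean cm per photon, rel err)
    lost_histories: int
    emitted_energy: float         # MeV total
    deposited_energy: float
    escaped_energy: float
    rouletted_energy: float
    batch_dep: np.ndarray         # (n_batches, n_tally) per-history means
    tally_ids: list
    tracks: list = field(default_factory=list)   # (history, x, y, z, cell, E)

    def by_organ(self) -> dict:
        """organ label -> (dose MeV/g/photon, relative error)."""
        out = {}
        for t in self.tallies.values():
            if t.organ is not None:
                out[t.organ] = (t.mean, t.rel_error)
        return out


# ---------------------------------------------------------------------------
# The runner
# ---------------------------------------------------------------------------


class _Runner:
    """Holds the per-run precomputed context for the history loop."""

    def __init__(self, scenario, config: RunConfig):
        scenario.validate()
        self.scenario = scenario
        self.config = config
        self.model = scenario.model
        self.tally_ids = sorted(scenario.tally_cells)
        self.tally_index = {cid: i for i, cid in enumerate(self.tally_ids)}
        self.tally_mass = np.array([scenario.tally_cells[c] for c in self.tally_ids])
        self.path_ids = list(scenario.path_tally_cells)
        self.path_index = {cid: i for i, cid in enumerate(self.path_ids)}
        self.planes = list(scenario.scoring_planes)
        self.plane_labels = [lbl for lbl, _ in self.planes]
        # cell id -> (material, density, tally idx | -1, path idx | -1, is_world)
        self.cell_info = {}
        for cell in self.model.cells:
            mat = MATERIALS[cell.material_id]
            dens = cell.density_override if cell.density_override is not None \
                else mat.density
            self.cell_info[cell.id] = (
                mat, dens, self.tally_index.get(cell.id, -1),
                self.path_index.get(cell.id, -1), cell.is_world)
        self.source_cell = self.model.locate_point(scenario.source.position)

    # -- single history -----------------------------------------------------

    def run_history(self, index: int, acc: TallyAccumulator):
        cfg = self.config
        rng = history_rng(cfg.seed, index)
        pos, direction, E0 = self.scenario.source.sample(rng)
        acc.emitted += E0
        acc.n += 1
        record = index if index < cfg.track_histories else None
        stack = [(pos, direction, E0, 1.0, False, self.source_cell)]
        try:
            while stack:
                self._track(stack.pop(), stack, acc, rng, record)
        except TrackingError:
            acc.lost += 1

    def _score_segment(self, cell_entry, p, u, L, E, w, collided, acc,
                       mat, dens):
        _, _, t_idx, p_idx, _ = cell_entry
        if t_idx >= 0 and not mat.is_vacuum:
            acc.dep_tl[t_idx] += (w * L * mat.mu_heating(E, dens) * E
                                  / self.tally_mass[t_idx])
        if p_idx >= 0:
            acc.path[p_idx] += w * L
        if self.planes:
            z0 = p[2]
            z1 = p[2] + L * u[2]
            for lbl, zp in self.planes:
                if (z0 - zp) * (z1 - zp) < 0.0:
                    acc.plane_w[lbl] += w
                    acc.plane_we[lbl] += w * E
                    if not collided:
                        acc.plane_w_uncollided[lbl] += w
                    b = np.searchsorted(PLANE_ENERGY_EDGES, E) - 1
                    if 0 <= b < len(acc.plane_hist[lbl]):
                        acc.plane_hist[lbl][b] += w

    def _deposit(self, t_idx, amount_energy, acc):
        acc.deposited += amount_energy
        if t_idx >= 0:
            acc.dep[t_idx] += amount_energy / self.tally_mass[t_idx]

    def _track(self, photon, stack, acc, rng, record=None):
        cfg = self.config
        model = self.model
        (x, y, z), (ux, uy, uz), E, w, collided, cell = photon
        info = self.cell_info[cell.id]
        mat, dens, t_idx = info[0], info[1], info[2]
        if E < cfg.cutoff:
            self._deposit(t_idx, w * E, acc)
            return
        for _ in range(100_000):
            if record is not None:
                acc.tracks.append((record, x, y, z, cell.id, E))
            if info[4]:                     # world: escape
                acc.escaped += w * E
                return
            if mat.is_vacuum:
                s = math.inf
            else:
                mu = mat.mu_total(E, dens)
                s = (-math.log(1.0 - rng.random()) / mu) if mu > 0 else math.inf
            d, sid = model.distance_to_boundary((x, y, z), (ux, uy, uz), cell)
            if s < d:
                # collision
                self._score_segment(info, (x, y, z), (ux, uy, uz), s, E, w,
                                    collided, acc, mat, dens)
                x += s * ux
                y += s * uy
                z += s * uz
                collided = True
                pe, co, pr = mat.mu_partials(E, dens)
                total = pe + co + pr
                if total <= 0:
                    raise PhysicsError(
                        f"no interaction possible in {mat.name} at {E} MeV")
                if cfg.analog:
                    r = rng.random() * total
                    if r <= pe:
                        self._deposit(t_idx, w * E, acc)
                        return
                    tag = "compton" if r <= pe + co else "pair"
                else:
                    # implicit capture of the photoelectric channel
                    f_pe = pe / total
                    self._deposit(t_idx, w * E * f_pe, acc)
                    w *= (1.0 - f_pe)
                    rest = co + pr
                    if rest <= 0 or w <= 0:
                        return
                    tag = "compton" if rng.random() * rest <= co else "pair"
                if tag == "compton":
                    e_scat, cos_t, e_dep = sample_compton(E, rng)
                    self._deposit(t_idx, w * e_dep, acc)
                    phi = 2.0 * math.pi * rng.random()
                    ux, uy, uz = rotate_direction((ux, uy, uz), cos_t, phi)
                    E = e_scat
                else:
                    self._deposit(t_idx, w * (E - PAIR_THRESHOLD), acc)
                    dvec = isotropic_direction(rng)
                    stack.append(((x, y, z), dvec, 0.511, w, True, cell))
                    ux, uy, uz = -dvec[0], -dvec[1], -dvec[2]
                    E = 0.511
                if E < cfg.cutoff:
                    self._deposit(t_idx, w * E, acc)
                    return
                if not cfg.analog and w < cfg.roulette_threshold:
                    if rng.random() < w / cfg.roulette_survival:
                        w = cfg.roulette_survival
                    else:
                        acc.rouletted += w * E
                        return
            else:
                # boundary crossing
                if not math.isfinite(d):
                    raise TrackingError(
                        f"lost in cell {cell.id} at {(x, y, z)}")
                self._score_segment(info, (x, y, z), (ux, uy, uz), d, E, w,
                                    collided, acc, mat, dens)
                x += (d + SURFACE_NUDGE) * ux
                y += (d + SURFACE_NUDGE) * uy
                z += (d + SURFACE_NUDGE) * uz
                cell = model.relocate((x, y, z), sid, exclude=cell.id)
                info = self.cell_info[cell.id]
                mat, dens, t_idx = info[0], info[1], info[2]
        raise TrackingError("history exceeded the segment guard")

    # -- batches ------------------------------------------------------------

    def run_batch(self, lo: int, hi: int) -> TallyAccumulator:
        acc = TallyAccumulator(len(self.tally_ids), len(self.path_ids),
                               self.plane_labels)
        for i in range(lo, hi):
            self.run_history(i, acc)
        return acc


def run_history(scenario, index: int, seed: int):
    """Run one history; returns (per-cell MeV/g scores, escaped MeV, emitted MeV).

    Convenience wrapper over the batch runner for tests and debugging.
    """
    cfg = RunConfig(n_histories=2, n_batches=2, seed=seed, analog=True)
    r = _Runner(scenario, cfg)
    acc = TallyAccumulator(len(r.tally_ids), len(r.path_ids), r.plane_labels)
    r.run_history(index, acc)
    scores = {cid: acc.dep[i] for cid, i in r.tally_index.items()}
    return scores, acc.escaped, acc.emitted, acc.deposited


def run(scenario, config: RunConfig) -> RunResult:
    """Execute a full run and reduce batch statistics.

    Results are normalised per source photon and are identical for identical
    (scenario, seed, n_histories) regardless of ``workers``.
    """
    runner = _Runner(scenario, config)
    n, nb = config.n_histories, config.n_batches
    bounds = [(k * n // nb, (k + 1) * n // nb) for k in range(nb)]

    if config.workers == 1:
        accs = [runner.run_batch(lo, hi) for lo, hi in bounds]
    else:
        with ThreadPoolExecutor(max_workers=config.workers) as pool:
            futures = [pool.submit(runner.run_batch, lo, hi)
                       for lo, hi in bounds]
            accs = [f.result() for f in futures]       # batch order preserved

    completed = sum(a.n for a in accs) - sum(a.lost for a in accs)
    lost = sum(a.lost for a in accs)
    if completed == 0:
        raise RunError("zero completed histories")
    if lost > LOST_FRACTION_LIMIT * n and lost > 1:
        raise RunError(f"{lost}/{n} histories lost - geometry problem")

    batch_n = np.array([a.n for a in accs], dtype=float)
    batch_dep = np.stack([a.dep / a.n for a in accs])          # per-history means
    batch_tl = np.stack([a.dep_tl / a.n for a in accs])
    tallies = {}
    target = config.target_relative_error
    for cid, i in runner.tally_index.items():
        mean, re = estimate_relative_error(batch_dep[:, i])
        mean_tl, re_tl = estimate_relative_error(batch_tl[:, i])
        cell = runner.model.cell(cid)
        tallies[cid] = TallyResult(
            cid, cell.organ_label, float(runner.tally_mass[i]), mean, re,
            mean_tl, re_tl,
            converged=(target is not None and np.isfinite(re) and re <= target))

    path_fluence = {}
    if runner.path_ids:
        batch_path = np.stack([a.path / a.n for a in accs])
        for cid, i in runner.path_index.items():
            mean, re = estimate_relative_error(batch_path[:, i])
            path_fluence[cid] = (mean, re)

    planes = {}
    for lbl in runner.plane_labels:
        wsum = sum(a.plane_w[lbl] for a in accs)
        wesum = sum(a.plane_we[lbl] for a in accs)
        hist = np.sum([a.plane_hist[lbl] for a in accs], axis=0)
        planes[lbl] = PlaneTally(
            lbl, wsum / n,
            sum(a.plane_w_uncollided[lbl] for a in accs) / n,
            (wesum / wsum) if wsum > 0 else float("nan"),
            PLANE_ENERGY_EDGES.copy(), hist / n)

    return RunResult(
        scenario.label, config.seed, n, nb, tallies, planes, path_fluence,
        lost,
        emitted_energy=sum(a.emitted for a in accs),
        deposited_energy=sum(a.deposited for a in accs),
        escaped_energy=sum(a.escaped for a in accs),
        rouletted_energy=sum(a.rouletted for a in accs),
        batch_dep=batch_dep, tally_ids=runner.tally_ids,
        tracks=[t for a in accs for t in a.tracks])
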