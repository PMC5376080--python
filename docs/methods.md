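# Methods

## Model overview

`straydose` transports photons only.  A history starts at the source (either
a collimated 6 MV spectrum beam or a monoenergetic isotropic point source),
random-walks through a constructive-solid-geometry world of quadric-surface
cells, and ends by photoelectric absorption, escape into the world cell, or
Russian roulette.  Three interaction channels cover 0.01–10 MeV:

* **photoelectric absorption** — the photon's full energy is deposited at the
  site (fluorescence is not modelled);
* **incoherent (Compton) scattering** — free-electron Klein–Nishina.  The
  scattered fraction `eps = E'/E` is drawn on `[1/(1+2a), 1]`, `a = E/m_e c²`,
  by the standard mixture-rejection scheme (`1/eps` and `eps` envelope terms,
  acceptance `1 − eps sin²θ/(1+eps²)`); the deposited energy is `E − E'`;
* **pair production** above 1.022 MeV — `E − 1.022` MeV is deposited locally
  and two 0.511 MeV annihilation quanta continue in antiparallel isotropic
  directions.

**Secondary electrons are not transported.**  All energy transferred to
electrons is deposited at the interaction point (collision-kerma
approximation).  This is the dominant difference from a coupled
photon–electron code: organ doses are collision kerma, valid where
charged-particle equilibrium holds (organ scales ≫ electron ranges), and the
water depth-dose curve has **no build-up region** — it peaks at the surface
bin instead of at ~1.5 cm for a real 6 MV beam.  Out-of-field dose ratios,
which are set by photon scatter, are much less sensitive to this choice.

Coherent (Rayleigh) scattering is omitted: it deposits no energy and only
slightly diffuses the beam; the embedded attenuation tables are built without
it for consistency.

## Cross-section data

The embedded per-element tables (`src/straydose/data/xs/*.csv`, 60-point log
grid 0.01–10 MeV, regenerable with `scripts/make_xs_tables.py`) are computed
from documented analytic models rather than copied from a data library:

* incoherent: exact closed-form Klein–Nishina total per electron × Z;
* photoelectric: `tau(Z, eps) = 7.705e-32 · Z^4.23 · eps^−3.2 +
  3.537e-33 · Z^5 / eps` cm² per atom (`eps = E/m_e c²`): a low-energy
  power-law term calibrated to standard reference anchor values (oxygen at
  10 keV, lead at 100 keV) plus the relativistic K-shell asymptote with a
  1.25 shell factor (reproduces lead at 1 MeV to ~4%).  Below the Moseley
  estimate of the K edge, `E_K = 13.6 eV (Z−0.3)²`, the value is held
  constant — **absorption edges are not modelled**, so high-Z photoelectric
  cross sections below ~100 keV are only order-of-magnitude (they matter only
  inside the tungsten collimator, where photons are absorbed either way);
* pair (+ triplet): `alpha · r_e² · Z(Z+1) · 1.45 ((eps−2)/eps)³ (ln eps + 0.2)`,
  a Born-type universal shape calibrated to water anchors at 2–10 MeV.

Water at 1 MeV comes out at 0.0706 cm²/g against the 0.0707 cm²/g standard
(coherent excluded) — the regime that controls this problem.  Materials are
mass-fraction mixtures over 19 elements (H, Be, C, N, O, Na, Mg, Al, Si, P,
S, Cl, Ar, K, Ca, Fe, Cu, W, Pb); ordinary concrete (2.35 g/cm³) keeps its
~34% silicon, which is why Si is in the library.  Interpolation is log-log
per element; material coefficients are mass-fraction sums of interpolated
elemental values, so the mixture rule is exactly linear.

## Tallies and statistics

Two energy-deposition estimators run side by side in every tally cell:

* **collision estimator** (primary): deposited energy scored at interaction
  sites, MeV/g per source photon;
* **track-length heating estimator** (cross-check): each chord scores
  `w · L · mu_heat(E) · E / m`, where `mu_heat` weights each partial
  coefficient by the mean fraction of `E` handed to electrons (photoelectric
  1, Compton `1 − ⟨E'/E⟩` from quadrature, pair `(E−1.022)/E`).

Under the local-deposition model both have the same expectation; their
agreement in homogeneous water is an acceptance test.  The thin central-axis
depth bins of the water benchmark use the track-length estimator (the
heating-tally style), which has far lower variance there because every
crossing scores.

Uncertainties are batch means: the run splits into `n_batches` (default 20)
contiguous history blocks; the relative error is the standard error of the
batch means over the grand mean (`s/√n / mean`), flagged converged at the
0.4% default target.  A zero mean has undefined relative error and reports
`nan`/not-converged.

Variance reduction (on by default, `analog=True` disables both): implicit
capture of the photoelectric channel (deposit `w·E·σ_pe/σ_t`, survive with
reduced weight) and Russian roulette below weight 0.01 with survival weight
0.1.  Analog mode conserves energy exactly per history (emitted = deposited +
escaped, to float round-off); this is asserted at 1e-9 relative.

## Reproducible parallelism

Each history draws from `numpy` Philox keyed by `(seed << 40) + history
index`; workers process whole batches and results are recombined in batch
order.  Tallies are therefore bit-identical for any worker count — the
testable substitute for an MPI run.  Workers are threads (the run is
CPU-bound in Python, so this is a determinism contract, not a speed-up).

## Geometry and tracking

Cells are boolean trees (intersection/union/complement) over signed
half-spaces of general quadrics `Ax²+By²+Cz²+Dxy+Eyz+Fzx+Gx+Hy+Iz+J=0`.
Numerical choices:

* surface crossing: advance `1e-6` cm past the crossed surface before
  relocating; ray-trace chords carry that nudge into the next cell so total
  traced length is exact to 1e-9 relative;
* ray/quadric roots: numerically stable quadratic (`q = −(b + sign(b)√disc)/2`),
  roots below `1e-9` cm treated as behind the particle;
* relocation tries the cells adjacent to the crossed surface first, then a
  full scan; ties between coincident surfaces resolve by surface id order
  through the deterministic candidate ordering;
* a particle in a bounded cell with no forward intersection is "lost": the
  history is dropped and the run aborts if more than 1e-6 of histories are
  lost (geometry-bug tripwire);
* space-filling is audited by Monte Carlo: 1e5 uniform points in the bounding
  box must each locate to exactly one cell.

## The scenario

Frame: origin at the isocenter, z vertical, beam toward −z, lengths in cm.
Published values are the defaults: room 13.7 × 9 × 4 m with 1 m ordinary
concrete (2.35 g/cm³) walls (thickness configurable; the publication gives
none), maze 2.2 m high × 2 m wide, control room 9.9 × 2 × 4 m with a door,
air at 0.00129 g/cm³, source-to-isocenter distance 100 cm, field 10 × 10 cm²
at the isocenter plane.

**Phantom.**  A stylized adult male in the MIRD/ORNL tradition, but with this
package's own documented shapes (the original phantom equations are not
reproduced): elliptic-cylinder trunk+head envelope (18 × 9 cm semi-axes,
170 cm long) with a 0.2 cm skin shell; ellipsoidal brain, heart, lungs,
liver and testes; cylindrical spine, esophagus and colon surrogate; a
skeleton surrogate of skull shell plus femur cylinders; everything else is
residual soft tissue.  Tissue densities: soft 1.04, lung 0.296, bone 1.4,
skin 1.05 g/cm³, 4-component (H/C/N/O) soft-tissue composition, 9-component
bone.  All organs are disjoint closed-form quadrics, so masses are analytic
volume × density and are verified by Monte Carlo volume audit.  Irradiation
points P1..P5 default to the organ centroids (their published positions are
only shown graphically); the beam enters anteriorly (configurable only by
editing the builders — a deliberate simplification).  Aiming translates the
phantom and couch rigidly so the chosen point sits at the isocenter.

**Linac head.**  Component dimensions are not published; the head is a
parameterized stack of defaults: tungsten target disc, tungsten primary
collimator with a conical channel, beryllium window, copper scattering foil,
ceramic (Al₂O₃) and aluminium spacers, and tungsten upper X-jaws whose
aperture projects to the configured field size.  In the default
spectrum-beam mode the source emits from the target position into the jaw
aperture with energies from an embedded **synthetic** generic 6 MV line
spectrum (24 lines, 0.05–6 MeV: thin-target `1/E (1−E/E_max)` shape hardened
by 11 cm water-equivalent filtration, mean ≈ 1.7 MeV, typical of a flattened
6 MV beam in air).  A user spectrum can be supplied as a two-column text
file.  The monoenergetic comparison mode is a 0.6616 MeV isotropic point
source at the same position.

What the synthetic pieces do **not** emulate: the true accelerator spectrum
and head leakage (no electron-on-target bremsstrahlung stage), anatomical
realism of a voxel phantom, absorption edges, electron transport.  Passing
tests therefore demonstrate correct *transport physics and workflow* under
the stated models, not clinical dose accuracy; published absolute organ
doses are treated as qualitative references only.

## Oracle design notes

* **Slab attenuation**: uncollided exit-plane current vs `exp(−tau)`,
  binomial sigma.
* **Inverse square**: thin spherical-shell *polar-cap* tallies on opposite
  poles at 50 and 100 cm around a central point source.  The expected track
  length in a cap of thickness `dr` and solid angle `Ω` is exactly
  `Ω·dr/4π` per photon at any radius, and putting the caps on opposite poles
  makes the two tallies' crossing events disjoint, so the comparison has
  genuine statistical spread.  (A full-shell tally of a central source is
  deterministic — every ray crosses both shells radially — which would make
  a "within 3 sigma" comparison vacuous.)
* **Klein–Nishina moments**: sampler means vs adaptive quadrature of the
  differential cross section; the closed-form total is itself checked
  against the angular integral to 1e-8.
* **Mini phantom**: target sphere at the isocenter, concentric near shell,
  far sphere 13 cm along the trunk axis (out of beam), in a soft-tissue
  cylinder; 10⁴ histories run in well under 30 s and must give
  `F(target)=1 > F(near) > F(far)`.

## Problem sizes

Default suite sizes were chosen to keep the whole test run on a single core
comfortable while leaving every statistical assertion at 3 sigma: slab
oracles 1e5 histories, Klein–Nishina moments 1e6 draws, water PDD 2e5
histories (0.5 cm bins, track-length tally), estimator agreement and
inverse-square 2e4, mini phantom 2e3–1e4.  The full treatment room at
14-cell-deep tracking costs ~5 ms/history in pure Python; organ-dose runs at
the bundled configs (1e5 histories) are minutes-scale, and relative errors
simply scale as 1/√n from the tested sizes.

## Known limitations

* No electron transport → no build-up, skin dose overestimated, small-field
  penumbra too sharp.
* No absorption edges, fluorescence, Rayleigh scattering, Doppler broadening
  or bound-electron effects; free-electron Compton only.
* Photoelectric fit is anchor-calibrated, not evaluated data; high-Z low-E
  values are approximate.
* Stylized phantom with centroid aiming; no gantry angles, wedges, MLC, or
  voxel anatomy.
* Fractionation application is a pure multiplication (`F × prescribed
  dose`); no inter-fraction setup variation or biological weighting.
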