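# straydose

Monte Carlo photon-transport estimation of **out-of-field (dispersed) dose**
in external-beam radiotherapy.

During a photon treatment, scatter inside the patient, the accelerator head
and the treatment room delivers unintended dose to healthy tissues far from
the target volume.  `straydose` simulates this scenario end to end — a 6 MV
linac head above a stylized adult male phantom on a couch, inside a concrete
treatment bunker (13.7 × 9 × 4 m room, maze, control room) — and reduces the
results to the quantities a medical physicist cares about:

* **absorbed dose per source photon** in 12 labelled tissues (aGy/photon),
  from a track-length/collision pair of energy-deposition tallies;
* **conversion coefficients** `F = D_d / D_t` — the ratio of the dispersed
  dose in a non-targeted tissue to the absorbed dose in the targeted tissue
  for the same irradiation (`F = 1` for the target itself, and `F` is
  independent of fluence because both doses are per source photon);
* **dispersed doses under a fractionation schedule**: for a prescribed total
  dose `D` the non-target tissue receives `F × D` Gy over the course —
  e.g. the CHART lung schedule, 54 Gy in 36 fractions, 3 per day for 12 days;
* **percent depth dose** `PDD(d) = 100 × D_d / D_max` in a water tank
  (SSD 100 cm, 10 × 10 cm² field) as the machine benchmark.

The transport engine is a self-contained photon Monte Carlo: constructive
solid geometry over quadric surfaces, photoelectric / Klein–Nishina Compton /
pair-production sampling on embedded photo-atomic tables (0.01–10 MeV),
implicit capture with Russian roulette, batch-means uncertainties, and
counter-based per-history random streams that make results bit-identical for
any worker count.  Secondary electrons are not transported (collision-kerma
approximation); see `docs/methods.md` for what that does and does not
reproduce.

## Worked example

Five irradiation positions are predefined: P1 testes, P2 colon, P3 liver,
P4 left lung, P5 brain.  A full-room organ-dose run is
`straydose run <config>` (bundled configs live in
`src/straydose/data/examples/`).  The three-organ mini phantom exercises the
identical workflow in seconds:

```python
from straydose import analysis as an, benchmarks as bm, transport as tr

sc = bm.make_mini_phantom_scenario()
res = tr.run(sc, tr.RunConfig(n_histories=10_000, n_batches=10, seed=1))
doses = an.DoseResult.from_run(res, "mini")
table = an.compute_conversion_coefficients(doses, "target")
```

which prints (doses per source photon, batch-means relative errors):

```
far_sphere        415.3 aGy/photon  (RE 30.7%)
near_shell      85563.5 aGy/photon  (RE 2.6%)
target         573306.7 aGy/photon  (RE 2.5%)
F(target) = 1.0000
F(near_shell) = 0.1492
F(far_sphere) = 0.0007
```

The target (in the beam) collects the full dose; the shell around it sees
~15% through lateral scatter; the sphere 13 cm away, outside the beam, sees
less than 0.1%.  Applying a conversion table for a left-lung treatment to the
CHART schedule (`an.dispersed_dose_report(table, an.CHART_SCHEDULE)`) gives
the per-organ course doses:

```
     organ      F  dispersed_dose_gy  per_fraction_gy  percent_of_target
 esophagus 0.6093               32.9            0.914              60.93
     heart 0.9463               51.1            1.420              94.63
 left_lung 1.0000               54.0            1.500             100.00
right_lung 0.6556               35.4            0.983              65.56
     spine 0.3519               19.0            0.528              35.19
```

i.e. with those coefficients the heart absorbs 51.1 Gy (94.63% of the
prescription) and the spine 19 Gy over the 12-day course.

## Command line

```
straydose run <config.yaml>          # organ doses + manifest for a scenario
straydose convert doses.json left_lung   # -> conversion coefficients F
straydose chart-report conversion.json   # dispersed doses for a schedule
straydose pdd <config.yaml>          # water-tank percent depth dose
straydose list-benchmarks            # analytic oracle cases
straydose run-benchmark slab_tau_1   # observed vs expected with sigma
straydose dump-geometry <config>     # ASCII cross-section slice
```

Output file columns are documented in `docs/FORMATS.md`.

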