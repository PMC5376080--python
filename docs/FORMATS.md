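# File formats

All CSV files: comma separator, dot decimal, one header row, UTF-8.

## doses.csv (straydose run)

| column | meaning |
| --- | --- |
| organ | tissue label (12 phantom organs, or mini-phantom regions) |
| dose_agy_per_photon | absorbed dose per source photon, aGy (1e-18 Gy) |
| relative_error | batch-means relative error (1 sigma of mean / mean) |
| dose_mev_per_g_per_photon | same dose in MeV/g per source photon |

## doses.json

`{"position": "P4", "source_mode": ..., "run_label": ..., "seed": ...,
"doses": {organ: [dose_agy_per_photon, relative_error], ...}}`

## conversion.csv / conversion.json (straydose convert)

CSV columns: `position, organ, F, relative_error`.  `F` is rounded to 4
decimals in the CSV; the JSON carries full precision plus provenance
(run label and seed) and is the input to `chart-report`.

## chart_report.csv (straydose chart-report)

| column | meaning |
| --- | --- |
| organ | tissue label |
| F | conversion coefficient (4 decimals) |
| dispersed_dose_gy | F x prescribed total dose, 3 significant figures |
| per_fraction_gy | dispersed dose per fraction, 3 significant figures |
| percent_of_target | 100 x F |

## pdd.csv (straydose pdd)

`depth_cm` (bin centre), `pdd_percent` (100 x D_i / D_max, track-length
tally), `relative_error`.

## run.log

Plain text: seed, history and lost-history counts, energy ledger (emitted /
deposited / escaped MeV), then one line per tally region with dose and
relative error and the converged flag.

## manifest.json

Config snapshot, code version, seed, scenario checksum (sha256 prefix of the
serialized geometry), ISO timestamps, sorted output file list.

## Cross-section resources (src/straydose/data/xs/*.csv)

`energy_mev, pe, incoherent, pair` — elemental mass-attenuation partials in
cm^2/g on a 60-point log grid, regenerable with `scripts/make_xs_tables.py`.

## Spectrum files (user supplied)

Two whitespace- or comma-separated columns: energy (MeV), relative
probability; `#` comments allowed.  Probabilities are renormalised.
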