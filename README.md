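# spotval

Validation toolkit for quantitative dried-blood-spot (DBS) LC-MS/MS assays.

`spotval` implements the statistical backbone of a bioanalytical method
validation for a 25-analyte PFAS panel measured in 10 µL volumetric dried
blood spots, and a synthetic-data generator that reproduces the statistical
structure of such a study so every stage is testable without instrument data:

- **panel** — domain model of the SRM panel: transition table (25 targets +
  9 isotope-labelled internal standards), IS mapping, gradient program and
  spiking arithmetic. Fixtures ship in `spotval/data/`.
- **simulate** — seeded generators for replicated multi-day calibration
  curves (heteroscedastic noise with `var(y) ∝ x^k`), matrix-effect /
  recovery spike sets, storage-stability grids, 3² factorial responses and
  Gaussian-peak chromatograms.
- **calibration** — heteroscedasticity assessment and weighting selection
  (none, 1/x, 1/x²), weighted least-squares fits, model-order selection by
  Mandel's fitting test plus a pure-error lack-of-fit test, and
  back-calculation on the concentration-ratio scale.
- **limits** — Hubaux-Vos detection limit from the four lowest calibrators
  with weighted (Currie-style) prediction bands, S/N measurement on
  chromatograms, S/N = 3 extrapolation, and LOQ assignment.
- **performance** — cyclic (leave-one-curve-out / leave-one-day-out)
  intra- and inter-day accuracy, intra-/inter-day precision, and the
  |bias| ≤ 20% / CV < 20% acceptance evaluation.
- **matrix** — matrix effect, extraction recovery, process efficiency
  (PE% = ME% × ER% / 100), ion-enhancement classification, and
  standard-addition quantification.
- **stability** — per-factor one-way ANOVA over storage temperature and
  time (two-way and Bonferroni options available).
- **doe** — full-factorial design generation, PCA of the runs × analytes
  response matrix, and MLR of PC1 scores on coded factors.
- **bagi** — Blue Applicability Grade Index practicability scoring
  (ten attributes graded 2.5–10; practical at ≥ 60 points).
- **report / cli** — end-to-end orchestration with deterministic JSON and
  markdown reports.

## CLI

```sh
# generate a synthetic measurements table for the packaged reference panel
spotval simulate --seed 7 --out measurements.csv --with-extras

# run the full validation pipeline and write reports
spotval validate --measurements measurements.csv --out-json report.json --out-md report.md

# individual stages
spotval calibrate --measurements measurements.csv
spotval limits    --measurements measurements.csv
spotval matrix    --measurements measurements.csv
spotval stability --measurements measurements.csv
spotval doe --seed 3
spotval bagi
```

## Data formats

- `measurements.csv` — long-format records: `analyte_id, role, day, curve,
  replicate, level_ng_ml, temp_c, time_d, run_id, added_ng_ml,
  area_analyte, area_is`; roles are `calibrator`, `qc`, `me_set1..3`,
  `stability`, `doe`, `std_addition`, `blank`.
- `transitions.csv` — one row per (analyte, product ion); the ordinal-1 row
  is the quantifier transition.
- `report.json` — validated against the minimal structural schema shipped at
  `spotval/data/report_schema.json`; floats carry 6 significant digits and
  key order is stable, so identical inputs give byte-identical reports.

## Notes

- Concentrations are ng/mL throughout; the calibration x-axis is the
  concentration ratio (level / IS concentration, IS at 20 ng/mL by default).
- BAGI grade shades map 2.5 → white, 5 → pale blue, 7.5 → light blue,
  10 → dark blue; the packaged reference assessment (4 low / 4 medium /
  2 high) totals exactly the 60-point practicality threshold.
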