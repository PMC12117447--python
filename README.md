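# lyoscat

Analysis toolkit for lyotropic liquid-crystalline nanocarriers
(hexosomes/cubosomes): composite small-angle-scattering model fitting with
derived structural metrics, mesophase peak indexing, formulation assays
(CAC, encapsulation efficiency, in-vitro release), lattice-spacing
estimation from micrographs, and synthetic-data generators for all of the
above.

## What it does

- **`lyoscat.io`** — read/write scattering curves (delimited text, comment
  lines `#`) and concentration-series CSVs. Canonical q unit is nm⁻¹;
  Å⁻¹ input is detected (header tag or magnitude heuristic) and converted.
- **`lyoscat.forward`** — the composite intensity model
  `I(q) = I₁ + I₂ + I₃ + I₄`: a one-level Guinier–Porod envelope, a
  two-level cylinder Guinier–Porod term, Lorentzian lattice peaks, and a
  flat background. All branch crossovers are C¹ by construction. Derived
  metrics: `Rg`, sphere-equivalent diameter `2√(5/3)·Rg`, cylinder radius
  `Rc = √2·Rg1`, length `L = √(12Rg2² − 6Rc²)`, per-peak d-spacing,
  hexagonal lattice constant `4π/(√3·q)` and correlation length `2π/σ`.
- **`lyoscat.fitting`** — peak detection on a detrended curve, data-driven
  initialization, and bounded trust-region least squares in log-parameter
  space with seeded multistart; bit-reproducible for a fixed seed.
- **`lyoscat.phase`** — Bragg spacings (`d = 2π/q`), peak-ratio indexing
  against hexagonal HII, cubic Pn3m/Im3m/Ia3d and lamellar ratio tables,
  lattice constants, and phase-transition detection over a temperature
  series.
- **`lyoscat.assays`** — CAC by exhaustive two-segment breakpoint search in
  log-log space, OLS calibration with inversion/extrapolation flags, EE%
  with replicate SD, and cumulative release corrected for aliquot
  sampling with replacement.
- **`lyoscat.images`** — lattice row spacing via windowed 2D FFT radial
  power spectrum, gray-profile light/dark segmentation, and the 2D→3D
  hexagonal correction factor `2/√3`.
- **`lyoscat.synth`** — seeded generators for every input above, including
  three presets (`unloaded`, `LEF`, `LEF_G`) whose derived metrics
  reproduce the reference systems' published values by construction.

## CLI

A single entry point with one subcommand per pipeline:

```sh
lyoscat synth --kind curve --preset unloaded --noise 0.01 --seed 1 --out work
lyoscat fit --input work/unloaded_curve.dat --out work --seed 1
lyoscat index --peaks 1.140,1.974,2.280 --out work
lyoscat transitions --input series.csv --out work
lyoscat cac --input cac_series.csv --out work
lyoscat ee --measured 0.31 --total 0.5 --out work
lyoscat release --input rel.csv --medium-volume 45 --aliquot-volume 1 \
    --total-loaded 300 --out work
lyoscat image --input micrograph.png --pixel-size 0.2 --out work
```

Every subcommand writes a JSON report with stable key ordering that embeds
the resolved configuration and seed.

## Layout

```
src/lyoscat/        package modules (io, forward, fitting, phase, assays,
                    images, synth, cli, exceptions)
tests/              pytest suite; tests/test_acceptance.py holds the
                    acceptance criteria, tests/helpers_oracle.py the
                    independent brute-force forward-model oracle
scripts/acceptance.py   acceptance-target report generator
```
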