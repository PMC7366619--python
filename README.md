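# phantomech

Uniaxial-compression (UC) analysis for soft silicone mixtures used as
kidney-phantom materials:

1. **Segmented moduli estimation** — a continuous piecewise-linear model
   with three change points is fitted to pooled replicate stress–strain
   data by iterative linearization with bootstrap restarting.  The
   low-strain modulus **E1** is the slope of the first segment (toe) and
   the high-strain modulus **E2** the slope of the third segment (between
   the second and third change points).  Reported values are averages
   over ten seeded runs, with change-point standard errors.
2. **Blatz constitutive fitting** — the two-parameter hyperelastic
   relation σ₀(λ) = γ/(α+1)·(λ·e^{α(λ²−1)} − λ⁻²·e^{α(1/λ−1)}) is fitted
   per technical replicate by multi-start nonlinear least squares, and
   replicate fits are aggregated into means, sample SDs and quantiles.
3. **Screening** — per-mixture moduli are ranked against kidney-cortex
   targets (E1 = 20 kPa, E2 = 500 kPa; cortex range 13.6–25.8 kPa) by the
   Euclidean norm of relative errors.

Input records are two-column plain-text (or CSV) files of nominal strain
and nominal stress; strain may be stored as a fraction or percent
(auto-detected), stress is kPa.  Replicate files follow the
`<material>_<dilution>_<replicate>.<ext>` naming pattern.

## CLI

```sh
# generate a synthetic replicate directory with a truth sidecar
phantomech simulate --kind bilinear --out fixtures --material SYNTH \
    --dilution 5 --e1 20 --e2 500 --noise-rel 0.02 --seed 1

# estimate E1/E2 for one mixture
phantomech fit-moduli fixtures --material SYNTH --dilution 5

# fit Blatz (alpha, gamma) per replicate
phantomech fit-blatz fixtures --material SYNTH --dilution 5

# rank a moduli CSV against the targets
phantomech screen moduli.csv

# full pipeline from a YAML config
phantomech run --config config.yaml --seed 1
```

A pipeline config lists mixtures (each either a `directory` of measured
replicates or a `synthetic` spec), fitting settings (`n_runs`, `n_boot`,
`psi0`) and targets; reports (`moduli.csv`, `blatz.csv`, `ranking.csv`,
per-parameter quantile TXT files) are written to `output_dir`.

```yaml
seed: 1
output_dir: out
mixtures:
  - material: ECOFLEX-0010
    dilution_pct: 5
    directory: data/ecoflex_5
target: {E1: 20, E2: 500}
```

## Notes on conventions

- Internal canonical units: strain as a dimensionless fraction, stress as
  a positive magnitude in kPa.  The constitutive model is signed
  (compression negative); magnitudes are negated before fitting.
- XLSX vendor exports are not parsed.  Convert a sheet's strain/stress
  columns to CSV first, e.g. with
  `python -c "import pandas as pd; pd.read_excel('f.xlsx')[['strain','stress']].to_csv('f.csv', index=False)"`.
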