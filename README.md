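# fermkin

Unstructured kinetic modeling of batch fermentation: logistic biomass
growth coupled to Luedeking–Piret product formation and
growth-plus-maintenance sugar consumption, packaged as a reusable
**simulate / fit / compare** pipeline with a seeded synthetic-data
generator.

The model (time in days, biomass `X` in g DW/L, sugar `S` and product
titer `P` in g/L):

```
dX/dt = mu_max * X * (1 - X / X_max)          # logistic growth
dP/dt = alpha * dX/dt + beta * X              # Luedeking-Piret
-dS/dt = (1/Y_XS) * dX/dt + M_s * X           # growth + maintenance
```

All three have closed forms given the logistic solution and its running
integral; trajectories can also be obtained by ODE integration, and the
two routes agree to 1e-6 relative error (tested).

## Modules

| module | what it does |
| --- | --- |
| `fermkin.kinetics` | parameter/state types, closed-form and ODE trajectories, peak growth rate |
| `fermkin.fitting` | multi-start nonlinear least squares (sequential or joint), conditional linear solves, R²/F statistics |
| `fermkin.synthetic` | seeded generator with additive/proportional Gaussian noise and replicate structure |
| `fermkin.comparison` | fold changes, productivity, percent increases, two-sample t tests, strain-comparison reports |
| `fermkin.io` / `fermkin.cli` | CSV/JSON I/O and the `fermkin` command-line tool |
| `fermkin.reference` | published parameter columns and the metabolite-content table used as defaults |

The fitter exploits the model's triangular structure: growth parameters
(`mu_max`, `X_max`, `X0`) are fitted by multi-start trust-region least
squares; given the growth curve, (`alpha`, `beta`) and (`1/Y_XS`, `M_s`)
are exact non-negative linear least-squares solutions. A `joint` strategy
refits everything simultaneously against range-weighted residuals.

## CLI

```bash
# noiseless model trajectory for the wild-type parameter preset
fermkin simulate --params WT --times 0:12:1 --out wt.csv

# synthetic triplicate data, 5% proportional noise
fermkin generate --params WT --times 0:12:2 --noise-kind proportional \
    --noise-sd 0.05 --replicates 3 --seed 1 --out wt_noisy.csv

# fit the model to a time-course CSV (columns: time_days, biomass_g_L,
# sugar_g_L, ga[, replicate, strain]); mg/L titers via --ga-unit mg_L
fermkin fit wt_noisy.csv --strategy sequential --starts 20 --out fit.json

# compare two parameter sets and a metabolite-content table
fermkin compare --params-control WT --params-treated FPS \
    --contents contents.csv --duration 12 --out report.json
```

`--params` accepts the presets `WT` / `FPS` or a JSON file with the
parameter fields. Exit codes: 0 success, 1 failure, 2 usage error;
diagnostics go to stderr, data to files.

## Notes on the reference values

Some printed reference numbers are internally inconsistent and are kept
verbatim rather than reconciled: the transgenic `beta` (1.151 g/g/day) is
dimensionally incompatible with the printed final titer of 0.209 g/L; the
printed productivity 0.018 vs 0.209/12 = 0.0174; the printed "8%" growth
rate increase vs the computed 8.9%. See `fermkin.reference` docstrings.
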