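# cueint

Circular cue-integration modelling and analysis for arena exit-bearing
experiments: von Mises cue-noise modelling, reliability-to-concentration
estimation, five directional integration models (WTA, WAM, WVS, NVS, BVS),
a Monte-Carlo cue-conflict simulator, binned-likelihood model comparison
(likelihood ratio / AIC / BIC), and the empirical behavioural pipeline
(normalisation, exclusion screens, menotaxis classification,
change-in-heading statistics), plus a synthetic-data generator with
known-truth manifests for end-to-end recovery testing.

## Layout

| module | contents |
| --- | --- |
| `cueint.circstats` | wrap/resultant/Rayleigh, von Mises pdf + sampler, kappa estimators |
| `cueint.reliability` | wind-speed / light-elevation precision fits, augmented R → kappa |
| `cueint.models` | the five integrators and their weight transforms |
| `cueint.simulate` | per-individual change-in-heading simulation, 5° PMFs, the 21-condition grid |
| `cueint.evaluate` | binned log likelihood, LR/AIC/BIC comparison table |
| `cueint.behavior` | exit-table pipeline: normalisation, screens, summaries |
| `cueint.synth` | synthetic reliability and conflict datasets + truth manifests |
| `cueint.io_cli` | CSV/JSON/YAML formats and the `cueint` command |
| `cueint.deposit` | loader for a locally provided copy of the deposited dataset |

## CLI

```sh
cueint synth --kind conflict --model BVS --n-beetles 30 --seed 1 --out exits.csv
cueint analyze --data exits.csv --mode conflict --out summary.csv
cueint simulate --nsim 100000 --seed 1 --out pmfs.csv
cueint evaluate --data exits.csv --nsim 100000 --seed 1 --out comparison.csv
cueint reproduce --data exits.csv --nsim 1000000 --seed 1 --out results/
```

`reproduce` chains the full pipeline with the default constants (sigmoid
steepness a = 53, bias variance 0.000303, 5° bins, the 21-condition grid)
and writes the changes table, the PMFs and the five-row comparison table.
A YAML/JSON config can override every constant (`cueint.io_cli.load_config`).

## Deposited data

The published behavioural dataset is not redistributed here. To run the
data-dependent benchmarks (acceptance criteria 1–3 and targets t6–t9),
convert the deposit to the exit-table schema and place
`reliability_light.csv`, `reliability_wind.csv`, `conflict.csv` and
`precision.csv` under `data/zenodo/` (or set `CUEINT_DATA_DIR`); an optional
`mapping.json` adapts differing column headers. See
`src/cueint/deposit.py`. Without the data those tests fail with an
explanatory message and the acceptance report omits the targets.

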