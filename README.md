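# soildt50

Probabilistic prediction of soil biotransformation half-lives (DT50) with
regulatory persistence screening.

The pipeline turns tables of replicate, possibly censored, experimental
DT50 values into per-compound Bayesian half-life distributions, trains
uncertainty-aware regressors (Gaussian-process regression with
heteroscedastic target noise, plus a random-forest baseline) on molecular
structure, converts predictive distributions into REACH persistence-class
probabilities p(nP)/p(P)/p(vP), and evaluates the predicted uncertainties
with calibration diagnostics (ECE, ENCE, distance-based calibration).

## Modules

| Module | Purpose |
| --- | --- |
| `soildt50.core_data` | Half-life table I/O, SMILES standardization (stereo stripping), applicability-domain gate (single organic structures, MW < 1200 Da) |
| `soildt50.bayes_halflife` | Per-compound posterior over (mean log10 DT50, replicate SD) by deterministic 2-D quadrature; handles `<`/`>` censored values |
| `soildt50.features` | MACCS / Avalon / path fingerprints, 2-D descriptors, external descriptor tables; min-max scaling, variance + Spearman-cluster feature selection; Tanimoto k-NN distances |
| `soildt50.prob_models` | GPR with per-sample noise `alpha = mu_std^2`; RF baseline with tree-spread SD; model archives |
| `soildt50.persistence` | Exceedance probabilities against the 120/180-day thresholds, confidence categories (SD < 0.5 good, < 0.7 acceptable) |
| `soildt50.evaluation` | Nested cross-validation, R²/RMSE, ECE, ENCE, distance calibration |
| `soildt50.synthetic_data` | Seeded generators emulating the statistical structure of soil DT50 collections (replicate counts 1–59, log10-normal values, right-censoring) |
| `soildt50.cli` | `soildt50 simulate / curate / train / eval / predict` |

## CLI workflow

```bash
# generate a synthetic half-life table (or bring your own CSV with
# columns compound_id, smiles, dt50_days, censor)
soildt50 simulate --output table.csv --n-compounds 100 --seed 1

# infer per-compound distributions (mu_mean, mu_std, sigma_mean)
soildt50 curate --input table.csv --output dists.csv

# train a GP model on the curated distributions
soildt50 train --distributions dists.csv --model-out model.joblib \
    --features maccs --kernel matern25 --seed 1

# nested cross-validation over feature-set x kernel candidates
soildt50 eval --distributions dists.csv --report-out report.json \
    --features maccs --features descriptors_2d --seed 1

# predict: single SMILES or batch; out-of-domain inputs are flagged,
# never silently scored
soildt50 predict --model model.joblib --smiles "CCO" --output pred.csv
soildt50 predict --model model.joblib --input batch.csv --output preds.csv
```

Prediction output columns include the standardized SMILES actually
scored, `pred_mean`/`pred_std` (log10 days), `p_nP`/`p_P`/`p_vP`, and the
confidence category.

## Notes

- Real training data (a large curated soil-study collection) is not
  bundled; `soildt50.synthetic_data` provides seeded stand-ins with the
  same shape so the whole pipeline is testable offline. To use real data,
  export it to the CSV dialect above and run the same commands.
- All randomness is controlled by explicit `--seed` options; numeric
  outputs are byte-reproducible for a fixed seed.
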