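# invasionrisk

Invasion-risk mapping for species spread by human activity — for example an
aquarium plant escaping into a country's inland waters. The package answers
the question conservation planners actually ask: *where is an invader both
able to establish and likely to be introduced?* It combines two surfaces on a
common geographic grid:

1. **Environmental suitability** from a presence–background maximum-entropy
   model (MaxEnt-style) relating species occurrence records to climate,
   topography and soil predictors.
2. **Introduction pressure** from a planar kernel-density surface of
   introduction points (e.g. aquarium/pet stores), linearly normalized to
   [0, 1].

Their cellwise product is the invasion-risk surface, which is then
summarized over protected-area polygons to flag conservation sites at risk.

## The model

Given presence sites x₁…x_m and background cells b₁…b_N with features
f(·), the suitability model is the Gibbs distribution

    p(b) = exp(η(b)) / Z,   η(x) = Σⱼ βⱼ fⱼ(x),   Z = Σ_b exp(η(b)),

with β chosen to maximize the L1-penalized presence log-likelihood

    (1/m) Σᵢ η(xᵢ) − log Z − Σⱼ λⱼ |βⱼ|.

At the optimum, |E_model[fⱼ] − mean_presence[fⱼ]| ≤ λⱼ for every feature —
with λ = 0 this is exact moment matching, the defining property of maximum
entropy. Suitability is reported on the cloglog scale,
`1 − exp(−e^H · p(x))` with H the entropy of the fitted background
distribution, so a featureless model scores 1 − 1/e everywhere. Features are
linear, quadratic, pairwise-product and hinge expansions of the predictors,
each rescaled to [0, 1] over the training data and clamped to the training
range at prediction time.

The surrounding pipeline implements the standard practice chain: record
cleaning (coordinates, year, coordinate uncertainty, duplicates), spatial
thinning to one record per grid cell, organic-soil reclassification and
focal density, greedy correlation pruning at |r| ≤ 0.7, background sampling
capped at 10 000 cells, 10-fold cross-validated AUC (mean ± sd ensemble),
permutation importance as normalized AUC drops, quartic-kernel store
density, and zonal risk statistics by cell-center containment.

A synthetic-data module generates landscapes with known generating
coefficients (spatially autocorrelated predictors, presences sampled from
exp(η), clustered stores, named polygons), so every stage is testable
without any external downloads.

## Worked example

```python
import invasionrisk as ir

cfg = {"seed": 42,
       "simulate": {"rows": 50, "cols": 50, "n_presence": 400, "n_stores": 100},
       "params": {"k_folds": 10}}
out = ir.run(cfg, "example_run")
```

On this simulated 50×50 landscape the run prints (see
`example_run/evaluation.json`, `importance.csv`, `risk_report.csv`):

```
mean_auc 0.776  sd 0.032

       variable  importance_pct  auc_drop
          env_3           60.99      0.18
  precip_annual           37.76      0.11
   temp_warmest            1.19      0.00
          env_2            0.05      0.00
organic_density            0.01      0.00
```

The generating truth for seed 42 gives nonzero weights only to
`precip_annual` (−0.98) and `env_3` (+1.10) — exactly the two variables that
receive essentially all (98.7 %) of the permutation importance, while the
known-irrelevant predictors score near zero. The cross-validated AUC of
0.78 reflects a moderately informative truth (occupied cells still overlap
environmentally with the background). `risk_report.csv` lists, for each
protected area, the mean and maximum invasion risk, the fraction of its
cells above the hotspot threshold (default 0.5), and its cell count.

The same run is available from the shell:

```sh
invasionrisk run --config config.yaml --outdir example_run
```

with subcommands `simulate`, `clean`, `thin`, `prep-organic`,
`focal-density`, `prune`, `fit`, `predict`, `kde` and `zonal` for the
individual stages.

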