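# arealrisk

Bayesian disease mapping for areal count data: who has elevated risk,
where, and how sure are we?

Public-health agencies allocate screening and intervention resources by
county (or district, or census tract).  Raw standardized morbidity ratios
`y_i / E_i` are noisy exactly where decisions are hardest — small
populations — and naive regressions ignore that neighboring areas share
unmeasured risk factors.  `arealrisk` implements the standard hierarchical
answer end to end:

    Y_i ~ Poisson(E_i * theta_i)
    log(theta_i) = b0 + x_i' beta + sigma * ( sqrt(phi) u_i + sqrt(1-phi) v_i )

where `E_i` are internally standardized expected counts, `u` is an
intrinsic CAR (ICAR) field on the queen-contiguity graph scaled so `sigma`
is the marginal SD of the combined random effect (the BYM2 convention),
`v` is IID noise and `phi` is the structured fraction of the spatial
variance.  Inference is a nested Laplace approximation: Gaussian
approximations to the latent field at its mode, integrated over a weighted
hyperparameter grid, with penalized-complexity priors on `sigma` and `phi`.

Around the model sits the full workflow of a county-level risk study:

* **synthetic data** — lattices generated from the model above with known
  truth (and controllable covariate/field correlation), so everything is
  testable without restricted surveillance data;
* **screening** — pairwise-correlation filter (|r| > 0.6), forward-BIC
  selection, VIF > 10 filter, FDR-adjusted negative-binomial interaction
  scan, chained-equation imputation;
* **model comparison** — GLM / IID / CAR / BYM variants by DIC and WAIC;
  Poisson vs negative binomial with Pearson overdispersion statistics;
* **diagnostics** — spatial-confounding check (fixed effects with vs
  without the structured field), global Moran and Getis–Ord Gi* on
  residuals;
* **hotspots and tiers** — LISA (local Moran) cluster/outlier labels on the
  posterior RRs, and SD-band classification into intervention tiers
  (>1.5 SD above RR = 1 → tier 1, 0.5–1.5 → tier 2, −0.5–0.5 → tier 3).

See `docs/methods.md` for the model, priors, conventions and limitations.

## Worked example

Run the whole pipeline on a synthetic 20×20-county map whose true smoking
effect is RR 1.08 per percentage point, with seven county-style covariates,
`sigma = 0.5`, `phi = 0.57` and 1.62% missing covariate cells:

```python
import arealrisk as ar

cfg = ar.default_config(seed=1)           # 20x20 lattice, 7 covariates
pipe = ar.PipelineConfig(outdir="demo", seed=1, simulate=cfg,
                         grid_points=5, n_draws=1000, permutations=999)
bundle = ar.run_pipeline(pipe)

fit = bundle["fit"]
print(fit.fixed_effects[["rr", "rr_lower", "rr_upper"]].round(4))
print(fit.hyper)
print(bundle["summary"]["tier_counts"])
```

Output (about 15 s on one CPU):

```
                 rr  rr_lower  rr_upper
(intercept)  0.1162    0.0668    0.2024
pct_smokers  1.0789    1.0634    1.0946
max_temp     1.0084    0.9934    1.0236
svi          0.9897    0.8232    1.1898
pct_alcohol  1.0047    0.9811    1.0287
pct_obese    1.0072    0.9948    1.0197
pm25         0.9852    0.9528    1.0188
{'sigma_mean': 0.624}
{'below-reference': 159, '3': 151, '2': 62, '1': 28}
```

Reading the numbers: the smoking RR per percentage point is estimated at
1.079 (95% CI 1.063–1.095) against a simulated truth of 1.080; every null
covariate's interval covers 1.  The imputation completed the 6 masked rows
(1.50%), the screening funnel kept 6 of 7 predictors, DIC preferred a
structured spatial model over the plain GLM by six orders of deviance, and
the SD-band tiering flags 28 areas for tier-1 intensive intervention.  The
report bundle (`demo/areas.csv`, `demo/summary.json`, `demo/areas.geojson`)
carries per-area RRs with intervals, structured/unstructured fields,
residuals, LISA labels (HH/LL/LH/HL) and tiers, ready for mapping.

The same stages are available as a CLI:

```bash
arealrisk simulate --rows 20 --cols 20 --seed 1 --outdir data
arealrisk screen data/attributes.csv --seed 1
arealrisk fit data/areas.geojson data/attributes.csv --random-effect bym
arealrisk run config.yaml
```

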