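# paraburden

Hierarchical negative-binomial reconstruction of long-term parasite-burden
trends from natural-history collection surveys.

## The problem

Almost no long-term abundance data exist for parasites of wildlife.  One way
to recover them is to dissect fluid-preserved fish specimens from museum
collections, count the metazoan parasites of each fish, and model how counts
changed over a century while controlling for host species, host size,
collection latitude, and fish-to-fish heterogeneity.  `paraburden`
implements that inference pipeline for surveys shaped like a Puget Sound
collection study: multiple host species, dozens of parasite taxa
classified by life-cycle complexity (1, 2, or 3+ obligately required host
species) and broad taxonomy, sparse decade-stratified sampling across
1880–2019, and annual environmental records (sea surface temperature,
sediment-core pollutants, host density) with uneven coverage.

## The model

For the count `y_i` of parasite taxon `k` in fish `f` of host–parasite pair
`j`:

```
eta_i = beta_o[j] (+ beta_og[g]) + X_lat,i * beta_lat[k]
        + X_len,i * beta_len[j] + zeta_f + sum_p U_{i,p} * gamma_{k,p}
y_i   ~ NB2(mean = exp(eta_i), dispersion = phi_k)
```

Every coefficient is a random effect with a normal hyper-distribution
(estimated mean and SD); `log phi_k ~ N(log mu_phi, sigma_logphi)` gives each
taxon its own overdispersion.  Predictor effects `gamma_{k,p}` (year, SST,
pollutant PCs, host density — all standardized) can share one mean, or have
distinct means per life-cycle group (`1`, `2`, `3+`) or per broad taxonomic
class, with a matching group-level intercept term.  Random effects are
integrated out with a Laplace approximation (sparse analytic inner
Hessians, Newton inner solver); outer parameters are estimated by
quasi-Newton maximum marginal likelihood, and model variants are compared
with AICc counted over the outer parameters.

The pipeline stages: prevalence filtering (keep host–parasite pairs found
in ≥ 5% of dissected hosts), covariate construction (monthly-SST
annualisation with a ≤ 1 missing month rule, two-core pollutant averaging →
interpolation → correlation PCA → LOESS smoothing, species-matched density
joins), phase-1 model selection over year-effect structures, phase-2
environmental-driver fits on era-matched data subsets, effect-size
conversion (percent change per decade / per °C), prediction curves, an
extirpation screen (taxa unseen ≥ 40 years), and simulation-based residual
diagnostics.  A synthetic-data generator reproduces all of this structure
with known truth, so the entire inference is testable offline.

## Worked example

```python
import numpy as np
from paraburden import (default_config, simulate_survey, filter_by_prevalence,
                        run_phase1, percent_change_per_decade, FitOptions)
from paraburden.simulate import SimConfig

cfg = default_config()                       # 8 species, 85 taxa, 1880-2019
cfg = SimConfig(**{**cfg.__dict__, "mu_gamma": (0.0, 0.0, -0.25), "seed": 101})
table, truth = simulate_survey(cfg)          # ~750 fish, ~8000 rows
filtered, rare = filter_by_prevalence(table) # 5% prevalence rule
result = run_phase1(filtered, options=FitOptions(n_starts=1))
print(result.comparison.table[["model", "k_fixed", "aicc", "delta_aicc"]])
m2 = result.fits["M2_year_by_n_hosts"]
pct = percent_change_per_decade(m2.params["mu_gamma[year][3+]"],
                                m2.scaling["year"])
print(f"3+-host trend: {m2.params['mu_gamma[year][3+]']:.3f} per SD of year "
      f"= {pct:.1f}% per decade")
```

Output from this exact script (a few minutes on one CPU):

```
                 model  k_fixed          aicc  delta_aicc
0   M2_year_by_n_hosts       14  24816.420503    0.000000
1  M3_year_by_taxonomy       18  24828.889405   12.468902
2     M1_year_by_taxon       11  24829.213393   12.792890
3           M0_no_year        9  24900.988360   84.567857
3+-host trend: -0.224 per SD of year = -4.9% per decade
```

The grouped-by-life-cycle model (`M2`) wins decisively over the no-year
model (ΔAICc ≈ 85), and the fitted 3+-host group trend of −0.224 per SD of
year (truth: −0.25) is a ~5% decline per decade at this design's year
spread, while the 1- and 2-host groups are flat.  The same
fitted objects feed `extract_taxon_effects` (per-taxon trends ± conditional
SE), `predict_group_average` / `predict_marginal_average` (count-per-host
curves), `extirpation_report`, and the `diagnostics` module.

A thin CLI wraps the pipeline (`paraburden simulate`, `prepare`, `fit`,
`select`, `run ...`; `paraburden config init` prints all defaults), and the
`examples/` directory holds short narrative scripts, one per capability.

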