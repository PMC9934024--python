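# Methods

## Model

The response is the count `y_i` of parasite taxon `k` in fish specimen `f`
of host–parasite pair `j` (one row per fish × roster taxon, with explicit
zeros).  The linear predictor on the log scale is

```
eta_i = beta_o[j] (+ beta_og[g]) + X_lat,i beta_lat[k] + X_len,i beta_len[j]
        + zeta_f + sum_p U_{i,p} gamma_{k,p}
```

with `y_i ~ NB2(exp(eta_i), phi_k)`.  NB2 means `Var = mu + mu^2/phi`, so
`phi -> inf` recovers the Poisson; this is the parameterisation in which a
taxon-specific dispersion "controls excess variance from the Poisson
expectation".  All continuous predictors (year, latitude, host total
length, environmental series) are standardized to mean 0, SD 1 over the
analysis rows; host length can alternatively be standardized within each
host–parasite pair (config switch, default global over pair-expanded rows).

Every coefficient is a random effect:

| block        | index      | prior                                   |
|--------------|------------|-----------------------------------------|
| `beta_o`     | pair j     | `N(mu_o, sigma_o)` (mean 0 when grouped) |
| `beta_og`    | group g    | `N(mu_beta_o, sigma_beta_og)` (grouped specs only) |
| `beta_lat`   | taxon k    | `N(mu_lat, sigma_lat)`                   |
| `beta_len`   | pair j     | `N(mu_len, sigma_len)`                   |
| `zeta`       | fish f     | `N(0, sigma_zeta)`                       |
| `gamma[p]`   | taxon k    | `N(mu_gamma[p] or mu_gamma[p][group(k)], sigma_gamma[p])` |
| `log phi`    | taxon k    | `N(log mu_phi, sigma_logphi)`            |

`sigma_logphi` is the SD of `log phi` (the typographically ambiguous
alternative — the log of an SD of `phi` — is not used).  When slope means
are grouped, pair intercepts are re-centred at zero and a group-level
intercept `beta_og` with its own mean and SD is added; the pair-level and
group-level intercept SDs are distinct parameters.  The number of obligate
hosts is collapsed to the three classes 1 / 2 / 3+.  Longitude is excluded
by default.

## Laplace marginal likelihood

Let `z` collect all random effects and `theta` the outer parameters (all
hyper-means, hyper-SDs on the log scale, and the dispersion hyper-pair).
The marginal NLL is approximated as

```
M(theta) = joint(z_hat) + 0.5 * logdet H(z_hat) - (dim(z)/2) * log(2 pi)
```

where `z_hat` minimises the joint penalized NLL and `H` is its Hessian in
`z`.  The inner problem is solved by Newton iteration with analytic
gradients and an analytic sparse Hessian: the NB contribution is
`A' diag(w) A` for the sparse design `A` mapping effects to `eta`, plus an
observation-level cross block between `eta`-effects and the taxon
log-dispersion block, plus diagonal prior precisions.  Negative curvature
in the dispersion block is handled with adaptive Levenberg damping; a
predicted decrease below float precision is treated as convergence.
Factorisation uses sparse LU (the log-determinant comes from the pivots;
conditional random-effect SDs from the diagonal of the inverse).  Inner
gradient tolerance: 1e-8 (infinity norm).

Outer maximisation is L-BFGS-B (box bounds keep trial steps inside the
safe range of `exp`).  The objective returns the value and a
forward-difference gradient (step 1e-4) together, with every probe
warm-started from the mode at the evaluation point itself: letting probes
chain off each other makes the surface path-dependent wherever the
dispersion block has nearby local inner modes, which silently stalls the
optimizer.  Each start runs a coarse pass (projected-gradient tolerance
1e-2) followed by a fine pass (1e-3) whose inner anchor is reset cold —
warm-chained inner modes can get trapped in a poor local basin of the
dispersion block, and the cold restart reliably escapes it.  `fit_model`
defaults to three jittered starts; the phase-1 runner uses one start per
model but warm-chains initial values cumulatively (no-year fit seeds the
year models; the pooled year fit seeds the grouped ones), which we found
converges to the same optima at a fraction of the cost.  Wald SEs come
from a central-difference Hessian of the marginal NLL (steps 1e-3, every
evaluation anchored at the base-point mode), with delta-method
translation for log-scale parameters; non-positive curvature yields a
per-parameter missing SE, not a failure.  For speed, the inner Hessian's
sparsity pattern is cached so each assembly is a permutation plus
segmented sum, and the digamma/trigamma terms are evaluated on unique
(count, dispersion) values only.

AICc is `2*NLL + 2k + 2k(k+1)/(n-k-1)` with `k` the number of outer
parameters — a pure function of the model spec (9 for the no-year model,
11 with ungrouped year effects, 14 grouped by hosts, 11 + number of
taxonomic groups + 3 grouped by taxonomy).

Accuracy: against adaptive 61-point Gauss–Hermite quadrature on
single-effect configurations informed by ~50–150 observations, the Laplace
marginal NLL agrees to ~1e-4 for mean-type effects (fish, slopes).  The
log-dispersion dimension is the least Gaussian; its 1-D gap is ~1e-3–5e-3
at realistic sample sizes, which is negligible against between-model AICc
differences but is the reason the quadrature tolerance for dispersion-type
fixtures is looser in the tests.

## Pipeline conventions

- **Prevalence filter.**  A host–parasite pair is retained iff the taxon
  was found in at least 5% of that host species' dissected fish, pooled
  over all years (inclusive boundary).  Individuals partition exactly
  between the retained table and the rare-taxa report.  The filter is
  applied before model-specific exclusion of rows with missing covariates;
  such rows are kept in the table and dropped per model with a logged
  count.
- **SST.**  Monthly series are annualised by the rule "discard a year
  missing more than one month"; the annual value is the mean of the
  months present.
- **Pollutants.**  Replicate cores are averaged within year, interior gaps
  bridged by linear interpolation (never extrapolated), PCA is computed on
  the correlation matrix (units differ across metals and biomarkers; a
  covariance-PCA switch exists), components are signed so the
  largest-magnitude loading is positive, and the first two score series
  are LOESS-smoothed (tricube weights, span 0.75, degree 2 — the smoother
  is implemented directly because the local-regression routine available
  in the stack is degree-1 only) before year matching.
- **Availability subsets.**  Because interpolation never extends beyond a
  series' observed range, each phase-2 candidate is fit on the subset of
  rows where all of its covariates exist; AICc is compared only within
  groups of candidates sharing an identical subset, and cross-subset
  candidates are compared by effect size.  Host-density models keep only
  rows whose host species has a density series.
- **Phase 2** restricts to taxa with ≥ 3 obligate hosts and uses the
  ungrouped-slope spec (only one life-cycle class remains).  The default
  candidate list: year; SST; SST+year; PC1+PC2; PC1+PC2+year; density;
  density+year.
- **Effect sizes.**  A fitted effect `b` per SD of year converts to
  `(exp(10 b / sd_year) - 1) * 100` percent per decade; the analogous
  per-unit formula serves SST (°C).  Scaling metadata ride on every fit,
  so conversions are exact.
- **Figure-style outputs.**  The "average parasite within a group" for
  group prediction curves is the member taxon whose observed mean count
  per host is closest to the mean abundance over all taxa; its curve uses
  conditional modes with a band from conditional SDs.  Marginal-average
  curves put all effects at their hyper-means with a delta-method band
  from the outer covariance.  Binned observed summaries use half-open
  bins anchored at multiples of the width, dropping bins with fewer than
  25 observations.
- **Extirpation screen.**  Runs on raw detections (count > 0) in the
  pre-filter table: a taxon is flagged when its last detection is at
  least 40 years (default) before the reference year (default: last
  collection year), with post-gap sampling effort and per-decade
  occurrence frequencies reported.  No model output is used.

## Diagnostics

`simulate_responses` redraws the full hierarchy (new random effects, then
NB counts) or, optionally, only the counts conditional on given effect
values.  Randomized PIT residuals use
`(#less + u * (1 + #eq)) / (nsim + 1)`, which counts the observation among
its own ties and is therefore strictly inside (0, 1) and exactly uniform
under exchangeability.  Marginally (unconditionally) the residuals are
uniform but *correlated* across observations sharing a fish, pair or
taxon effect, which makes the iid-based KS test anticonservative; the
calibration property (type-I rate ≈ alpha) therefore holds for the
conditional residual check, and that is what the calibration test and the
acceptance script exercise.  The overdispersion test compares the variance
of standardized residuals (means/SDs estimated from the simulations) with
its simulated null; `p` is the two-sided simulation rank.

## Synthetic data

The generator mirrors the target survey: 8 host species; 85 taxa split
20 / 21 / 44 across 1 / 2 / 3+ obligate hosts (3+-host taxa draw 3 or 4
hosts at 80/20); each taxon host-specific, assigned round-robin across
species; broad taxonomy drawn from overlapping menus per life-cycle class
(directly transmitted groups for 1-host taxa, trophically transmitted
helminth groups for multi-host taxa) so taxonomy crosscuts life cycle and
the two grouping structures are statistically distinguishable.  Sampling
is decade-stratified over 1880–2019: each species-decade cell is empty
with probability 0.35, otherwise holds Binomial(20, 0.5) fish — roughly
700 fish in total with a per-cell median near the target design.
Latitude is uniform on 47–49° N; lengths are lognormal around a
species-level median.  Default hyper-parameters (log scale, per SD of
predictor): `mu_o = 0`, `sigma_o = 1`, `mu_lat = 0`, `sigma_lat = 0.25`,
`mu_len = 0.3`, `sigma_len = 0.25`, `sigma_zeta = 0.5`, `mu_phi = 1`,
`sigma_logphi = 0.75`, `sigma_gamma = 0.2`, group year-trends 0 — chosen
to give mean counts of a few parasites per fish with realistic
overdispersion and fish-level clustering.  Environmental series: monthly
SST with seasonal cycle, 1 °C/century trend, AR(1) noise (rho 0.6) and a
2% missing-month rate over 1921–2019; two sediment cores driven by two
latent factors (an industrial-rise logistic and a mid-century pulse) with
5% multiplicative measurement noise and 15% missing years; positive AR(1)
density series for six of the eight species over two era windows
(1946–1977, 1972–2011) with 10% gaps.  Counts can be coupled to the
latent SST series (`sst_effect_mu/sigma`) for phase-2 recovery tests.

What the generator does **not** emulate: spatial structure beyond a
latitude gradient, preservation artifacts (shrinkage, parasite loss in
fixatives), taxon-by-space hotspots, or secular changes in collection
practice.  Passing recovery tests therefore demonstrate that the
estimator recovers the model's own generative process at survey scale —
not that real museum data satisfy that process.

## Problem sizes and determinism

The recovery experiments run the full survey dimensions (~700 fish, 85
taxa, ~8000 rows, ~1100 random effects) with 5 seeded replicates in the
test suite (4 by default in the acceptance script, configurable with
``--replicates``); single-effect quadrature fixtures use
50–150 observations; diagnostic calibration uses 40 replicates of a
3-species / 12-taxon survey with 250 simulations each.  All randomness
flows from explicit seeds (generator default 20230109); index assignment
is lexicographic; refits under row permutation or a constant year shift
reproduce the NLL to 1e-6.

## Known limitations

- Outer gradients are finite-difference; the attainable projected-gradient
  tolerance (1e-3) is coarser than the inner tolerance, and Wald SEs near
  a variance-component boundary (`sigma -> 0`) can be unstable — they are
  reported as missing when curvature is non-positive.
- The Laplace approximation is least accurate in the per-taxon
  log-dispersion dimension (~1e-3–5e-3 in 1-D fixtures); quantities that
  depend on dispersion hyper-parameters inherit this.
- AICc uses the outer parameter count, the convention of
  marginal-likelihood mixed modelling; comparisons across different
  observation subsets are refused by design.
- No spatial random fields, zero-inflation, model averaging, or formal
  extirpation-date estimation.
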