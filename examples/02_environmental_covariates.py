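"""Build environmental predictor series and attach them to observations.

Annualises a monthly SST record (discarding years missing more than one
month), reduces a two-core pollutant matrix to smoothed principal
components, and joins everything to a small survey by collection year.
"""

import numpy as np

from paraburden import (
    attach_covariates,
    filter_by_prevalence,
    pca_pollutants,
    simulate_environment,
    simulate_survey,
)
from paraburden.simulate import SimConfig, simulate_pollutant_cores

cfg = SimConfig(n_host_species=3, taxa_per_group=(4, 4, 8), seed=7)

cores = simulate_pollutant_cores(cfg)
res = pca_pollutants(cores[0])
print("pollutant PCA on one core: PC1+PC2 explain "
      f"{100 * res.variance_explained[:2].sum():.1f}% of variance")

bundle = simulate_environment(cfg)
print(f"SST series covers {bundle.sst.years.min()}-{bundle.sst.years.max()} "
      f"({len(bundle.sst)} usable years after the missing-month rule)")
print(f"density series available for {len(bundle.host_density)} host species")

table, _ = simulate_survey(cfg)
filtered, _ = filter_by_prevalence(table)
attached = attach_covariates(filtered, bundle)
n_sst = attached.df["sst"].notna().sum()
print(f"{n_sst}/{len(attached)} rows have an SST value for their collection "
      "year (earlier fish predate the record and drop out of SST models)")
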