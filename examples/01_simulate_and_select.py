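"""Simulate a century-scale survey and select the year-effect structure.

Generates a full-size synthetic survey in which only parasites with three
or more obligate hosts decline, applies the 5% prevalence filter, fits the
four phase-1 model variants, and prints the AICc ranking plus the fitted
group trend converted to percent change per decade.
"""

from paraburden import (
    FitOptions,
    default_config,
    filter_by_prevalence,
    percent_change_per_decade,
    run_phase1,
    simulate_survey,
)
from paraburden.simulate import SimConfig

cfg = default_config()
cfg = SimConfig(**{**cfg.__dict__, "mu_gamma": (0.0, 0.0, -0.25), "seed": 101})
table, truth = simulate_survey(cfg)
print(f"simulated {table.n_fish} fish x {table.n_taxa} taxa "
      f"({table.total_individuals} parasite individuals)")

filtered, rare = filter_by_prevalence(table, threshold=0.05)
print(f"prevalence filter kept {filtered.n_taxa} taxa; "
      f"{rare.n_pairs} rare pairs ({rare.total_individuals} individuals) set aside")

result = run_phase1(filtered, options=FitOptions(n_starts=1))
print(result.comparison.table[["model", "k_fixed", "nll", "aicc",
                               "delta_aicc"]].to_string(index=False))

m2 = result.fits["M2_year_by_n_hosts"]
for group in m2.slope_group_labels:
    eff = m2.params[f"mu_gamma[year][{group}]"]
    pct = percent_change_per_decade(eff, m2.scaling["year"])
    print(f"group {group:>2}: year effect {eff:+.3f} per SD "
          f"-> {pct:+.1f}% per decade")
# A near-zero effect for 1- and 2-host taxa and a clear decline for the
# 3+-host group reproduces the generating truth (0, 0, -0.25).
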