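import pandas as pd
import pytest

from paraburden import (
    CountTable,
    FitOptions,
    ModelSpec,
    build_model_data,
    filter_by_prevalence,
    fit_model,
    simulate_survey,
)
from paraburden.simulate import SimConfig


@pytest.fixture(scope="session")
def small_survey():
    """A small but structured survey: 3 species, 16 taxa, ~100 fish."""
    cfg = SimConfig(
        n_host_species=3, taxa_per_group=(4, 4, 8), year_range=(1920, 2019),
        p_empty_cell=0.3, max_fish_per_cell=10, seed=21,
        mu_gamma=(0.0, 0.0, -0.4),
    )
    table, truth = simulate_survey(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def small_filtered(small_survey):
    _, table, truth = small_survey
    filtered, rare = filter_by_prevalence(table)
    return filtered, rare, truth


@pytest.fixture(scope="session")
def small_m2_fit(small_filtered):
    """One grouped-by-hosts fit on the small survey, with Wald SEs."""
    table, _, truth = small_filtered
    spec = ModelSpec(predictors=("year",), slope_grouping="by_n_hosts",
                     intercept_grouping="by_n_hosts")
    data = build_model_data(table, spec)
    fit = fit_model(data, options=FitOptions(n_starts=1, compute_se=True))
    return fit, data, truth


def toy_table(counts_by_fish_taxon, years=None, species="SPA",
              latitudes=None, lengths=None, taxa_meta=None):
    """Construct a CountTable from {fish: {taxon: count}} (explicit zeros)."""
    rows = []
    for fish, taxa in counts_by_fish_taxon.items():
        for taxon, count in taxa.items():
            rows.append({
                "fish_id": fish,
                "host_species": species if isinstance(species, str) else species[fish],
                "taxon_code": taxon,
                "count": count,
                "year": (years or {}).get(fish, 2000),
                "latitude": (latitudes or {}).get(fish, 48.0),
                "total_length_cm": (lengths or {}).get(fish, 30.0),
            })
    return CountTable(pd.DataFrame(rows), taxa=taxa_meta)
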