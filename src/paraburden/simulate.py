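"""Synthetic collection-survey generator with known truth.

Emulates the statistical structure the inference assumes: eight host
species sampled sparsely by decade over 1880-2019, a roster of common
parasite taxa split into 1-host / 2-host / 3+-host life-cycle groups,
fish-level random effects, taxon-level NB dispersion heterogeneity,
group-level log-linear year trends, and environmental series (SST,
two-core pollutant concentrations, per-species host density) with gaps.
Every draw is deterministic given the config seed, and the full truth
(all random effects and hyper-parameters) is returned for recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import (
    AnnualSeries,
    CovariateBundle,
    MonthlySeries,
    PollutantMatrix,
    annualize_sst,
    average_replicate_series,
    interpolate_annual,
    loess_annual,
    pca_pollutants,
)
from .dataio import CountTable

__all__ = ["SimConfig", "SimTruth", "simulate_survey", "simulate_environment",
           "simulate_pollutant_cores", "default_config"]

DEFAULT_SEED = 20230109

#: Broad-group menus per life-cycle class; single-host parasites are the
#: directly transmitted ectoparasite groups, multi-host ones the trophically
#: transmitted helminths.  Menus overlap so taxonomy crosscuts life cycle.
_GROUP_MENUS = {
    "1": ("Copepoda", "Monogenea", "Hirudinea"),
    "2": ("Trematoda", "Nematoda", "Copepoda"),
    "3+": ("Trematoda", "Cestoda", "Nematoda", "Acanthocephala"),
}


@dataclass
class SimConfig:
    """Study-condition defaults for the generator.

    Dimensions mirror the survey the pipeline targets: 8 host species,
    85 common taxa (20 with one obligate host, 21 with two, 44 with three
    or more), decade-stratified sampling 1880-2019 with a median of roughly
    9-10 fish per sampled species-decade cell (empty cells are common),
    giving on the order of 700 fish.  Hyper-parameters are per-SD effects on
    the log count scale; ``mu_gamma`` is the (1, 2, 3+) triple of group mean
    year trends per SD of year.
    """

    n_host_species: int = 8
    taxa_per_group: tuple = (20, 21, 44)
    year_range: tuple = (1880, 2019)
    p_empty_cell: float = 0.35
    max_fish_per_cell: int = 20
    p_fish: float = 0.5
    latitude_range: tuple = (47.0, 49.0)
    tl_median_range: tuple = (15.0, 60.0)
    tl_log_sd: float = 0.25

    mu_o: float = 0.0
    sigma_o: float = 1.0
    mu_lat: float = 0.0
    sigma_lat: float = 0.25
    mu_len: float = 0.3
    sigma_len: float = 0.25
    sigma_zeta: float = 0.5
    mu_phi: float = 1.0
    sigma_logphi: float = 0.75
    mu_gamma: tuple = (0.0, 0.0, 0.0)
    sigma_gamma: float = 0.2
    sst_effect_mu: float = 0.0
    sst_effect_sigma: float = 0.2

    sst_years: tuple = (1921, 2019)
    sst_mean: float = 10.0
    sst_seasonal_amp: float = 3.0
    sst_trend_per_century: float = 1.0
    sst_ar1_rho: float = 0.6
    sst_noise_sd: float = 0.35
    sst_missing_month_rate: float = 0.02

    pollutant_years: tuple = (1774, 2005)
    n_pollutant_vars: int = 12
    pollutant_noise_sd: float = 0.05
    pollutant_gap_rate: float = 0.15

    density_species: int = 6
    density_windows: tuple = ((1946, 1977), (1972, 2011))
    density_gap_rate: float = 0.1

    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if any(s <= 0 for s in (self.sigma_o, self.sigma_lat, self.sigma_len,
                                self.sigma_zeta, self.sigma_logphi,
                                self.sigma_gamma)):
            raise ValueError("all hyper-parameter SDs must be > 0")
        if any(t < 1 for t in self.taxa_per_group):
            raise ValueError("each life-cycle group needs at least one taxon")


@dataclass
class SimTruth:
    """Everything needed to recompute a simulated table deterministically."""

    config: SimConfig
    taxa: pd.DataFrame
    gamma_year: np.ndarray
    gamma_sst: np.ndarray | None
    log_phi: np.ndarray
    beta_o: np.ndarray
    beta_lat: np.ndarray
    beta_len: np.ndarray
    zeta: dict
    year_scaling: tuple  # (mean, sd) used when applying year effects
    seeds: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "year_scaling": list(self.year_scaling),
            "gamma_year": self.gamma_year.tolist(),
            "log_phi": self.log_phi.tolist(),
            "beta_o": self.beta_o.tolist(),
            "beta_lat": self.beta_lat.tolist(),
            "beta_len": self.beta_len.tolist(),
            "zeta": {k: float(v) for k, v in self.zeta.items()},
            "seeds": self.seeds,
        }
        if self.gamma_sst is not None:
            payload["gamma_sst"] = self.gamma_sst.tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def default_config() -> SimConfig:
    """The default study conditions (8 species, 85 taxa, 1880-2019)."""
    return SimConfig()


def _taxon_frame(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n1, n2, n3 = config.taxa_per_group
    labels = ["1"] * n1 + ["2"] * n2 + ["3+"] * n3
    n_hosts = [1] * n1 + [2] * n2 + list(rng.choice([3, 4], size=n3, p=[0.8, 0.2]))
    codes = [f"TX{i + 1:03d}" for i in range(len(labels))]
    species = [f"SP{(i % config.n_host_species) + 1:02d}" for i in range(len(labels))]
    counters = {g: 0 for g in _GROUP_MENUS}
    broad = []
    for g in labels:
        menu = _GROUP_MENUS[g]
        broad.append(menu[counters[g] % len(menu)])
        counters[g] += 1
    df = pd.DataFrame({
        "taxon_code": codes,
        "taxon_name": [f"Synthetic taxon {c}" for c in codes],
        "broad_group": broad,
        "n_obligate_hosts": n_hosts,
        "life_cycle_group": labels,
        "host_species": species,
        "host_specific_name": True,
    })
    return df.set_index("taxon_code", drop=False)


def simulate_survey(config: SimConfig | None = None,
                    bundle: CovariateBundle | None = None
                    ) -> tuple[CountTable, SimTruth]:
    """Draw a complete survey (fish, roster, counts) from the model.

    When ``config.sst_effect_mu`` or ``config.sst_effect_sigma`` couple
    counts to temperature, the latent SST series is generated internally
    (or taken from ``bundle``) and its scaled value enters the linear
    predictor alongside the year trend.
    """
    config = config or default_config()
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_fish, rng_effects, rng_counts = (
        np.random.default_rng(s) for s in ss.spawn(4))

    taxa = _taxon_frame(config, rng_struct)
    species = [f"SP{i + 1:02d}" for i in range(config.n_host_species)]
    roster = {sp: taxa.index[taxa["host_species"] == sp].tolist() for sp in species}

    # --- fish, decade-stratified ---------------------------------------
    y0, y1 = config.year_range
    decades = np.arange((y0 // 10) * 10, y1 + 1, 10)
    fish_rows = []
    fid = 0
    for sp in species:
        tl_median = np.exp(rng_fish.uniform(np.log(config.tl_median_range[0]),
                                            np.log(config.tl_median_range[1])))
        for dec in decades:
            if rng_fish.random() < config.p_empty_cell:
                continue
            n_cell = int(rng_fish.binomial(config.max_fish_per_cell, config.p_fish))
            for _ in range(n_cell):
                year = int(rng_fish.integers(max(dec, y0), min(dec + 9, y1) + 1))
                fish_rows.append({
                    "fish_id": f"F{fid:05d}",
                    "host_species": sp,
                    "year": year,
                    "latitude": float(rng_fish.uniform(*config.latitude_range)),
                    "total_length_cm": float(
                        np.exp(rng_fish.normal(np.log(tl_median), config.tl_log_sd))),
                })
                fid += 1
    fish = pd.DataFrame(fish_rows)
    if not len(fish):
        empty = pd.DataFrame(columns=[
            "fish_id", "host_species", "taxon_code", "count", "year",
            "latitude", "total_length_cm"])
        truth = SimTruth(config, taxa, np.zeros(len(taxa)), None,
                         np.zeros(len(taxa)), np.zeros(len(taxa)),
                         np.zeros(len(taxa)), np.zeros(len(taxa)), {},
                         (0.0, 1.0))
        return CountTable(empty, taxa=taxa), truth

    # --- random effects -------------------------------------------------
    K = len(taxa)
    group_idx = taxa["life_cycle_group"].map({"1": 0, "2": 1, "3+": 2}).to_numpy()
    mu_gamma = np.asarray(config.mu_gamma, dtype=float)[group_idx]
    gamma_year = rng_effects.normal(mu_gamma, config.sigma_gamma)
    log_phi = rng_effects.normal(np.log(config.mu_phi), config.sigma_logphi, size=K)
    beta_o = rng_effects.normal(config.mu_o, config.sigma_o, size=K)  # J == K
    beta_lat = rng_effects.normal(config.mu_lat, config.sigma_lat, size=K)
    beta_len = rng_effects.normal(config.mu_len, config.sigma_len, size=K)
    zeta = rng_effects.normal(0.0, config.sigma_zeta, size=len(fish))
    zeta_map = dict(zip(fish["fish_id"], zeta))

    gamma_sst = None
    sst_lookup = None
    if config.sst_effect_mu != 0.0:
        gamma_sst = rng_effects.normal(config.sst_effect_mu,
                                       config.sst_effect_sigma, size=K)
        env = bundle or simulate_environment(config)
        if env.sst is None or not len(env.sst):
            raise ValueError("SST coupling requested but no SST series available")
        vals = env.sst.value_for(fish["year"].to_numpy())
        vals = np.where(np.isnan(vals), np.nanmean(env.sst.values), vals)
        mu_s, sd_s = float(np.mean(vals)), float(np.std(vals, ddof=1))
        sst_lookup = dict(zip(fish["fish_id"], (vals - mu_s) / max(sd_s, 1e-12)))

    # --- expand to rows and emit counts ---------------------------------
    taxon_pos = {t: i for i, t in enumerate(taxa.index)}
    blocks = []
    for sp in species:
        sub = fish[fish["host_species"] == sp]
        tx = roster[sp]
        if not len(sub) or not tx:
            continue
        block = sub.loc[sub.index.repeat(len(tx))].reset_index(drop=True)
        block["taxon_code"] = np.tile(tx, len(sub))
        blocks.append(block)
    rows = pd.concat(blocks, ignore_index=True)

    yr = rows["year"].to_numpy(dtype=float)
    yr_mean, yr_sd = float(np.mean(yr)), float(np.std(yr, ddof=1))
    lat = rows["latitude"].to_numpy()
    lat_s = (lat - lat.mean()) / max(np.std(lat, ddof=1), 1e-12)
    tl = rows["total_length_cm"].to_numpy()
    tl_s = (tl - tl.mean()) / max(np.std(tl, ddof=1), 1e-12)
    kpos = rows["taxon_code"].map(taxon_pos).to_numpy()
    eta = (
        beta_o[kpos]
        + lat_s * beta_lat[kpos]
        + tl_s * beta_len[kpos]
        + np.array([zeta_map[f] for f in rows["fish_id"]])
        + ((yr - yr_mean) / max(yr_sd, 1e-12)) * gamma_year[kpos]
    )
    if gamma_sst is not None:
        eta = eta + np.array([sst_lookup[f] for f in rows["fish_id"]]) * gamma_sst[kpos]
    mu = np.exp(eta)
    phi = np.exp(log_phi)[kpos]
    counts = rng_counts.negative_binomial(phi, phi / (phi + mu))
    rows["count"] = counts.astype(int)
    cols = ["fish_id", "host_species", "taxon_code", "count", "year",
            "latitude", "total_length_cm"]
    rows = rows[cols].sort_values(["host_species", "fish_id", "taxon_code"])
    table = CountTable(rows.reset_index(drop=True), taxa=taxa)

    truth = SimTruth(
        config=config, taxa=taxa, gamma_year=gamma_year, gamma_sst=gamma_sst,
        log_phi=log_phi, beta_o=beta_o, beta_lat=beta_lat, beta_len=beta_len,
        zeta=zeta_map, year_scaling=(yr_mean, yr_sd),
        seeds={"seed": config.seed},
    )
    return table, truth


# ---------------------------------------------------------------------------
# environment


def _simulate_sst_monthly(config: SimConfig, rng: np.random.Generator
                          ) -> MonthlySeries:
    y0, y1 = config.sst_years
    years = np.arange(y0, y1 + 1)
    seasonal = -config.sst_seasonal_amp * np.cos(2 * np.pi * (np.arange(12)) / 12)
    recs = []
    e = 0.0
    for year in years:
        trend = config.sst_trend_per_century * (year - y0) / 100.0
        for m in range(12):
            e = config.sst_ar1_rho * e + rng.normal(0.0, config.sst_noise_sd) \
                if config.sst_noise_sd > 0 else 0.0
            if rng.random() < config.sst_missing_month_rate:
                continue
            recs.append({"year": int(year), "month": m + 1,
                         "value": config.sst_mean + seasonal[m] + trend + e})
    return MonthlySeries(pd.DataFrame(recs), units="degC")


def simulate_pollutant_cores(config: SimConfig | None = None,
                             rng: np.random.Generator | None = None
                             ) -> list:
    """Two sediment cores driven by two latent contamination factors.

    With zero noise the standardized concentration matrix is exactly rank 2,
    so the first two principal components explain all the variance.
    """
    config = config or default_config()
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(7)[-1])
    y0, y1 = config.pollutant_years
    years = np.arange(y0, y1 + 1)
    t = (years - y0) / (y1 - y0)
    f1 = 1.0 / (1.0 + np.exp(-8 * (t - 0.6)))        # industrial rise
    f2 = np.exp(-((t - 0.75) ** 2) / 0.02)           # mid-century pulse
    F = np.column_stack([(f - f.mean()) / f.std() for f in (f1, f2)])
    V = config.n_pollutant_vars
    base = rng.uniform(5.0, 50.0, size=V)
    load = rng.uniform(0.4, 1.0, size=(V, 2)) * rng.choice([1.0, 1.0, -1.0], size=(V, 2))
    names = ["lead", "arsenic", "zinc", "nickel", "vanadium", "chromium",
             "copper", "barium", "beryllium", "lignin", "soil_biomarker_a",
             "soil_biomarker_b"][:V]
    cores = []
    for core_id in ("PS-1", "PS-4"):
        X = base[None, :] * (1.0 + 0.12 * (F @ load.T))
        if config.pollutant_noise_sd > 0:
            X = X * (1.0 + rng.normal(0.0, config.pollutant_noise_sd, size=X.shape))
        X = np.clip(X, 1e-6, None)
        keep = rng.random(len(years)) >= config.pollutant_gap_rate
        keep[0] = keep[-1] = True
        df = pd.DataFrame(X[keep], index=pd.Index(years[keep], name="year"),
                          columns=names)
        cores.append(PollutantMatrix(df, core_id=core_id))
    return cores


def simulate_environment(config: SimConfig | None = None) -> CovariateBundle:
    """Generate the full covariate bundle (SST, pollutant PCs, densities).

    Pollutant principal components are produced by the same pipeline the
    analysis uses on real cores: average the two cores by year, interpolate
    interior gaps, PCA on the correlation matrix, then LOESS-smooth the
    first two score series.
    """
    config = config or default_config()
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(8)
    rng_sst = np.random.default_rng(streams[4])
    rng_dens = np.random.default_rng(streams[5])
    rng_poll = np.random.default_rng(streams[6])

    sst = annualize_sst(_simulate_sst_monthly(config, rng_sst))

    cores = simulate_pollutant_cores(config, rng=rng_poll)
    merged = {}
    for name in cores[0].df.columns:
        series = [AnnualSeries(c.df.index.to_numpy(), c.df[name].to_numpy(),
                               name=name) for c in cores]
        avg = average_replicate_series(series)
        merged[name] = interpolate_annual(avg)
    years = merged[next(iter(merged))].years
    mat = PollutantMatrix(
        pd.DataFrame({n: s.values for n, s in merged.items()},
                     index=pd.Index(years, name="year")))
    pca = pca_pollutants(mat)
    pc1 = loess_annual(AnnualSeries(years, pca.scores["PC1"].to_numpy(),
                                    name="pollutant_pc1"))
    pc2 = loess_annual(AnnualSeries(years, pca.scores["PC2"].to_numpy(),
                                    name="pollutant_pc2"))

    density = {}
    for i in range(min(config.density_species, config.n_host_species)):
        sp = f"SP{i + 1:02d}"
        w0, w1 = config.density_windows[0 if i < 4 else 1]
        yrs = np.arange(w0, w1 + 1)
        e = np.zeros(len(yrs))
        for t in range(1, len(yrs)):
            e[t] = 0.7 * e[t - 1] + rng_dens.normal(0.0, 0.25)
        vals = np.exp(np.log(rng_dens.uniform(0.5, 5.0)) + e)
        keep = rng_dens.random(len(yrs)) >= config.density_gap_rate
        keep[0] = keep[-1] = True
        density[sp] = AnnualSeries(yrs[keep], vals[keep], name=f"density_{sp}")

    return CovariateBundle(sst=sst, pollutant_pc1=pc1, pollutant_pc2=pc2,
                           host_density=density)
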