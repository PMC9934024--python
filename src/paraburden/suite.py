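"""Phase-1 and phase-2 model suites.

Phase 1 asks whether parasite counts changed through time by comparing, on
one fixed observation set, a no-year model against three year-effect models
with different hierarchical grouping structures (none / by number of
obligate hosts / by broad taxonomy), ranked by AICc.

Phase 2 restricts to taxa with three or more obligately required hosts and
swaps or adds environmental covariates (SST, pollutant principal
components, host density) for year.  Because the covariate records span
different eras, each candidate is fit on the subset of observations where
all of its covariates are available; AICc is only comparable within groups
of models sharing the same subset, and cross-subset candidates are compared
by effect size instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .dataio import BROAD_GROUPS, CountTable
from .nbglmm import (
    FitOptions,
    FitResult,
    ModelSpec,
    build_model_data,
    fit_model,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PHASE1_SPECS",
    "DEFAULT_PHASE2_CANDIDATES",
    "ModelComparison",
    "Phase1Result",
    "run_phase1",
    "subset_by_covariate_availability",
    "run_phase2",
    "extract_taxon_effects",
]

#: The four phase-1 variants, in reporting order.
PHASE1_SPECS = {
    "M0_no_year": ModelSpec(),
    "M1_year_by_taxon": ModelSpec(predictors=("year",)),
    "M2_year_by_n_hosts": ModelSpec(predictors=("year",),
                                    slope_grouping="by_n_hosts",
                                    intercept_grouping="by_n_hosts"),
    "M3_year_by_taxonomy": ModelSpec(predictors=("year",),
                                     slope_grouping="by_taxonomy",
                                     intercept_grouping="by_taxonomy"),
}

#: Phase-2 candidate predictor sets (each fit on its availability subset).
DEFAULT_PHASE2_CANDIDATES = (
    ("year",),
    ("sst",),
    ("sst", "year"),
    ("pollutant_pc1", "pollutant_pc2"),
    ("pollutant_pc1", "pollutant_pc2", "year"),
    ("host_density",),
    ("host_density", "year"),
)


@dataclass
class ModelComparison:
    """AICc ranking of fits sharing one observation set."""

    table: pd.DataFrame
    failures: dict = field(default_factory=dict)

    @property
    def best_label(self) -> str:
        return self.table.loc[self.table["delta_aicc"].idxmin(), "model"]

    @classmethod
    def from_fits(cls, fits: dict, failures: dict | None = None) -> "ModelComparison":
        rows = []
        for label, fit in fits.items():
            rows.append({"model": label, "k_fixed": fit.k_fixed, "n": fit.n,
                         "nll": fit.nll, "aicc": fit.aicc})
        df = pd.DataFrame(rows)
        df["delta_aicc"] = df["aicc"] - df["aicc"].min()
        df["best"] = df["delta_aicc"] == 0.0
        if df["best"].sum() > 1:  # exact tie: keep the first as flagged best
            first = df.index[df["best"]][0]
            df["best"] = False
            df.loc[first, "best"] = True
        return cls(df.sort_values("aicc").reset_index(drop=True),
                   failures=dict(failures or {}))


@dataclass
class Phase1Result:
    comparison: ModelComparison
    fits: dict  # label -> FitResult

    @property
    def best_fit(self) -> FitResult:
        return self.fits[self.comparison.best_label]


def run_phase1(table: CountTable, options: FitOptions | None = None,
               compute_se: str | bool = "best") -> Phase1Result:
    """Fit the four phase-1 models on one observation set and rank by AICc.

    All four models are built from the same table (the year column is a
    predictor only where the spec says so, so the response vectors are
    identical).  The no-year fit is run first and its estimates seed the
    year models.  ``compute_se`` is True, False or ``"best"`` (SEs for the
    grouped-by-hosts and best models only).
    """
    options = options or FitOptions(n_starts=1)
    fits: dict = {}
    failures: dict = {}
    chain_init: dict = {}
    for label, spec in PHASE1_SPECS.items():
        data = build_model_data(table, spec)
        opts = FitOptions(**{**options.__dict__,
                             "compute_se": compute_se is True,
                             "init": {**chain_init, **(options.init or {})}})
        try:
            fits[label] = fit_model(data, options=opts)
        except Exception as exc:  # noqa: BLE001 - survivors are still compared
            logger.warning("phase-1 fit %s failed: %s", label, exc)
            failures[label] = repr(exc)
            continue
        # cumulative warm chain: each model seeds the next (shared blocks)
        fitted = fits[label].params
        chain_init.update({k: v for k, v in fitted.items()
                           if not k.startswith("mu_gamma")})
        chain_init["mu_beta_o"] = fitted.get("mu_beta_o",
                                             fitted.get("mu_o", 0.0))
        chain_init["mu_o"] = fitted.get("mu_o",
                                        fitted.get("mu_beta_o", 0.0))
        if label == "M1_year_by_taxon":
            # grouped specs start their group means at the pooled mean
            mg = fitted.get("mu_gamma[year]", 0.0)
            for g in ("1", "2", "3+", *BROAD_GROUPS):
                chain_init[f"mu_gamma[year][{g}]"] = mg
    if not fits:
        raise RuntimeError(f"all phase-1 fits failed: {failures}")
    comparison = ModelComparison.from_fits(fits, failures)
    if compute_se == "best":
        from .nbglmm import wald_se

        for label in {comparison.best_label, "M2_year_by_n_hosts"} & set(fits):
            wald_se(fits[label])
    return Phase1Result(comparison=comparison, fits=fits)


def subset_by_covariate_availability(table: CountTable, covariate: str
                                     ) -> CountTable:
    """Rows with a non-missing value of ``covariate`` (logged retention)."""
    if covariate not in table.df.columns:
        raise ValueError(f"covariate {covariate!r} not attached")
    mask = table.df[covariate].notna()
    logger.info("subset_by_covariate_availability(%s): %d/%d rows retained",
                covariate, int(mask.sum()), len(mask))
    out = table.copy()
    out.df = out.df[mask.to_numpy()].reset_index(drop=True)
    return out


def _phase2_label(predictors: tuple) -> str:
    return "+".join(predictors)


def run_phase2(table: CountTable,
               candidates: tuple = DEFAULT_PHASE2_CANDIDATES,
               options: FitOptions | None = None,
               min_hosts: int = 3) -> dict:
    """Fit environmental-driver candidates on 3+-host taxa.

    Returns ``{label: FitResult}``; ``FitResult.n`` records each candidate's
    subset size.  Use :func:`phase2_comparisons` to rank candidates that
    share a subset.
    """
    if table.taxa is None:
        raise ValueError("phase 2 requires taxon metadata (n_obligate_hosts)")
    keep_taxa = table.taxa.index[table.taxa["n_obligate_hosts"] >= min_hosts]
    sub = table.copy()
    sub.df = sub.df[sub.df["taxon_code"].isin(keep_taxa)].reset_index(drop=True)
    sub.taxa = sub.taxa.loc[sub.taxa.index.isin(sub.df["taxon_code"].unique())]
    options = options or FitOptions(n_starts=1, compute_se=True)

    fits: dict = {}
    for predictors in candidates:
        work = sub
        skip = False
        for cov in predictors:
            if cov not in work.df.columns:
                logger.warning("phase-2 candidate %s skipped: %s not attached",
                               predictors, cov)
                skip = True
                break
            work = subset_by_covariate_availability(work, cov)
        if skip or not len(work.df):
            logger.warning("phase-2 candidate %s skipped: empty subset", predictors)
            continue
        spec = ModelSpec(predictors=tuple(predictors))
        data = build_model_data(work, spec)
        label = _phase2_label(tuple(predictors))
        try:
            fits[label] = fit_model(data, options=options)
        except Exception as exc:  # noqa: BLE001
            logger.warning("phase-2 fit %s failed: %s", label, exc)
    return fits


def phase2_comparisons(fits: dict) -> list:
    """Group phase-2 fits by identical observation subset and rank each
    group by AICc; models on different subsets are never ranked together."""
    groups: dict = {}
    for label, fit in fits.items():
        groups.setdefault(fit.n, {})[label] = fit
    return [ModelComparison.from_fits(g) for _, g in sorted(groups.items())]


def extract_taxon_effects(fit: FitResult, predictor: str) -> pd.DataFrame:
    """Per-taxon conditional modes and SDs of a predictor's random effect.

    One row per taxon with the effect (per SD of the predictor), its
    conditional SE, and the taxon's group labels; the frame's ``attrs``
    carry the group-level means and their Wald SEs ("mean effect over all
    taxa").
    """
    block = f"gamma[{predictor}]"
    if block not in fit.re_modes:
        raise ValueError(f"fit has no effect for predictor {predictor!r}; "
                         f"available: {list(fit.re_modes)}")
    taxa = fit.re_labels[block]
    meta = fit.taxon_meta
    df = pd.DataFrame({
        "taxon_code": taxa,
        "predictor": predictor,
        "effect": fit.re_modes[block],
        "cond_se": fit.re_sds[block],
    })
    for col in ("n_obligate_hosts", "broad_group", "abundance"):
        if col in meta.columns:
            df[col] = meta.reindex(taxa)[col].to_numpy()

    means = {}
    if fit.spec.slope_grouping == "none":
        name = f"mu_gamma[{predictor}]"
        means["all"] = (fit.params.get(name), fit.se.get(name))
    else:
        for g in fit.slope_group_labels:
            name = f"mu_gamma[{predictor}][{g}]"
            means[g] = (fit.params.get(name), fit.se.get(name))
    df.attrs["group_means"] = means
    return df
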