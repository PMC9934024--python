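"""Effect-size conversion, prediction curves, binned summaries, and the
extirpation screen.

Fitted effects live on the scale of standardized predictors (per SD of year,
SST, ...).  The converters here undo that scaling exactly, e.g. turning a
per-SD-of-year log slope into a percent change per decade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import CountTable, ScalingInfo
from .nbglmm import FitResult

__all__ = [
    "PredictionCurve",
    "ExtirpationReport",
    "percent_change_per_decade",
    "percent_change_per_unit",
    "predict_group_average",
    "predict_marginal_average",
    "bin_counts",
    "extirpation_report",
]


@dataclass
class PredictionCurve:
    """Predicted count per host along a natural-scale grid with a +/-1 SE band."""

    grid: np.ndarray
    predicted: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    variable: str
    provenance: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            self.variable: self.grid, "predicted": self.predicted,
            "lower": self.lower, "upper": self.upper,
        })


@dataclass
class ExtirpationReport:
    """Taxa unseen for at least ``min_gap_years`` before the reference year."""

    table: pd.DataFrame
    min_gap_years: int
    reference_year: int

    @property
    def n_flagged(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# effect-size conversion


def percent_change_per_decade(effect_on_scaled_year: float,
                              scaling: ScalingInfo) -> float:
    """Percent change in expected count per 10 calendar years.

    ``effect_on_scaled_year`` is the log-scale slope per SD of year;
    dividing by the year SD gives the per-year slope, and
    ``(exp(10 * slope) - 1) * 100`` is the decade change (negative =
    decline).
    """
    if not scaling.sd > 0:
        raise ValueError("year scaling SD must be > 0")
    return (np.exp(10.0 * effect_on_scaled_year / scaling.sd) - 1.0) * 100.0


def percent_change_per_unit(effect_on_scaled_covariate: float,
                            scaling: ScalingInfo, unit: float = 1.0) -> float:
    """Percent change in expected count per natural-scale covariate unit
    (e.g. per 1 degC of SST)."""
    if not scaling.sd > 0:
        raise ValueError("covariate scaling SD must be > 0")
    return (np.exp(unit * effect_on_scaled_covariate / scaling.sd) - 1.0) * 100.0


def decade_percent_to_slope(percent: float, scaling: ScalingInfo) -> float:
    """Inverse of :func:`percent_change_per_decade` (slope per SD of year)."""
    return np.log(1.0 + percent / 100.0) / 10.0 * scaling.sd


# ---------------------------------------------------------------------------
# prediction curves


def _group_key_for(fit: FitResult) -> pd.Series:
    meta = fit.taxon_meta
    if "n_obligate_hosts" not in meta.columns:
        raise ValueError("fit lacks n_obligate_hosts metadata")
    return meta["n_obligate_hosts"].map(lambda n: "3+" if n >= 3 else str(int(n)))


def representative_taxon(fit: FitResult, group: str) -> str:
    """The 'average' taxon of a life-cycle group: the member whose observed
    mean abundance is closest to the average abundance over *all* taxa."""
    meta = fit.taxon_meta
    key = _group_key_for(fit)
    members = meta.index[key == group]
    if not len(members):
        raise ValueError(f"no taxa in life-cycle group {group!r}")
    target = meta["abundance"].mean()
    gaps = (meta.loc[members, "abundance"] - target).abs()
    return gaps.idxmin()


def predict_group_average(fit: FitResult, years: np.ndarray, group: str
                          ) -> PredictionCurve:
    """Predicted counts over years for the representative taxon of a group.

    Random effects are held at their conditional modes (other covariates at
    their means, i.e. zero on the scaled scale); the band propagates the
    conditional SDs of the intercept and year effect.
    """
    years = np.asarray(years, dtype=float)
    taxon = representative_taxon(fit, group)
    if "year" not in fit.scaling:
        raise ValueError("fit has no year effect")
    u = fit.scaling["year"].transform(years)

    k = fit.re_labels["gamma[year]"].index(taxon)
    gamma = fit.re_modes["gamma[year]"][k]
    gamma_sd = fit.re_sds["gamma[year]"][k]

    # the taxon's (best-sampled) pair intercept
    pair_ids = [i for i, (_, t) in enumerate(fit.pair_labels) if t == taxon]
    j = pair_ids[0]
    eta0 = fit.re_modes["beta_o"][j] if "beta_o" in fit.re_modes \
        else fit.params.get("mu_o", 0.0)
    sd0 = fit.re_sds["beta_o"][j] if "beta_o" in fit.re_sds else 0.0
    if "beta_og" in fit.re_modes:
        g = fit.re_labels["beta_og"].index(group) if group in fit.re_labels["beta_og"] else None
        if g is not None:
            eta0 = eta0 + fit.re_modes["beta_og"][g]
            sd0 = float(np.hypot(sd0, fit.re_sds["beta_og"][g]))

    eta = eta0 + u * gamma
    se = np.sqrt(sd0 ** 2 + (u * gamma_sd) ** 2)
    pred = np.exp(eta)
    return PredictionCurve(
        grid=years, predicted=pred,
        lower=np.exp(eta - se), upper=np.exp(eta + se),
        variable="year",
        provenance={"taxon": taxon, "group": group, "rule": "closest-to-mean-abundance"},
    )


def predict_marginal_average(fit: FitResult, covariate: str, grid: np.ndarray
                             ) -> PredictionCurve:
    """Predictions for an average taxon of an average pair.

    All random effects sit at their hyper-means, so the curve is
    ``exp(mu_o + u * mu_gamma)`` along the scaled grid; the +/-1 SE band is
    a delta-method propagation of the outer-parameter covariance.
    Grid points outside the covariate's observed range are flagged.
    """
    if covariate not in fit.scaling:
        raise ValueError(f"covariate {covariate!r} not in fit")
    grid = np.asarray(grid, dtype=float)
    sc = fit.scaling[covariate]
    u = sc.transform(grid)
    if np.any(np.abs(u) > 4):
        import warnings

        warnings.warn(f"{covariate}: grid extends well beyond observed range "
                      "(extrapolation)")

    mu_o_name = "mu_o" if "mu_o" in fit.params else "mu_beta_o"
    if fit.spec.slope_grouping == "none":
        slope_names = [f"mu_gamma[{covariate}]"]
        weights = [np.ones_like(u)]
    else:
        slope_names = [f"mu_gamma[{covariate}][{g}]" for g in fit.slope_group_labels]
        # marginal over groups: average group means weighted by taxon counts
        key = _group_key_for(fit) if fit.spec.slope_grouping == "by_n_hosts" \
            else fit.taxon_meta["broad_group"]
        counts = key.value_counts()
        w = np.array([counts.get(g, 0) for g in fit.slope_group_labels], dtype=float)
        w = w / w.sum()
        weights = [wi * np.ones_like(u) for wi in w]

    eta = np.full_like(u, fit.params[mu_o_name])
    for name, w in zip(slope_names, weights):
        eta = eta + u * w * fit.params[name]

    # delta method: eta is linear in (mu_o, slopes)
    names = [mu_o_name] + slope_names
    se = np.zeros_like(u)
    if fit.outer_cov is not None and fit.se:
        all_names = list(fit.params.keys())
        idx = [all_names.index(n) for n in names]
        C = fit.outer_cov[np.ix_(idx, idx)]
        G = np.column_stack([np.ones_like(u)] +
                            [u * w for w in weights])  # d eta / d params
        se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", G, C, G), 0.0, None))
    elif fit.se:
        se = np.sqrt(fit.se.get(mu_o_name, 0.0) ** 2 +
                     sum((u * w * fit.se.get(n, 0.0)) ** 2
                         for n, w in zip(slope_names, weights)))
    pred = np.exp(eta)
    return PredictionCurve(
        grid=grid, predicted=pred, lower=np.exp(eta - se), upper=np.exp(eta + se),
        variable=covariate,
        provenance={"kind": "marginal-average", "covariate": covariate},
    )


# ---------------------------------------------------------------------------
# binned observed summaries


def bin_counts(table: CountTable, variable: str, width: float,
               min_n: int = 25) -> pd.DataFrame:
    """Mean observed count in half-open natural-unit bins of ``variable``.

    Bins are ``[lower, lower + width)`` anchored at multiples of ``width``;
    bins with fewer than ``min_n`` observations are omitted.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    if variable not in table.df.columns:
        raise ValueError(f"variable {variable!r} not attached")
    df = table.df.dropna(subset=[variable])
    lower = np.floor(df[variable].to_numpy(dtype=float) / width) * width
    out = (
        pd.DataFrame({"lower": lower, "count": df["count"].to_numpy()})
        .groupby("lower")["count"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "mean_count", "size": "n"})
    )
    out = out[out["n"] >= min_n].reset_index(drop=True)
    out["bin_center"] = out["lower"] + width / 2.0
    return out[["bin_center", "mean_count", "n", "lower"]]


# ---------------------------------------------------------------------------
# extirpation screen


def extirpation_report(table: CountTable, min_gap_years: int = 40,
                       reference_year: int | None = None,
                       period_width: int = 10) -> ExtirpationReport:
    """Flag taxa not detected for at least ``min_gap_years``.

    Works on raw detections (count > 0; run it on the pre-filter table so
    rare taxa are screened too).  For each flagged taxon the report gives
    the last detection year, the gap, how many of its host's fish were
    dissected after the last detection (post-gap sampling effort), life
    cycle class, and per-period occurrence frequencies.
    """
    df = table.df
    if reference_year is None:
        reference_year = int(df["year"].max())
    if reference_year < df["year"].min():
        raise ValueError("reference_year precedes all data")
    rows = []
    for taxon, sub in df.groupby("taxon_code"):
        detected = sub[sub["count"] > 0]
        if not len(detected):
            continue
        last = int(detected["year"].max())
        gap = reference_year - last
        if gap < min_gap_years:
            continue
        hosts = sub["host_species"].unique()
        later = df[(df["host_species"].isin(hosts)) & (df["year"] > last)]
        n_after = later["fish_id"].nunique()
        periods = {}
        lo = int(np.floor(sub["year"].min() / period_width) * period_width)
        for start in range(lo, reference_year + 1, period_width):
            win = sub[(sub["year"] >= start) & (sub["year"] < start + period_width)]
            if len(win):
                periods[f"{start}s"] = float((win["count"] > 0).mean())
        entry = {
            "taxon_code": taxon,
            "last_detection_year": last,
            "years_since_last_detection": gap,
            "n_dissected_after": int(n_after),
            "occurrence_by_period": periods,
        }
        if table.taxa is not None and taxon in table.taxa.index:
            n_h = table.taxa.loc[taxon, "n_obligate_hosts"]
            entry["n_obligate_hosts"] = int(n_h)
            entry["life_cycle"] = "complex" if n_h >= 2 else "direct"
        rows.append(entry)
    out = pd.DataFrame(rows)
    return ExtirpationReport(table=out, min_gap_years=min_gap_years,
                             reference_year=reference_year)
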