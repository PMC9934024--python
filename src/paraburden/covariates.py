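"""Environmental covariate construction.

Builds the annual predictor series the models consume: annualised sea surface
temperature (SST) from monthly lighthouse records, pollutant principal
components from sediment-core concentration profiles (PCA -> LOESS smoothing
-> year matching), and per-species host-density series.  Interior gaps are
bridged by linear interpolation; nothing is extrapolated beyond the observed
range, so observations outside a series' span simply receive a missing value
and drop out of that covariate's model subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import CountTable, ScalingInfo, scale_predictor

__all__ = [
    "MonthlySeries",
    "AnnualSeries",
    "PollutantMatrix",
    "PCAResult",
    "CovariateBundle",
    "annualize_sst",
    "average_replicate_series",
    "interpolate_annual",
    "pca_pollutants",
    "loess_annual",
    "attach_covariates",
]


@dataclass
class MonthlySeries:
    """(year, month, value) triples, at most one value per month."""

    df: pd.DataFrame  # columns: year, month, value
    units: str = ""

    def __post_init__(self):
        m = self.df["month"]
        if ((m < 1) | (m > 12)).any():
            raise ValueError("month outside 1..12")
        if self.df.duplicated(["year", "month"]).any():
            raise ValueError("duplicate (year, month) entries")


@dataclass
class AnnualSeries:
    """A per-year scalar series with provenance tags.

    ``provenance`` marks each value ``raw``, ``interpolated`` or ``smoothed``.
    Lookups outside the observed years return NaN (an explicit missing
    marker), never an extrapolated value.
    """

    years: np.ndarray
    values: np.ndarray
    units: str = ""
    name: str = ""
    provenance: np.ndarray = None

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.provenance is None:
            self.provenance = np.full(len(self.years), "raw", dtype=object)
        else:
            self.provenance = np.asarray(self.provenance, dtype=object)
        if len(self.years) != len(self.values):
            raise ValueError("years/values length mismatch")
        if len(self.years) > 1 and not np.all(np.diff(self.years) > 0):
            order = np.argsort(self.years)
            self.years = self.years[order]
            self.values = self.values[order]
            self.provenance = self.provenance[order]
            if np.any(np.diff(self.years) == 0):
                raise ValueError("duplicate years")

    def __len__(self):
        return len(self.years)

    def value_for(self, year) -> np.ndarray:
        """Vectorised lookup; missing years map to NaN."""
        year = np.atleast_1d(np.asarray(year, dtype=float))
        out = np.full(year.shape, np.nan)
        ok = ~np.isnan(year)
        lut = dict(zip(self.years.tolist(), self.values.tolist()))
        out[ok] = [lut.get(int(y), np.nan) for y in year[ok]]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "year": self.years, "value": self.values, "provenance": self.provenance,
        })


@dataclass
class PollutantMatrix:
    """Years x variables table of sediment concentrations (ug/g) plus
    lignin/soil biomarkers, for one core."""

    df: pd.DataFrame  # index: year; columns: variables
    core_id: str = ""

    def __post_init__(self):
        if (self.df.to_numpy(dtype=float) < 0).any():
            raise ValueError("negative concentrations")


@dataclass
class PCAResult:
    scores: pd.DataFrame            # index year, columns PC1..PCm
    variance_explained: np.ndarray  # proportions, sum to 1
    loadings: pd.DataFrame          # variables x components


@dataclass
class CovariateBundle:
    """Named annual series attachable to observations by collection year."""

    sst: AnnualSeries | None = None
    pollutant_pc1: AnnualSeries | None = None
    pollutant_pc2: AnnualSeries | None = None
    host_density: Mapping[str, AnnualSeries] = field(default_factory=dict)
    scaling: dict = field(default_factory=dict)

    def series_names(self) -> list:
        names = [n for n in ("sst", "pollutant_pc1", "pollutant_pc2")
                 if getattr(self, n) is not None]
        if self.host_density:
            names.append("host_density")
        return names

    def standardized(self) -> "CovariateBundle":
        """Scale each series to mean 0 / SD 1 over its own years, recording
        :class:`~paraburden.dataio.ScalingInfo`.  Host-density series are
        scaled jointly across species (one global scale)."""
        new = CovariateBundle(host_density={})
        for name in ("sst", "pollutant_pc1", "pollutant_pc2"):
            s = getattr(self, name)
            if s is None:
                continue
            scaled, info = scale_predictor(s.values, name=name)
            setattr(new, name, replace(s, values=scaled))
            new.scaling[name] = info
        if self.host_density:
            pooled = np.concatenate([s.values for s in self.host_density.values()])
            _, info = scale_predictor(pooled, name="host_density")
            new.host_density = {
                sp: replace(s, values=(s.values - info.mean) / info.sd)
                for sp, s in self.host_density.items()
            }
            new.scaling["host_density"] = info
        return new


# ---------------------------------------------------------------------------
# operations


def annualize_sst(monthly: MonthlySeries, max_missing_months: int = 1) -> AnnualSeries:
    """Annual mean SST, discarding years missing more than ``max_missing_months``.

    A year is kept iff at least ``12 - max_missing_months`` monthly values are
    present; its value is the mean of the present months.
    """
    df = monthly.df.dropna(subset=["value"])
    if len(df) and ((df["value"] < -5) | (df["value"] > 40)).any():
        raise ValueError("monthly SST outside plausible range (-5, 40) degC")
    if not len(df):
        return AnnualSeries(np.array([], int), np.array([]), units=monthly.units,
                            name="sst")
    g = df.groupby("year")["value"]
    agg = pd.DataFrame({"n": g.size(), "mean": g.mean()})
    agg = agg[12 - agg["n"] <= max_missing_months]
    return AnnualSeries(agg.index.to_numpy(), agg["mean"].to_numpy(),
                        units=monthly.units, name="sst")


def average_replicate_series(series_list: Sequence[AnnualSeries]) -> AnnualSeries:
    """Per-year mean across replicate series (cores, basins).

    Years present in only some series average over those; years present in
    none are absent from the output.
    """
    if not series_list:
        raise ValueError("need at least one series")
    frames = [s.to_frame()[["year", "value"]] for s in series_list]
    allv = pd.concat(frames, ignore_index=True).dropna(subset=["value"])
    g = allv.groupby("year")["value"].mean()
    first = series_list[0]
    return AnnualSeries(g.index.to_numpy(), g.to_numpy(), units=first.units,
                        name=first.name)


def interpolate_annual(series: AnnualSeries) -> AnnualSeries:
    """Linearly fill interior year gaps; never extrapolate.

    Filled values are tagged ``interpolated``; queries outside the observed
    range still return NaN through :meth:`AnnualSeries.value_for`.
    """
    obs_mask = ~np.isnan(series.values)
    yrs, vals = series.years[obs_mask], series.values[obs_mask]
    if len(yrs) < 2:
        raise ValueError("need >= 2 observed years to interpolate")
    full_years = np.arange(yrs[0], yrs[-1] + 1)
    full_vals = np.interp(full_years, yrs, vals)
    prov = np.where(np.isin(full_years, yrs), "raw", "interpolated").astype(object)
    return AnnualSeries(full_years, full_vals, units=series.units,
                        name=series.name, provenance=prov)


def pca_pollutants(matrix: PollutantMatrix, standardize: bool = True) -> PCAResult:
    """Principal components of the pollutant concentration matrix.

    With ``standardize`` (default) the PCA is on the correlation matrix, so
    results are invariant to per-variable units; components are ordered by
    decreasing eigenvalue and each is signed so its largest-magnitude loading
    is positive.
    """
    X = matrix.df.to_numpy(dtype=float)
    if len(X) < 3:
        raise ValueError("need >= 3 years for PCA")
    if np.isnan(X).any():
        raise ValueError("missing cells; interpolate before PCA")
    Xc = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        const = np.flatnonzero(sd == 0)
        if len(const):
            names = [matrix.df.columns[i] for i in const]
            raise ValueError(f"constant column(s) cannot be standardized: {names}")
        Xc = Xc / sd
    cov = (Xc.T @ Xc) / (len(Xc) - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign convention: largest-magnitude loading positive
    for c in range(eigvec.shape[1]):
        col = eigvec[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            eigvec[:, c] = -col
    scores = Xc @ eigvec
    prop = eigval / eigval.sum()
    cols = [f"PC{i + 1}" for i in range(eigvec.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.df.index, columns=cols),
        variance_explained=prop,
        loadings=pd.DataFrame(eigvec, index=matrix.df.columns, columns=cols),
    )


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def loess_annual(series: AnnualSeries, span: float = 0.75, degree: int = 2
                 ) -> AnnualSeries:
    """LOESS smoother (local weighted polynomial, tricube weights).

    At each observed year the ``span`` fraction of nearest years is fit with
    a degree-``degree`` weighted polynomial and evaluated at that year.  The
    smoother damps year-to-year measurement error in e.g. pollutant PC score
    series before matching to collections.
    """
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    x = series.years.astype(float)
    y = series.values
    n = len(x)
    if n < max(5, degree + 2):
        raise ValueError(f"need >= {max(5, degree + 2)} points for LOESS")
    k = max(int(np.ceil(span * n)), degree + 1)
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:k]
        dmax = d[idx].max()
        if dmax == 0:
            out[i] = y[idx].mean()
            continue
        w = _tricube(d[idx] / dmax)
        # guard: boundary point of the window has weight exactly 0
        pos = w > 0
        if pos.sum() <= degree:
            w = np.maximum(w, 1e-9)
            pos = w > 0
        coef = np.polyfit(x[idx][pos] - x[i], y[idx][pos], deg=degree,
                          w=np.sqrt(w[pos]))
        out[i] = coef[-1]
    prov = np.full(n, "smoothed", dtype=object)
    return AnnualSeries(series.years.copy(), out, units=series.units,
                        name=series.name, provenance=prov)


def attach_covariates(table: CountTable, bundle: CovariateBundle) -> CountTable:
    """Join covariate values to observations by collection year.

    Host density joins species-specifically: a row receives a density value
    only if its own host species has a density series covering its year.
    Unmatched rows get NaN (missingness is data, not failure).  Row counts
    and parasite counts are unchanged.
    """
    out = table.copy()
    years = out.df["year"].to_numpy(dtype=float)
    for name in ("sst", "pollutant_pc1", "pollutant_pc2"):
        s = getattr(bundle, name)
        if s is not None:
            out.df[name] = s.value_for(years)
    if bundle.host_density:
        dens = np.full(len(out.df), np.nan)
        for sp, s in bundle.host_density.items():
            sel = (out.df["host_species"] == sp).to_numpy()
            if sel.any():
                dens[sel] = s.value_for(years[sel])
        out.df["host_density"] = dens
    return out
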