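"""Observation data model: long-format host x parasite count tables.

The analysis operates on one row per (fish specimen, parasite taxon) with a
nonnegative count, including *explicit zeros* for every taxon in the host
species' roster that was screened but not found.  Fish-level metadata (host
species, collection year, latitude, total length) ride along on each row;
taxon-level metadata (broad taxonomic group, number of obligately required
hosts) live in a companion taxon table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BROAD_GROUPS",
    "CountTable",
    "ScalingInfo",
    "RareTaxaReport",
    "SchemaError",
    "ValidationError",
    "read_count_table",
    "read_taxon_table",
    "expand_zero_counts",
    "compute_prevalence",
    "filter_by_prevalence",
    "scale_predictor",
]

#: The seven broad taxonomic classes recognised for metazoan fish parasites.
BROAD_GROUPS = (
    "Copepoda",
    "Hirudinea",
    "Monogenea",
    "Trematoda",
    "Cestoda",
    "Nematoda",
    "Acanthocephala",
)

#: Canonical observation columns, in storage order.
CORE_COLUMNS = (
    "fish_id",
    "host_species",
    "taxon_code",
    "count",
    "year",
    "latitude",
    "total_length_cm",
)

OPTIONAL_COLUMNS = ("longitude", "collection")

#: Covariate columns that :func:`paraburden.covariates.attach_covariates` adds.
COVARIATE_COLUMNS = ("sst", "pollutant_pc1", "pollutant_pc2", "host_density")


class SchemaError(ValueError):
    """A required input column could not be resolved."""


class ValidationError(ValueError):
    """An input row violates a data-model invariant."""


@dataclass
class ScalingInfo:
    """Mean/SD standardisation record for one predictor.

    ``scope`` is either ``"global"`` (one mean/SD over all analysis rows) or
    ``"within_pair"`` (one mean/SD per host-parasite pair).  For the
    within-pair scope, ``mean``/``sd`` are mappings keyed by pair label.
    SDs use the n-1 (sample) convention.
    """

    name: str
    scope: str = "global"
    mean: float | dict = 0.0
    sd: float | dict = 1.0

    def transform(self, values, pairs=None):
        values = np.asarray(values, dtype=float)
        if self.scope == "global":
            return (values - self.mean) / self.sd
        if pairs is None:
            raise ValueError("within_pair scaling requires pair labels")
        mu = np.array([self.mean[p] for p in pairs])
        sd = np.array([self.sd[p] for p in pairs])
        return (values - mu) / sd

    def inverse(self, scaled, pairs=None):
        scaled = np.asarray(scaled, dtype=float)
        if self.scope == "global":
            return scaled * self.sd + self.mean
        mu = np.array([self.mean[p] for p in pairs])
        sd = np.array([self.sd[p] for p in pairs])
        return scaled * sd + mu

    def to_dict(self):
        return dataclasses.asdict(self)


@dataclass
class RareTaxaReport:
    """Host-parasite pairs excluded by the prevalence filter.

    One row per excluded (taxon, host species) pair with the number of
    infected fish, fish dissected, prevalence, and total parasite individuals
    removed with the pair.
    """

    table: pd.DataFrame
    threshold: float

    @property
    def n_pairs(self) -> int:
        return len(self.table)

    @property
    def total_individuals(self) -> int:
        return int(self.table["total_individuals"].sum())

    @property
    def n_taxa(self) -> int:
        return self.table["taxon_code"].nunique()


@dataclass
class CountTable:
    """Long-format fish x taxon counts with metadata.

    ``df`` holds one row per (fish, taxon) observation; ``taxa`` is indexed by
    ``taxon_code`` with columns ``taxon_name``, ``broad_group``,
    ``n_obligate_hosts`` and optionally ``host_specific_name``.
    """

    df: pd.DataFrame
    taxa: pd.DataFrame | None = None

    def __post_init__(self):
        self.df = self.df.reset_index(drop=True)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        missing = [c for c in CORE_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"count table missing columns: {missing}")
        counts = self.df["count"]
        numeric = pd.to_numeric(counts, errors="coerce")
        bad = numeric.isna() | (numeric < 0) | (numeric % 1 != 0)
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"row {idx}: count {counts.iloc[idx]!r} is not a nonnegative integer"
            )
        self.df["count"] = numeric.astype(int)
        dup = self.df.duplicated(subset=["fish_id", "taxon_code"])
        if dup.any():
            pair = self.df.loc[dup.idxmax(), ["fish_id", "taxon_code"]].tolist()
            raise ValidationError(f"duplicate (fish, taxon) observation: {pair}")
        years = self.df["year"].dropna()
        if ((years < 1800) | (years > 2100)).any():
            raise ValidationError("year outside [1800, 2100]")
        lat = self.df["latitude"].dropna()
        if ((lat < -90) | (lat > 90)).any():
            raise ValidationError("latitude outside [-90, 90]")
        tl = self.df["total_length_cm"].dropna()
        if (tl <= 0).any():
            raise ValidationError("total_length_cm must be > 0")
        if self.taxa is not None:
            bad_group = set(self.taxa["broad_group"]) - set(BROAD_GROUPS)
            if bad_group:
                raise ValidationError(f"unknown broad taxonomic group(s): {bad_group}")
            if (self.taxa["n_obligate_hosts"] < 1).any():
                raise ValidationError("n_obligate_hosts must be >= 1")

    # -- convenience -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_fish(self) -> int:
        return self.df["fish_id"].nunique()

    @property
    def n_taxa(self) -> int:
        return self.df["taxon_code"].nunique()

    @property
    def total_individuals(self) -> int:
        return int(self.df["count"].sum())

    def missing_metadata_mask(self) -> pd.Series:
        """Rows flagged for missing year or total length (kept, not dropped)."""
        return self.df["year"].isna() | self.df["total_length_cm"].isna()

    def copy(self) -> "CountTable":
        return CountTable(self.df.copy(), None if self.taxa is None else self.taxa.copy())

    def write_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def taxa_for(self, host_species: str) -> list:
        sub = self.df.loc[self.df["host_species"] == host_species, "taxon_code"]
        return sorted(sub.unique())


# ---------------------------------------------------------------------------
# readers


def _apply_schema(df: pd.DataFrame, schema: Mapping[str, str] | None,
                  required: Sequence[str], optional: Sequence[str] = ()) -> pd.DataFrame:
    schema = dict(schema or {})
    rename = {}
    for canonical in tuple(required) + tuple(optional):
        source = schema.get(canonical, canonical)
        if source in df.columns:
            rename[source] = canonical
        elif canonical in required:
            raise SchemaError(
                f"required column {canonical!r} (source name {source!r}) not found; "
                f"available: {list(df.columns)}"
            )
    return df.rename(columns=rename)


def read_count_table(path, schema: Mapping[str, str] | None = None,
                     taxa: pd.DataFrame | None = None) -> CountTable:
    """Read a long-format count CSV, validating counts and metadata.

    ``schema`` maps canonical column names to the file's column names.  Rows
    with missing year or total length are retained and can be located with
    :meth:`CountTable.missing_metadata_mask`.
    """
    df = pd.read_csv(path)
    df = _apply_schema(df, schema, CORE_COLUMNS, OPTIONAL_COLUMNS + COVARIATE_COLUMNS)
    keep = [c for c in CORE_COLUMNS + OPTIONAL_COLUMNS + COVARIATE_COLUMNS if c in df.columns]
    return CountTable(df[keep], taxa=taxa)


def read_taxon_table(path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read taxon metadata (broad group, obligate host count) indexed by code."""
    df = pd.read_csv(path)
    df = _apply_schema(
        df, schema,
        required=("taxon_code", "broad_group", "n_obligate_hosts"),
        optional=("taxon_name", "host_specific_name"),
    )
    df["n_obligate_hosts"] = df["n_obligate_hosts"].astype(int)
    return df.set_index("taxon_code", drop=False)


# ---------------------------------------------------------------------------
# zero expansion


def expand_zero_counts(detections: CountTable,
                       roster: Mapping[str, Sequence[str]],
                       fish: pd.DataFrame | None = None) -> CountTable:
    """Fill in explicit zero counts for undetected roster taxa.

    ``roster`` maps each host species to the taxa screened for in that
    species.  Every fish gains one row per roster taxon of its species;
    detections keep their counts, everything else becomes 0.  ``fish``
    optionally supplies metadata for fish with no detections at all
    (columns as in the count table, one row per fish).
    """
    det = detections.df
    orphans = []
    for species, grp in det.groupby("host_species"):
        extra = set(grp["taxon_code"]) - set(roster.get(species, ()))
        orphans += [(species, t) for t in sorted(extra)]
    if orphans:
        raise ValidationError(f"detections outside the roster: {orphans}")

    meta_cols = [c for c in CORE_COLUMNS + OPTIONAL_COLUMNS
                 if c not in ("taxon_code", "count") and c in det.columns]
    fish_meta = det[meta_cols].drop_duplicates("fish_id")
    if fish is not None:
        add = fish[[c for c in meta_cols if c in fish.columns]]
        fish_meta = (
            pd.concat([fish_meta, add], ignore_index=True)
            .drop_duplicates("fish_id")
        )

    blocks = []
    for species, grp in fish_meta.groupby("host_species"):
        taxa = sorted(roster.get(species, ()))
        if not taxa:
            continue
        block = grp.loc[grp.index.repeat(len(taxa))].reset_index(drop=True)
        block["taxon_code"] = np.tile(taxa, len(grp))
        blocks.append(block)
    if not blocks:
        full = det.iloc[0:0].copy()
    else:
        full = pd.concat(blocks, ignore_index=True)
        full = full.merge(
            det[["fish_id", "taxon_code", "count"]],
            on=["fish_id", "taxon_code"], how="left",
        )
        full["count"] = full["count"].fillna(0).astype(int)
    cols = [c for c in CORE_COLUMNS + OPTIONAL_COLUMNS if c in full.columns]
    full = full[cols].sort_values(["host_species", "fish_id", "taxon_code"])
    return CountTable(full.reset_index(drop=True), taxa=detections.taxa)


# ---------------------------------------------------------------------------
# prevalence


def compute_prevalence(table: CountTable) -> pd.DataFrame:
    """Per (host species, taxon) prevalence pooled over all years.

    Prevalence is the fraction of dissected fish of the host species in which
    the taxon was found at least once.  Requires explicit zeros so that the
    number of dissected fish equals the number of rows per pair.
    """
    df = table.df
    grp = df.groupby(["host_species", "taxon_code"])["count"]
    out = pd.DataFrame({
        "n_infected": grp.apply(lambda c: int((c > 0).sum())),
        "n_dissected": grp.size(),
    })
    zero = out["n_dissected"] == 0
    if zero.any():
        import warnings

        warnings.warn(f"{int(zero.sum())} pairs with no dissected fish excluded")
        out = out[~zero]
    out["prevalence"] = out["n_infected"] / out["n_dissected"]
    return out


def filter_by_prevalence(table: CountTable, threshold: float = 0.05
                         ) -> tuple[CountTable, RareTaxaReport]:
    """Drop host-parasite pairs below the prevalence threshold (inclusive keep).

    A pair is retained iff its all-years prevalence is **at least**
    ``threshold``.  All rows (and parasite individuals) of dropped pairs move
    to the returned :class:`RareTaxaReport`, so individuals partition exactly.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    prev = compute_prevalence(table)
    keep_pairs = prev.index[prev["prevalence"] >= threshold]
    df = table.df
    key = pd.MultiIndex.from_frame(df[["host_species", "taxon_code"]])
    keep_mask = key.isin(keep_pairs)

    dropped = df[~keep_mask]
    rare = (
        dropped.groupby(["host_species", "taxon_code"])["count"]
        .sum()
        .rename("total_individuals")
        .to_frame()
        .join(prev)
        .reset_index()
    )
    rare = rare[["taxon_code", "host_species", "n_infected", "n_dissected",
                 "prevalence", "total_individuals"]]
    report = RareTaxaReport(table=rare.reset_index(drop=True), threshold=threshold)

    kept_df = df[keep_mask].reset_index(drop=True)
    taxa = table.taxa
    if taxa is not None:
        taxa = taxa[taxa["taxon_code"].isin(kept_df["taxon_code"].unique())]
    return CountTable(kept_df, taxa=taxa), report


# ---------------------------------------------------------------------------
# predictor scaling


def scale_predictor(values, scope: str = "global", pair_index=None,
                    name: str = "predictor") -> tuple[np.ndarray, ScalingInfo]:
    """Standardise a predictor to mean 0, SD 1 (sample SD).

    ``scope="within_pair"`` standardises separately within each host-parasite
    pair given by ``pair_index``; the default standardises over all rows.
    Constant input (SD of 0) is an error.
    """
    values = np.asarray(values, dtype=float)
    if scope == "global":
        mu = float(np.nanmean(values))
        sd = float(np.nanstd(values, ddof=1))
        if not sd > 0:
            raise ValueError(f"{name}: constant values, cannot scale (SD = 0)")
        info = ScalingInfo(name=name, scope="global", mean=mu, sd=sd)
        return (values - mu) / sd, info
    if scope != "within_pair":
        raise ValueError(f"unknown scaling scope {scope!r}")
    if pair_index is None:
        raise ValueError("within_pair scaling requires pair_index")
    pairs = np.asarray(pair_index)
    means, sds = {}, {}
    out = np.empty_like(values)
    for p in np.unique(pairs):
        sel = pairs == p
        mu = float(np.nanmean(values[sel]))
        sd = float(np.nanstd(values[sel], ddof=1))
        if not sd > 0:
            raise ValueError(f"{name}: constant values within pair {p!r}")
        means[p], sds[p] = mu, sd
        out[sel] = (values[sel] - mu) / sd
    info = ScalingInfo(name=name, scope="within_pair", mean=means, sd=sds)
    return out, info
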