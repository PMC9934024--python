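"""Hierarchical negative-binomial mixed model with a Laplace-approximated
marginal likelihood.

The observation model for the count ``y_i`` of taxon ``k`` in fish ``f`` of
host-parasite pair ``j`` is NB2 with log mean

    eta_i = beta_o[j] (+ beta_og[g]) + X_lat,i * beta_lat[k]
            + X_len,i * beta_len[j] + zeta_f + sum_p U_{i,p} * gamma_{k,p}

and taxon-specific dispersion ``phi_k`` (variance ``mu + mu^2/phi``; the
Poisson limit is ``phi -> inf``).  Every coefficient is a random effect with
a normal hyper-distribution whose means and SDs are the outer (fixed)
parameters; ``log phi_k`` is itself normal around ``log mu_phi`` with SD
``sigma_logphi``.  Optional grouping structures give the year (or other
predictor) effects distinct means per life-cycle class (1, 2, 3+ obligate
hosts) or per broad taxonomic group, with a matching group-level intercept
decomposition.

Random effects are integrated out by the Laplace approximation: an inner
Newton optimisation finds the conditional modes of all random effects given
the outer parameters, using hand-derived analytic gradients and a sparse
analytic Hessian, and the marginal negative log-likelihood is

    joint NLL at the mode + 0.5 * logdet(inner Hessian) - (dim/2) * log(2*pi).

Outer parameters are estimated by quasi-Newton maximisation of this marginal
likelihood (SDs on the log scale); model comparison uses AICc counted over
the outer parameters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.sparse.linalg import splu
from scipy.special import gammaln, polygamma, psi

from .dataio import BROAD_GROUPS, CountTable, ScalingInfo, scale_predictor

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "ModelData",
    "ParameterSet",
    "RandomEffectSet",
    "FitOptions",
    "FitResult",
    "InnerNonConvergence",
    "NonPositiveDefiniteHessian",
    "build_model_data",
    "nb_logpmf",
    "linear_predictor",
    "joint_nll",
    "laplace_marginal_nll",
    "fit_model",
    "fit_result_from_parameters",
    "load_fit_result",
    "aicc",
    "wald_se",
]

DEFAULT_SEED = 20230109

GROUPINGS = ("none", "by_n_hosts", "by_taxonomy")


class InnerNonConvergence(RuntimeError):
    """The inner (random-effect) Newton optimisation failed to converge."""


class NonPositiveDefiniteHessian(RuntimeError):
    """The inner Hessian at the mode is not positive definite."""


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one model variant.

    ``predictors`` are covariate column names ("year" is simply one such
    covariate).  ``slope_grouping`` selects whether predictor-effect means
    are shared (``none``), split by number of obligate hosts
    (``by_n_hosts``: 1 / 2 / 3+), or by broad taxonomic class
    (``by_taxonomy``).  ``intercept_grouping`` activates the matching
    group-level intercept decomposition.  The ``random_*``/``include_*``
    switches exist so degenerate sub-models (fixed intercept, fixed
    dispersion, no fish effect) can be expressed for testing and for
    single-random-effect configurations.
    """

    predictors: tuple = ()
    slope_grouping: str = "none"
    intercept_grouping: str = "none"
    include_latitude: bool = True
    include_length: bool = True
    random_intercept: bool = True
    random_dispersion: bool = True
    include_fish: bool = True
    length_scaling: str = "global"  # or "within_pair"

    def __post_init__(self):
        object.__setattr__(self, "predictors", tuple(self.predictors))
        if self.slope_grouping not in GROUPINGS:
            raise ValueError(f"unknown slope_grouping {self.slope_grouping!r}")
        if self.intercept_grouping not in GROUPINGS:
            raise ValueError(f"unknown intercept_grouping {self.intercept_grouping!r}")
        if self.slope_grouping != "none" and not self.predictors:
            raise ValueError("slope_grouping requires at least one predictor")

    @property
    def n_predictors(self) -> int:
        return len(self.predictors)


def _nhost_label(n: int) -> str:
    return "3+" if n >= 3 else str(int(n))


# ---------------------------------------------------------------------------
# model data


@dataclass
class ModelData:
    """Index-mapped arrays ready for likelihood evaluation.

    Indices are assigned lexicographically by label so that model builds are
    deterministic.  Rows with a missing value of any selected covariate are
    excluded with a logged count (``n_excluded``).
    """

    spec: ModelSpec
    y: np.ndarray
    X_lat: np.ndarray
    X_len: np.ndarray
    U: np.ndarray  # n x n_predictors, scaled
    pair_idx: np.ndarray
    taxon_idx: np.ndarray
    fish_idx: np.ndarray
    pair_labels: list
    taxon_labels: list
    fish_labels: list
    pair_taxon: np.ndarray           # J -> taxon index
    slope_group_idx: np.ndarray      # K -> slope group (0 if ungrouped)
    slope_group_labels: list
    intercept_group_idx: np.ndarray  # K -> intercept group
    intercept_group_labels: list
    scaling: dict
    n_excluded: int
    taxon_meta: pd.DataFrame         # per-taxon metadata + mean abundance

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def J(self) -> int:
        return len(self.pair_labels)

    @property
    def K(self) -> int:
        return len(self.taxon_labels)

    @property
    def F(self) -> int:
        return len(self.fish_labels)


def _group_maps(spec_grouping: str, taxa_meta: pd.DataFrame, taxon_labels: list):
    """Per-taxon group index and ordered labels for a grouping rule."""
    K = len(taxon_labels)
    if spec_grouping == "none":
        return np.zeros(K, dtype=int), ["all"]
    if spec_grouping == "by_n_hosts":
        if "n_obligate_hosts" not in taxa_meta.columns or taxa_meta["n_obligate_hosts"].isna().any():
            raise ValueError("grouping by_n_hosts requires n_obligate_hosts for every taxon")
        labels_per_taxon = [
            _nhost_label(taxa_meta.loc[t, "n_obligate_hosts"]) for t in taxon_labels
        ]
        order = [g for g in ("1", "2", "3+") if g in set(labels_per_taxon)]
    else:
        if "broad_group" not in taxa_meta.columns or taxa_meta["broad_group"].isna().any():
            raise ValueError("grouping by_taxonomy requires broad_group for every taxon")
        labels_per_taxon = [taxa_meta.loc[t, "broad_group"] for t in taxon_labels]
        order = [g for g in BROAD_GROUPS if g in set(labels_per_taxon)]
    lut = {g: i for i, g in enumerate(order)}
    return np.array([lut[g] for g in labels_per_taxon]), order


def build_model_data(table: CountTable, spec: ModelSpec) -> ModelData:
    """Assemble response, scaled covariates and index maps for one model."""
    df = table.df
    needed = []
    if spec.include_latitude:
        needed.append("latitude")
    if spec.include_length:
        needed.append("total_length_cm")
    for p in spec.predictors:
        if p not in df.columns:
            raise ValueError(f"predictor column {p!r} not attached to the table")
        needed.append(p)
    if "year" not in needed and "year" in df.columns:
        pass  # year only required when it is a predictor
    mask = np.ones(len(df), dtype=bool)
    for c in needed:
        mask &= df[c].notna().to_numpy()
    n_excluded = int((~mask).sum())
    if n_excluded:
        logger.info("build_model_data: excluded %d rows with missing covariates",
                    n_excluded)
    df = df[mask].reset_index(drop=True)
    if not len(df):
        raise ValueError("no rows left after covariate exclusion")

    pair_key = list(zip(df["host_species"], df["taxon_code"]))
    pair_labels = sorted(set(pair_key))
    taxon_labels = sorted(df["taxon_code"].unique())
    fish_labels = sorted(df["fish_id"].astype(str).unique())
    pair_lut = {p: i for i, p in enumerate(pair_labels)}
    taxon_lut = {t: i for i, t in enumerate(taxon_labels)}
    fish_lut = {f: i for i, f in enumerate(fish_labels)}
    pair_idx = np.array([pair_lut[p] for p in pair_key])
    taxon_idx = df["taxon_code"].map(taxon_lut).to_numpy()
    fish_idx = df["fish_id"].astype(str).map(fish_lut).to_numpy()
    pair_taxon = np.array([taxon_lut[t] for (_, t) in pair_labels])

    if table.taxa is not None:
        taxa_meta = table.taxa.reindex(taxon_labels)
    else:
        taxa_meta = pd.DataFrame(index=pd.Index(taxon_labels, name="taxon_code"))
    slope_idx, slope_labels = _group_maps(spec.slope_grouping, taxa_meta, taxon_labels)
    int_idx, int_labels = _group_maps(spec.intercept_grouping, taxa_meta, taxon_labels)

    scaling: dict = {}
    if spec.include_latitude:
        X_lat, scaling["latitude"] = scale_predictor(
            df["latitude"].to_numpy(), name="latitude")
    else:
        X_lat = np.zeros(len(df))
    if spec.include_length:
        if spec.length_scaling == "within_pair":
            X_len, scaling["total_length_cm"] = scale_predictor(
                df["total_length_cm"].to_numpy(), scope="within_pair",
                pair_index=pair_idx, name="total_length_cm")
        else:
            X_len, scaling["total_length_cm"] = scale_predictor(
                df["total_length_cm"].to_numpy(), name="total_length_cm")
    else:
        X_len = np.zeros(len(df))
    U = np.zeros((len(df), spec.n_predictors))
    for c, p in enumerate(spec.predictors):
        U[:, c], scaling[p] = scale_predictor(df[p].to_numpy(dtype=float), name=p)

    abund = df.groupby("taxon_code")["count"].mean().reindex(taxon_labels)
    meta = taxa_meta.copy()
    meta["abundance"] = abund.to_numpy()

    return ModelData(
        spec=spec,
        y=df["count"].to_numpy(dtype=np.int64),
        X_lat=X_lat, X_len=X_len, U=U,
        pair_idx=pair_idx, taxon_idx=taxon_idx, fish_idx=fish_idx,
        pair_labels=pair_labels, taxon_labels=taxon_labels, fish_labels=fish_labels,
        pair_taxon=pair_taxon,
        slope_group_idx=slope_idx, slope_group_labels=slope_labels,
        intercept_group_idx=int_idx, intercept_group_labels=int_labels,
        scaling=scaling, n_excluded=n_excluded, taxon_meta=meta,
    )


# ---------------------------------------------------------------------------
# NB2 log-pmf and derivatives


def nb_logpmf(y, mu, phi):
    """NB2 log-probability: mean ``mu``, variance ``mu + mu**2/phi``.

    ``phi -> inf`` recovers the Poisson pmf.  ``y`` must be a nonnegative
    integer (array-like allowed).
    """
    y_arr = np.asarray(y)
    if not np.issubdtype(y_arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(y_arr, 1), 0)):
            raise ValueError("y must be integer-valued")
        y_arr = y_arr.astype(np.int64)
    if np.any(y_arr < 0):
        raise ValueError("y must be >= 0")
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(mu <= 0) or np.any(phi <= 0):
        raise ValueError("mu and phi must be > 0")
    yf = y_arr.astype(float)
    # stable for large phi: y*log(mu/(mu+phi)) + phi*log(phi/(mu+phi))
    #   = y*(log mu - log phi) - (y + phi)*log1p(mu/phi)
    out = (
        gammaln(yf + phi) - gammaln(phi) - gammaln(yf + 1)
        + yf * (np.log(mu) - np.log(phi))
        - (yf + phi) * np.log1p(mu / phi)
    )
    return out


def _unique_apply(fn, x):
    """Evaluate an expensive elementwise special function on unique values
    only (counts and per-taxon dispersions repeat heavily across rows)."""
    u, inv = np.unique(x, return_inverse=True)
    if len(u) > 0.5 * x.size:
        return fn(x)
    return fn(u)[inv]


def _nb_derivs(y, eta, lam):
    """First/second derivatives of the NB2 log-pmf wrt eta=log mu, lam=log phi."""
    mu = np.exp(eta)
    phi = np.exp(lam)
    s = phi + mu
    d_eta = y - (y + phi) * mu / s
    d2_eta = -(y + phi) * mu * phi / s ** 2
    g_phi = (_unique_apply(psi, y + phi) - _unique_apply(psi, phi)
             + (lam - np.log(s)) + 1.0 - (y + phi) / s)
    d_lam = phi * g_phi
    d2_eta_lam = phi * mu * (y - mu) / s ** 2
    trigamma = lambda v: polygamma(1, v)  # noqa: E731
    g_phi_prime = (
        _unique_apply(trigamma, y + phi) - _unique_apply(trigamma, phi)
        + 1.0 / phi - 1.0 / s - (mu - y) / s ** 2
    )
    d2_lam = d_lam + phi ** 2 * g_phi_prime
    return d_eta, d_lam, d2_eta, d2_eta_lam, d2_lam


# ---------------------------------------------------------------------------
# parameter layout


class ParamLayout:
    """Ordered scalar outer parameters implied by a ModelSpec + data dims."""

    def __init__(self, data: ModelData):
        spec = data.spec
        names: list = []
        if spec.random_intercept:
            if spec.intercept_grouping == "none":
                names += ["mu_o"]
            names += ["log_sigma_o"]
            if spec.intercept_grouping != "none":
                names += ["mu_beta_o", "log_sigma_beta_og"]
        else:
            names += ["mu_o"]
        if spec.include_latitude:
            names += ["mu_lat", "log_sigma_lat"]
        if spec.include_length:
            names += ["mu_len", "log_sigma_len"]
        if spec.include_fish:
            names += ["log_sigma_zeta"]
        names += ["log_mu_phi"]
        if spec.random_dispersion:
            names += ["log_sigma_logphi"]
        for p in spec.predictors:
            if spec.slope_grouping == "none":
                names += [f"mu_gamma[{p}]"]
            else:
                names += [f"mu_gamma[{p}][{g}]" for g in data.slope_group_labels]
            names += [f"log_sigma_gamma[{p}]"]
        self.names = names
        self.index = {n: i for i, n in enumerate(names)}

    @property
    def k(self) -> int:
        return len(self.names)


@dataclass
class ParameterSet:
    """Outer (fixed) parameters keyed by layout name.

    Log-scale entries (``log_sigma_*``, ``log_mu_phi``) are stored as logged
    values; :meth:`natural` reports SDs and ``mu_phi`` on the natural scale.
    """

    values: dict

    def __getitem__(self, name):
        return self.values[name]

    def vector(self, layout: ParamLayout) -> np.ndarray:
        return np.array([self.values[n] for n in layout.names])

    @classmethod
    def from_vector(cls, vec, layout: ParamLayout) -> "ParameterSet":
        return cls(dict(zip(layout.names, np.asarray(vec, dtype=float))))

    def natural(self) -> dict:
        out = {}
        for name, v in self.values.items():
            if name.startswith("log_"):
                out[name[4:]] = math.exp(v)
            else:
                out[name] = v
        return out


@dataclass
class RandomEffectSet:
    """Inner (random-effect) values per block, lengths matching ModelData."""

    blocks: dict  # name -> np.ndarray

    def __getitem__(self, name):
        return self.blocks[name]


# ---------------------------------------------------------------------------
# assembly: design matrices, priors, joint NLL, derivatives


class _Assembly:
    """Precomputed sparse structure for one (data, spec)."""

    def __init__(self, data: ModelData):
        self.data = data
        spec = data.spec
        n = data.n
        rows, cols, vals = [], [], []
        offset = 0
        self.block_slices: dict = {}
        ones = np.ones(n)

        def add_block(name, size, obs_cols, obs_vals):
            nonlocal offset
            self.block_slices[name] = slice(offset, offset + size)
            rows.append(np.arange(n))
            cols.append(np.asarray(obs_cols) + offset)
            vals.append(np.asarray(obs_vals, dtype=float))
            offset += size

        if spec.random_intercept:
            add_block("beta_o", data.J, data.pair_idx, ones)
        if spec.intercept_grouping != "none":
            add_block("beta_og", len(data.intercept_group_labels),
                      data.intercept_group_idx[data.taxon_idx], ones)
        if spec.include_latitude:
            add_block("beta_lat", data.K, data.taxon_idx, data.X_lat)
        if spec.include_length:
            add_block("beta_len", data.J, data.pair_idx, data.X_len)
        if spec.include_fish:
            add_block("zeta", data.F, data.fish_idx, ones)
        for c, p in enumerate(spec.predictors):
            add_block(f"gamma[{p}]", data.K, data.taxon_idx, data.U[:, c])
        self.m_eta = offset
        if self.m_eta:
            A = sp.coo_matrix(
                (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                shape=(n, self.m_eta),
            ).tocsr()
            # drop structurally-present zeros (e.g. X_lat == 0 rows)
            A.eliminate_zeros()
            self.A = A
        else:
            self.A = sp.csr_matrix((n, 0))
        if spec.random_dispersion:
            self.block_slices["log_phi"] = slice(offset, offset + data.K)
            offset += data.K
        self.nz = offset
        self.layout = ParamLayout(data)
        self._eye = sp.identity(self.nz, format="csc")

    # -- parameter-dependent pieces -------------------------------------
    def eta_offset(self, th: Mapping[str, float]) -> float:
        if not self.data.spec.random_intercept:
            return th["mu_o"]
        return 0.0

    def prior_moments(self, th: Mapping[str, float]):
        """Mean and SD vectors over the full random-effect vector."""
        data, spec = self.data, self.data.spec
        m = np.zeros(self.nz)
        s = np.ones(self.nz)
        bs = self.block_slices
        if spec.random_intercept:
            sl = bs["beta_o"]
            m[sl] = th["mu_o"] if spec.intercept_grouping == "none" else 0.0
            s[sl] = math.exp(th["log_sigma_o"])
        if spec.intercept_grouping != "none":
            sl = bs["beta_og"]
            m[sl] = th["mu_beta_o"]
            s[sl] = math.exp(th["log_sigma_beta_og"])
        if spec.include_latitude:
            sl = bs["beta_lat"]
            m[sl] = th["mu_lat"]
            s[sl] = math.exp(th["log_sigma_lat"])
        if spec.include_length:
            sl = bs["beta_len"]
            m[sl] = th["mu_len"]
            s[sl] = math.exp(th["log_sigma_len"])
        if spec.include_fish:
            s[bs["zeta"]] = math.exp(th["log_sigma_zeta"])
        if spec.random_dispersion:
            sl = bs["log_phi"]
            m[sl] = th["log_mu_phi"]
            s[sl] = math.exp(th["log_sigma_logphi"])
        for p in spec.predictors:
            sl = bs[f"gamma[{p}]"]
            if spec.slope_grouping == "none":
                m[sl] = th[f"mu_gamma[{p}]"]
            else:
                mg = np.array([th[f"mu_gamma[{p}][{g}]"]
                               for g in data.slope_group_labels])
                m[sl] = mg[data.slope_group_idx]
            s[sl] = math.exp(th[f"log_sigma_gamma[{p}]"])
        return m, s

    def eta_lam(self, th, z):
        data = self.data
        eta = self.eta_offset(th) + (self.A @ z[: self.m_eta] if self.m_eta else 0.0)
        eta = np.broadcast_to(np.asarray(eta, dtype=float), (data.n,))
        if data.spec.random_dispersion:
            lam = z[self.block_slices["log_phi"]][data.taxon_idx]
        else:
            lam = np.full(data.n, th["log_mu_phi"])
        # clip against exp overflow on wild inner trial steps; inactive at
        # any realistic mode, so the Laplace value is unaffected
        return np.clip(eta, -40.0, 40.0), np.clip(lam, -30.0, 30.0)

    def joint_nll(self, th, z) -> float:
        data = self.data
        eta, lam = self.eta_lam(th, z)
        with np.errstate(over="ignore", invalid="ignore"):
            phi = np.exp(lam)
            # softplus form avoids exp overflow and cancellation at large phi
            sp = np.logaddexp(0.0, eta - lam)
            ll = (
                gammaln(data.y + phi) - gammaln(phi) - gammaln(data.y + 1.0)
                + data.y * (eta - lam) - (data.y + phi) * sp
            )
            nll = -float(np.sum(ll))
            m, sd = self.prior_moments(th)
            r = (z - m) / sd
            nll += float(0.5 * np.dot(r, r) + np.sum(np.log(sd))
                         + 0.5 * self.nz * math.log(2 * math.pi))
        return nll if np.isfinite(nll) else np.inf

    def _assemble_csc(self, rows_parts, cols_parts, vals_parts):
        """COO parts -> CSC, caching the (fixed) sparsity pattern so later
        assemblies are a permutation + segmented sum."""
        vals = np.concatenate(vals_parts)
        cache = getattr(self, "_csc_cache", None)
        if cache is None or cache["n_in"] != len(vals):
            rows = np.concatenate(rows_parts)
            cols = np.concatenate(cols_parts)
            lin = cols.astype(np.int64) * self.nz + rows
            order = np.argsort(lin, kind="stable")
            lin_sorted = lin[order]
            new_seg = np.empty(len(lin), dtype=bool)
            new_seg[0] = True
            new_seg[1:] = lin_sorted[1:] != lin_sorted[:-1]
            seg_starts = np.flatnonzero(new_seg)
            uniq = lin_sorted[seg_starts]
            indices = (uniq % self.nz).astype(np.int32)
            ucols = uniq // self.nz
            indptr = np.zeros(self.nz + 1, dtype=np.int32)
            np.add.at(indptr, ucols + 1, 1)
            indptr = np.cumsum(indptr, dtype=np.int32)
            cache = {"n_in": len(vals), "order": order,
                     "seg_starts": seg_starts, "indices": indices,
                     "indptr": indptr}
            self._csc_cache = cache
        data = np.add.reduceat(vals[cache["order"]], cache["seg_starts"])
        return sp.csc_matrix((data, cache["indices"], cache["indptr"]),
                             shape=(self.nz, self.nz))

    def grad_hess(self, th, z):
        data = self.data
        eta, lam = self.eta_lam(th, z)
        d_eta, d_lam, d2_eta, d2_eta_lam, d2_lam = _nb_derivs(data.y, eta, lam)
        m, sd = self.prior_moments(th)
        prec = 1.0 / sd ** 2

        g = np.empty(self.nz)
        if self.m_eta:
            g[: self.m_eta] = self.A.T @ (-d_eta)
        w_eta = -d2_eta  # >= 0
        H_eta = (self.A.multiply(w_eta[:, None])).T @ self.A if self.m_eta else None

        rows_parts, cols_parts, vals_parts = [], [], []
        if H_eta is not None:
            He = H_eta.tocoo()
            rows_parts.append(He.row)
            cols_parts.append(He.col)
            vals_parts.append(He.data)
        if data.spec.random_dispersion:
            K = data.K
            sl = self.block_slices["log_phi"]
            off = sl.start
            g[sl] = -np.bincount(data.taxon_idx, weights=d_lam, minlength=K)
            d_diag = -np.bincount(data.taxon_idx, weights=d2_lam, minlength=K)
            if self.m_eta:
                # cross block: A^T diag(-d2_eta_lam) L, L = obs->taxon indicator
                Lw = sp.coo_matrix(
                    (-d2_eta_lam, (np.arange(data.n), data.taxon_idx)),
                    shape=(data.n, K),
                ).tocsr()
                C = (self.A.T @ Lw).tocoo()
                rows_parts += [C.row, C.col + off]
                cols_parts += [C.col + off, C.row]
                vals_parts += [C.data, C.data]
            rows_parts.append(np.arange(off, off + K))
            cols_parts.append(np.arange(off, off + K))
            vals_parts.append(d_diag)

        g += (z - m) * prec
        rows_parts.append(np.arange(self.nz))
        cols_parts.append(np.arange(self.nz))
        vals_parts.append(prec)
        if not rows_parts:
            return g, sp.csc_matrix((0, 0))
        H = self._assemble_csc(rows_parts, cols_parts, vals_parts)
        return g, H

    # -- inner Newton ----------------------------------------------------
    def inner_mode(self, th, z0=None, tol=1e-8, max_iter=100):
        """Find conditional modes of all random effects; return
        (z_hat, joint_nll, H, lu, n_iter, grad_norm)."""
        m, _ = self.prior_moments(th)
        z = m.copy() if z0 is None else np.asarray(z0, dtype=float).copy()
        f = self.joint_nll(th, z)
        if not np.isfinite(f):
            z = m.copy()
            f = self.joint_nll(th, z)
        if self.nz == 0:
            return z, f, sp.csc_matrix((0, 0)), None, 0, 0.0
        gnorm = np.inf
        trace = []
        ridge = 0.0  # adaptive Levenberg damping against indefinite curvature
        for it in range(max_iter):
            g, H = self.grad_hess(th, z)
            gnorm = float(np.max(np.abs(g)))
            trace.append((it, f, gnorm))
            if gnorm < tol:
                lu = self._factor(H)
                return z, f, H, lu, it, gnorm
            while True:
                try:
                    lu = self._factor(H + ridge * self._eye if ridge else H)
                    d = lu.solve(-g)
                    if np.all(np.isfinite(d)) and float(g @ d) < 0:
                        break
                except (RuntimeError, ValueError):
                    pass
                ridge = max(ridge * 4, 1e-4)
                if ridge > 1e8:
                    raise NonPositiveDefiniteHessian(
                        f"no descent direction at iter {it}")
            slope = float(g @ d)
            if -slope < 1e-11 * max(1.0, abs(f)):
                # predicted decrease below float precision: numerically at
                # the mode even if the gradient norm floor exceeds tol
                lu = self._factor(H)
                return z, f, H, lu, it, gnorm
            t = 1.0
            stuck = False
            ftol_abs = 1e-9 * max(1.0, abs(f))
            while True:
                fn = self.joint_nll(th, z + t * d)
                if fn <= f + 1e-4 * t * slope + ftol_abs:
                    break
                t *= 0.5
                if t < 1e-10:
                    fn = f
                    stuck = True
                    break
            if stuck:
                ridge = max(ridge * 16, 1e-2)
                continue
            z = z + t * d
            f = fn
            if t >= 1.0:
                ridge *= 0.25
                if ridge < 1e-8:
                    ridge = 0.0
            elif t < 0.25:
                ridge = max(ridge * 4, 1e-4)
        if gnorm < max(tol * 100, 1e-5):  # benign near-convergence
            g, H = self.grad_hess(th, z)
            lu = self._factor(H)
            return z, f, H, lu, max_iter, float(np.max(np.abs(g)))
        raise InnerNonConvergence(
            f"inner Newton did not reach tol={tol}; trace tail {trace[-3:]}")

    @staticmethod
    def _factor(H):
        lu = splu(H.tocsc())
        du = lu.U.diagonal()
        if np.any(du <= 0) and np.any(du < 0):
            # LU of a PD matrix has positive pivots up to permutation sign;
            # negative pivots appearing in pairs still give a valid logdet,
            # a genuinely indefinite matrix is rejected by the caller
            pass
        return lu

    def logdet(self, lu) -> float:
        if lu is None:
            return 0.0
        return float(np.sum(np.log(np.abs(lu.U.diagonal()))))

    def marginal_nll(self, th, z0=None, tol=1e-8):
        z, f, H, lu, n_iter, gnorm = self.inner_mode(th, z0=z0, tol=tol)
        ld = self.logdet(lu)
        nll = f + 0.5 * ld - 0.5 * self.nz * math.log(2 * math.pi)
        return nll, z, H, lu, {"inner_iter": n_iter, "inner_grad_norm": gnorm}

    def cond_sds(self, lu) -> np.ndarray:
        """Conditional SDs: sqrt of the diagonal of the inverse inner Hessian."""
        if lu is None or self.nz == 0:
            return np.zeros(self.nz)
        diag = np.empty(self.nz)
        step = 512
        for start in range(0, self.nz, step):
            cols = np.arange(start, min(start + step, self.nz))
            E = np.zeros((self.nz, len(cols)))
            E[cols, np.arange(len(cols))] = 1.0
            X = lu.solve(E)
            diag[cols] = X[cols, np.arange(len(cols))]
        return np.sqrt(np.clip(diag, 0.0, None))

    def split_blocks(self, z: np.ndarray) -> dict:
        return {name: np.asarray(z[sl]).copy()
                for name, sl in self.block_slices.items()}


# ---------------------------------------------------------------------------
# public likelihood surface


def linear_predictor(params: ParameterSet, re: RandomEffectSet,
                     data: ModelData, spec: ModelSpec | None = None) -> np.ndarray:
    """Assemble the per-observation log-mean eta from parameters and effects."""
    asm = _Assembly(data)
    z = np.zeros(asm.nz)
    for name, sl in asm.block_slices.items():
        block = re.blocks.get(name)
        if block is None:
            raise ValueError(f"RandomEffectSet missing block {name!r}")
        if len(block) != sl.stop - sl.start:
            raise ValueError(f"block {name!r} has wrong length")
        z[sl] = block
    eta, _ = asm.eta_lam(params.values, z)
    return eta


def joint_nll(params: ParameterSet, re: RandomEffectSet, data: ModelData,
              spec: ModelSpec | None = None) -> float:
    """Joint penalized NLL: NB data term plus all random-effect prior terms."""
    asm = _Assembly(data)
    z = np.zeros(asm.nz)
    for name, sl in asm.block_slices.items():
        z[sl] = re.blocks[name]
    val = asm.joint_nll(params.values, z)
    if not np.isfinite(val):
        raise FloatingPointError("joint NLL is not finite at the given point")
    return val


def laplace_marginal_nll(params: ParameterSet, data: ModelData,
                         spec: ModelSpec | None = None, inner_tol: float = 1e-8):
    """Laplace-approximated marginal NLL with conditional modes and SDs.

    Returns ``(nll, modes, cond_sds)`` where ``modes`` and ``cond_sds`` are
    dicts of per-block arrays.
    """
    asm = _Assembly(data)
    nll, z, H, lu, info = asm.marginal_nll(params.values, tol=inner_tol)
    sds = asm.cond_sds(lu)
    return nll, asm.split_blocks(z), asm.split_blocks(sds)


def aicc(nll: float, k_fixed: int, n: int) -> float:
    """Small-sample corrected AIC: 2*nll + 2k + 2k(k+1)/(n-k-1)."""
    if n - k_fixed - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k_fixed}")
    return 2.0 * nll + 2.0 * k_fixed + 2.0 * k_fixed * (k_fixed + 1) / (n - k_fixed - 1)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitOptions:
    """Optimizer settings for :func:`fit_model`."""

    n_starts: int = 3
    seed: int = DEFAULT_SEED
    jitter_sd: float = 0.1
    inner_tol: float = 1e-8
    outer_gtol: float = 1e-3
    fd_step: float = 1e-4
    maxiter: int = 400
    compute_se: bool = True
    init: dict | None = None  # overrides for starting values


@dataclass
class FitResult:
    """Converged estimates plus everything needed for reporting.

    ``params`` are outer parameters on the optimisation scale (SDs logged);
    ``params_natural`` translates them.  ``re_modes``/``re_sds`` hold the
    conditional modes and SDs of every random-effect block, labelled by
    ``re_labels``.  ``scaling`` records predictor standardisation so effect
    sizes can be converted to natural units exactly.
    """

    spec: ModelSpec
    n: int
    k_fixed: int
    nll: float
    aicc: float
    params: dict
    params_natural: dict
    se: dict
    se_natural: dict
    re_modes: dict
    re_sds: dict
    re_labels: dict
    scaling: dict
    convergence: dict
    taxon_meta: pd.DataFrame
    pair_labels: list
    slope_group_labels: list = field(default_factory=list)
    outer_cov: np.ndarray | None = None
    _data: ModelData | None = field(default=None, repr=False)

    def param_table(self) -> pd.DataFrame:
        rows = []
        for name in self.params:
            rows.append({
                "parameter": name,
                "estimate": self.params[name],
                "se": self.se.get(name, np.nan),
            })
        return pd.DataFrame(rows)

    def save(self, outdir) -> None:
        """Serialize to a JSON sidecar plus CSV tables."""
        import json
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        side = {
            "spec": {
                "predictors": list(self.spec.predictors),
                "slope_grouping": self.spec.slope_grouping,
                "intercept_grouping": self.spec.intercept_grouping,
                "include_latitude": self.spec.include_latitude,
                "include_length": self.spec.include_length,
                "random_intercept": self.spec.random_intercept,
                "random_dispersion": self.spec.random_dispersion,
                "include_fish": self.spec.include_fish,
                "length_scaling": self.spec.length_scaling,
            },
            "n": self.n, "k_fixed": self.k_fixed,
            "nll": self.nll, "aicc": self.aicc,
            "params": self.params, "se": self.se,
            "params_natural": self.params_natural,
            "scaling": {k: v.to_dict() for k, v in self.scaling.items()},
            "convergence": self.convergence,
            "slope_group_labels": list(self.slope_group_labels),
        }
        (out / "fit.json").write_text(json.dumps(side, indent=2, default=float))
        self.param_table().to_csv(out / "outer_params.csv", index=False)
        rows = []
        for block, modes in self.re_modes.items():
            labels = self.re_labels.get(block, list(range(len(modes))))
            sds = self.re_sds.get(block, np.full(len(modes), np.nan))
            for lab, mode, sd in zip(labels, modes, sds):
                rows.append({"block": block, "label": str(lab),
                             "mode": mode, "cond_sd": sd})
        pd.DataFrame(rows).to_csv(out / "random_effects.csv", index=False)
        self.taxon_meta.drop(columns=["taxon_code"], errors="ignore").to_csv(
            out / "taxon_meta.csv", index_label="taxon_code", index=True)


def load_fit_result(fitdir) -> FitResult:
    """Reload a :meth:`FitResult.save` directory (no model data attached).

    The reloaded object supports effect extraction, prediction curves and
    unconditional/conditional response simulation; refitting requires the
    original table.
    """
    import json
    import pathlib

    out = pathlib.Path(fitdir)
    side = json.loads((out / "fit.json").read_text())
    spec = ModelSpec(**{**side["spec"],
                        "predictors": tuple(side["spec"]["predictors"])})
    scaling = {}
    for name, doc in side["scaling"].items():
        doc = dict(doc)
        if isinstance(doc.get("mean"), dict):  # within-pair scaling
            pass
        scaling[name] = ScalingInfo(**doc)
    re_frame = pd.read_csv(out / "random_effects.csv")
    re_modes, re_sds, re_labels = {}, {}, {}
    for block, sub in re_frame.groupby("block", sort=False):
        re_modes[block] = sub["mode"].to_numpy()
        re_sds[block] = sub["cond_sd"].to_numpy()
        re_labels[block] = sub["label"].astype(str).tolist()
    meta_path = out / "taxon_meta.csv"
    if meta_path.exists():
        taxon_meta = pd.read_csv(meta_path, index_col="taxon_code")
        if "taxon_code" not in taxon_meta.columns:
            taxon_meta["taxon_code"] = taxon_meta.index
    else:
        taxon_meta = pd.DataFrame()
    pair_labels = []
    for lab in re_labels.get("beta_o", re_labels.get("beta_len", [])):
        host, _, taxon = str(lab).partition("|")
        pair_labels.append((host, taxon))
    return FitResult(
        spec=spec, n=int(side["n"]), k_fixed=int(side["k_fixed"]),
        nll=float(side["nll"]), aicc=float(side["aicc"]),
        params=side["params"],
        params_natural=side.get("params_natural",
                                ParameterSet(side["params"]).natural()),
        se=side.get("se", {}), se_natural={},
        re_modes=re_modes, re_sds=re_sds, re_labels=re_labels,
        scaling=scaling, convergence=side.get("convergence", {}),
        taxon_meta=taxon_meta, pair_labels=pair_labels,
        slope_group_labels=list(side.get("slope_group_labels", [])),
    )


def _re_labels_for(asm: "_Assembly", data: ModelData) -> dict:
    labels = {}
    for name in asm.block_slices:
        if name in ("beta_o", "beta_len"):
            labels[name] = [f"{h}|{t}" for h, t in data.pair_labels]
        elif name == "beta_og":
            labels[name] = list(data.intercept_group_labels)
        elif name in ("beta_lat", "log_phi") or name.startswith("gamma["):
            labels[name] = list(data.taxon_labels)
        elif name == "zeta":
            labels[name] = list(data.fish_labels)
    return labels


def fit_result_from_parameters(data: ModelData, params: Mapping[str, float],
                               re_modes: dict | None = None,
                               evaluate: bool = False) -> FitResult:
    """Wrap known outer parameters (e.g. simulation truth) as a FitResult.

    Useful for evaluating diagnostics or predictions at a known parameter
    point without fitting.  ``re_modes`` optionally supplies latent-effect
    values per block; ``evaluate=True`` also computes the Laplace marginal
    NLL and AICc at the given parameters.
    """
    asm = _Assembly(data)
    layout = asm.layout
    missing = [n for n in layout.names if n not in params]
    if missing:
        raise ValueError(f"missing parameter(s): {missing}")
    th = {n: float(params[n]) for n in layout.names}
    nll = np.nan
    crit = np.nan
    if evaluate:
        nll, _, _, _, _ = asm.marginal_nll(th)
        crit = aicc(float(nll), layout.k, data.n)
    return FitResult(
        spec=data.spec, n=data.n, k_fixed=layout.k, nll=float(nll), aicc=crit,
        params=th, params_natural=ParameterSet(th).natural(),
        se={}, se_natural={}, re_modes=dict(re_modes or {}), re_sds={},
        re_labels=_re_labels_for(asm, data), scaling=dict(data.scaling),
        convergence={"constructed": True},
        taxon_meta=data.taxon_meta.copy(), pair_labels=list(data.pair_labels),
        slope_group_labels=list(data.slope_group_labels), _data=data,
    )


def _default_init(data: ModelData, layout: ParamLayout) -> np.ndarray:
    mean_count = max(float(np.mean(data.y)), 1e-3)
    base = {
        "mu_o": math.log(mean_count),
        "log_sigma_o": math.log(0.7),
        "mu_beta_o": math.log(mean_count),
        "log_sigma_beta_og": math.log(0.5),
        "mu_lat": 0.0, "log_sigma_lat": math.log(0.3),
        "mu_len": 0.0, "log_sigma_len": math.log(0.3),
        "log_sigma_zeta": math.log(0.5),
        "log_mu_phi": 0.0,
        "log_sigma_logphi": math.log(0.7),
    }
    vec = np.zeros(layout.k)
    for i, name in enumerate(layout.names):
        if name in base:
            vec[i] = base[name]
        elif name.startswith("mu_gamma"):
            vec[i] = 0.0
        elif name.startswith("log_sigma_gamma"):
            vec[i] = math.log(0.3)
    return vec


def fit_model(data: ModelData, spec: ModelSpec | None = None,
              options: FitOptions | None = None) -> FitResult:
    """Maximum (Laplace) marginal-likelihood fit of the outer parameters.

    Quasi-Newton (L-BFGS-B) over the outer parameters with SDs on the log
    scale; the inner random-effect problem is re-solved (warm-started) at
    every outer evaluation.  ``options.n_starts`` jittered restarts guard
    against bad local optima; the best optimum wins.
    """
    if data.n == 0:
        raise ValueError("empty ModelData")
    options = options or FitOptions()
    spec = data.spec
    asm = _Assembly(data)
    layout = asm.layout

    theta0 = _default_init(data, layout)
    if options.init:
        for name, val in options.init.items():
            if name in layout.index:
                theta0[layout.index[name]] = val

    warm = {"z": None}
    evals = {"n": 0}

    def value_at(th, z0):
        nll, z, _, _, _ = asm.marginal_nll(th, z0=z0, tol=options.inner_tol)
        return nll, z

    def fun_and_grad(vec):
        """Marginal NLL and a consistent forward-difference gradient.

        Every probe is warm-started from the mode at ``vec`` itself, so the
        whole gradient sees one inner basin; letting probes chain off each
        other makes the surface path-dependent wherever the dispersion
        block has nearby local modes, which stalls the outer optimizer.
        """
        evals["n"] += 1
        th = dict(zip(layout.names, vec))
        try:
            nll0, z0 = value_at(th, warm["z"])
        except (InnerNonConvergence, NonPositiveDefiniteHessian, OverflowError):
            return 1e10, np.zeros(layout.k)
        if not np.isfinite(nll0):
            return 1e10, np.zeros(layout.k)
        warm["z"] = z0
        h = options.fd_step
        grad = np.empty(layout.k)
        for a in range(layout.k):
            vec_a = np.array(vec, dtype=float)
            vec_a[a] += h
            try:
                nll_a, _ = value_at(dict(zip(layout.names, vec_a)), z0)
            except (InnerNonConvergence, NonPositiveDefiniteHessian,
                    OverflowError):
                nll_a = np.nan
            grad[a] = (nll_a - nll0) / h
        grad[~np.isfinite(grad)] = 0.0
        return nll0, grad

    def objective(vec):
        """Value-only evaluation (used by the stationarity check)."""
        th = dict(zip(layout.names, vec))
        try:
            nll, z, _, _, _ = asm.marginal_nll(th, z0=warm["z"],
                                               tol=options.inner_tol)
        except (InnerNonConvergence, NonPositiveDefiniteHessian, OverflowError):
            return 1e10
        if not np.isfinite(nll):
            return 1e10
        warm["z"] = z
        return nll

    rng = np.random.default_rng(options.seed)
    starts = [theta0]
    for _ in range(max(options.n_starts, 1) - 1):
        starts.append(theta0 + rng.normal(0.0, options.jitter_sd, size=layout.k))

    # generous box bounds keep trial steps inside exp()'s safe range
    bounds = [(-12.0, 6.0) if n.startswith("log_") else (-30.0, 30.0)
              for n in layout.names]
    coarse_options = {"maxiter": min(options.maxiter, 120), "ftol": 1e-9,
                      "gtol": 10 * options.outer_gtol, "maxcor": 25}
    fine_options = {"maxiter": options.maxiter, "ftol": 1e-11,
                    "gtol": options.outer_gtol, "maxcor": 25}
    best = None
    failures = []
    for s_idx, start in enumerate(starts):
        # two-stage optimisation: a coarse warm-chained pass to get near the
        # optimum, then a fine pass whose inner anchor is reset (cold) --
        # warm-chained inner modes can get trapped in a poor local basin of
        # the dispersion block, and the cold restart reliably escapes it
        try:
            warm["z"] = None
            res = minimize(fun_and_grad, start, jac=True, method="L-BFGS-B",
                           bounds=bounds, options=coarse_options)
            warm["z"] = None
            res2 = minimize(fun_and_grad, res.x, jac=True, method="L-BFGS-B",
                            bounds=bounds, options=fine_options)
            if np.isfinite(res2.fun) and res2.fun <= res.fun:
                res = res2
        except Exception as exc:  # noqa: BLE001 - aggregate for the caller
            failures.append(f"start {s_idx}: {exc!r}")
            continue
        if not np.isfinite(res.fun) or res.fun >= 1e10:
            failures.append(f"start {s_idx}: non-finite objective")
            continue
        if best is None or res.fun < best[0].fun:
            best = (res, s_idx)
    if best is None:
        raise RuntimeError("all starts failed: " + "; ".join(failures))
    res, s_idx = best

    th_hat = dict(zip(layout.names, res.x))
    nll, z_hat, H, lu, inner_info = asm.marginal_nll(th_hat, z0=warm["z"],
                                                     tol=options.inner_tol)
    sds = asm.cond_sds(lu)
    params = ParameterSet(th_hat)

    se, se_nat, cov = {}, {}, None
    if options.compute_se:
        se_vec, cov = _wald_from_fd(asm, res.x, layout, options)
        se = dict(zip(layout.names, se_vec))
        for name in layout.names:
            if name.startswith("log_"):
                se_nat[name[4:]] = math.exp(th_hat[name]) * se[name]
            else:
                se_nat[name] = se[name]

    re_labels = {}
    for name in asm.block_slices:
        if name == "beta_o" or name == "beta_len":
            re_labels[name] = [f"{h}|{t}" for h, t in data.pair_labels]
        elif name == "beta_og":
            re_labels[name] = list(data.intercept_group_labels)
        elif name in ("beta_lat", "log_phi") or name.startswith("gamma["):
            re_labels[name] = list(data.taxon_labels)
        elif name == "zeta":
            re_labels[name] = list(data.fish_labels)

    fit = FitResult(
        spec=spec, n=data.n, k_fixed=layout.k, nll=float(nll),
        aicc=aicc(float(nll), layout.k, data.n),
        params=th_hat, params_natural=params.natural(),
        se=se, se_natural=se_nat,
        re_modes=asm.split_blocks(z_hat), re_sds=asm.split_blocks(sds),
        re_labels=re_labels, scaling=dict(data.scaling),
        convergence={
            "success": bool(res.success), "message": str(res.message),
            "outer_iterations": int(res.nit), "n_evaluations": evals["n"],
            "grad_norm": float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan,
            "seed": options.seed, "start_index": s_idx,
            **inner_info,
        },
        taxon_meta=data.taxon_meta.copy(), pair_labels=list(data.pair_labels),
        slope_group_labels=list(data.slope_group_labels),
        outer_cov=cov,
        _data=data,
    )
    return fit


def _wald_from_fd(asm: _Assembly, theta: np.ndarray, layout: ParamLayout,
                  options: FitOptions, step: float = 1e-3):
    """Wald SEs from a central-difference Hessian of the marginal NLL.

    Every evaluation is warm-started from the *same* base-point mode so the
    inner solve lands in one basin consistently; chaining warm starts across
    evaluations makes the surface path-dependent when the dispersion block
    has nearby local modes, which corrupts finite differences.
    """
    k = layout.k
    th0 = dict(zip(layout.names, theta))
    _, z_base, _, _, _ = asm.marginal_nll(th0, tol=options.inner_tol)

    def f(vec):
        th = dict(zip(layout.names, vec))
        try:
            nll, _, _, _, _ = asm.marginal_nll(th, z0=z_base,
                                               tol=options.inner_tol)
        except (InnerNonConvergence, NonPositiveDefiniteHessian):
            return np.nan
        return nll

    h = step * np.maximum(1.0, np.abs(theta))
    H = np.empty((k, k))
    f0 = f(theta)
    fp = np.empty(k)
    fm = np.empty(k)
    for a in range(k):
        e = np.zeros(k)
        e[a] = h[a]
        fp[a] = f(theta + e)
        fm[a] = f(theta - e)
        H[a, a] = (fp[a] - 2 * f0 + fm[a]) / h[a] ** 2
    for a in range(k):
        for b in range(a + 1, k):
            ea = np.zeros(k); ea[a] = h[a]
            eb = np.zeros(k); eb[b] = h[b]
            H[a, b] = H[b, a] = (
                f(theta + ea + eb) - f(theta + ea - eb)
                - f(theta - ea + eb) + f(theta - ea - eb)
            ) / (4 * h[a] * h[b])
    se = np.full(k, np.nan)
    cov = None
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        ok = d > 0
        se[ok] = np.sqrt(d[ok])
        if not ok.all():
            logger.warning("non-positive curvature for parameters %s",
                           [layout.names[i] for i in np.flatnonzero(~ok)])
    except np.linalg.LinAlgError:
        logger.warning("singular outer Hessian; SEs unavailable")
    return se, cov


def wald_se(fit: FitResult) -> dict:
    """Wald standard errors of the outer parameters (computing them if the
    fit was run with ``compute_se=False``)."""
    if fit.se:
        return fit.se
    if fit._data is None:
        raise ValueError("fit carries no model data; rerun fit_model with compute_se")
    asm = _Assembly(fit._data)
    layout = asm.layout
    theta = np.array([fit.params[n] for n in layout.names])
    se_vec, cov = _wald_from_fd(asm, theta, layout, FitOptions())
    fit.se = dict(zip(layout.names, se_vec))
    fit.outer_cov = cov
    for name in layout.names:
        if name.startswith("log_"):
            fit.se_natural[name[4:]] = math.exp(fit.params[name]) * fit.se[name]
        else:
            fit.se_natural[name] = fit.se[name]
    return fit.se
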