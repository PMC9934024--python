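import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats
from scipy.special import logsumexp

from paraburden import (
    CountTable,
    FitOptions,
    ModelSpec,
    ParameterSet,
    RandomEffectSet,
    aicc,
    build_model_data,
    fit_model,
    joint_nll,
    laplace_marginal_nll,
    linear_predictor,
    nb_logpmf,
)
from paraburden.nbglmm import ParamLayout

from conftest import toy_table


def taxa_frame(entries):
    df = pd.DataFrame(entries)
    return df.set_index("taxon_code", drop=False)


class TestNbLogpmf:
    def test_poisson_limit(self):
        assert nb_logpmf(0, 1.0, 1e12) == pytest.approx(-1.0, abs=1e-9)

    def test_normalization(self):
        y = np.arange(0, 1001)
        total = np.exp(nb_logpmf(y, 2.0, 1.5)).sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_gamma_poisson_quadrature(self):
        # NB2 is the Poisson-Gamma mixture: integrate it directly
        from scipy.integrate import quad

        for y, mu, phi in [(3, 2.0, 1.5), (0, 0.5, 0.7), (12, 6.0, 4.0)]:
            def integrand(g):
                return stats.poisson.pmf(y, mu * g) * stats.gamma.pdf(g, phi, scale=1.0 / phi)
            val, _ = quad(integrand, 0, np.inf, epsabs=1e-13, epsrel=1e-12)
            assert nb_logpmf(y, mu, phi) == pytest.approx(np.log(val), abs=1e-8)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            nb_logpmf(1.5, 2.0, 1.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            nb_logpmf(1, -1.0, 1.0)
        with pytest.raises(ValueError):
            nb_logpmf(-1, 1.0, 1.0)


def two_fish_table():
    taxa = taxa_frame([
        {"taxon_code": "t1", "broad_group": "Trematoda", "n_obligate_hosts": 3},
        {"taxon_code": "t2", "broad_group": "Copepoda", "n_obligate_hosts": 1},
    ])
    return toy_table(
        {"F1": {"t1": 2, "t2": 0}, "F2": {"t1": 1, "t2": 4}},
        years={"F1": 1950, "F2": 2000},
        latitudes={"F1": 47.5, "F2": 48.5},
        lengths={"F1": 20.0, "F2": 40.0},
        taxa_meta=taxa,
    )


class TestModelData:
    def test_indices_enumerated(self):
        data = build_model_data(two_fish_table(), ModelSpec(predictors=("year",)))
        assert data.n == 4
        assert data.J == 2 and data.K == 2 and data.F == 2
        # lexicographic assignment
        assert data.pair_labels == [("SPA", "t1"), ("SPA", "t2")]
        assert data.taxon_labels == ["t1", "t2"]

    def test_nhost_collapse_to_3plus(self):
        taxa = taxa_frame([
            {"taxon_code": "t1", "broad_group": "Cestoda", "n_obligate_hosts": 4},
            {"taxon_code": "t2", "broad_group": "Copepoda", "n_obligate_hosts": 1},
        ])
        table = toy_table({"F1": {"t1": 1, "t2": 0}, "F2": {"t1": 0, "t2": 2}},
                          years={"F1": 1950, "F2": 1990},
                          latitudes={"F1": 47.5, "F2": 48.5},
                          lengths={"F1": 22.0, "F2": 41.0}, taxa_meta=taxa)
        data = build_model_data(table, ModelSpec(predictors=("year",),
                                                 slope_grouping="by_n_hosts",
                                                 intercept_grouping="by_n_hosts"))
        assert "3+" in data.slope_group_labels

    def test_missing_covariate_rows_excluded_with_count(self):
        table = two_fish_table()
        extra = table.df[table.df["fish_id"] == "F2"].copy()
        extra["fish_id"] = "F3"
        extra["latitude"] = 47.9
        extra["total_length_cm"] = 33.0
        extra["year"] = 1975
        table = CountTable(pd.concat([table.df, extra], ignore_index=True),
                           taxa=table.taxa)
        table.df.loc[table.df["fish_id"] == "F1", "latitude"] = np.nan
        data = build_model_data(table, ModelSpec(predictors=("year",)))
        assert data.n_excluded == 2
        assert data.n == 4

    def test_grouping_without_metadata_errors(self):
        table = two_fish_table()
        table.taxa = None
        with pytest.raises(ValueError, match="n_obligate_hosts"):
            build_model_data(table, ModelSpec(predictors=("year",),
                                              slope_grouping="by_n_hosts"))

    def test_slope_grouping_requires_predictors(self):
        with pytest.raises(ValueError):
            ModelSpec(slope_grouping="by_n_hosts")


class TestParameterCount:
    """k_fixed is a pure function of the spec (hand counts)."""

    @pytest.mark.parametrize("spec,expected", [
        (ModelSpec(), 9),
        (ModelSpec(predictors=("year",)), 11),
        (ModelSpec(predictors=("year",), slope_grouping="by_n_hosts",
                   intercept_grouping="by_n_hosts"), 14),
    ])
    def test_phase1_counts(self, small_filtered, spec, expected):
        table, _, _ = small_filtered
        data = build_model_data(table, spec)
        assert ParamLayout(data).k == expected

    def test_taxonomy_count_depends_on_groups_present(self, small_filtered):
        table, _, _ = small_filtered
        spec = ModelSpec(predictors=("year",), slope_grouping="by_taxonomy",
                         intercept_grouping="by_taxonomy")
        data = build_model_data(table, spec)
        g = len(data.slope_group_labels)
        # (sigma_o, mu_beta_o, sigma_og) + 2 lat + 2 len + 1 zeta + 2 disp
        # + g group means + 1 sigma_gamma
        assert ParamLayout(data).k == 10 + g + 1


class TestLinearPredictorAndJointNLL:
    def _setup(self):
        spec = ModelSpec(predictors=("year",))
        data = build_model_data(two_fish_table(), spec)
        params = ParameterSet({
            "mu_o": 0.3, "log_sigma_o": math.log(0.8),
            "mu_lat": 0.1, "log_sigma_lat": math.log(0.5),
            "mu_len": -0.2, "log_sigma_len": math.log(0.4),
            "log_sigma_zeta": math.log(0.6),
            "log_mu_phi": 0.2, "log_sigma_logphi": math.log(0.5),
            "mu_gamma[year]": -0.15, "log_sigma_gamma[year]": math.log(0.3),
        })
        rng = np.random.default_rng(31)
        re = RandomEffectSet({
            "beta_o": rng.normal(0.3, 0.5, data.J),
            "beta_lat": rng.normal(0, 0.5, data.K),
            "beta_len": rng.normal(0, 0.5, data.J),
            "zeta": rng.normal(0, 0.5, data.F),
            "gamma[year]": rng.normal(0, 0.3, data.K),
            "log_phi": rng.normal(0.2, 0.5, data.K),
        })
        return spec, data, params, re

    def test_constant_intercept(self):
        spec, data, params, re = self._setup()
        re0 = RandomEffectSet({k: np.zeros_like(v) for k, v in re.blocks.items()})
        re0.blocks["beta_o"][:] = 1.7
        eta = linear_predictor(params, re0, data)
        np.testing.assert_allclose(eta, 1.7, atol=1e-12)

    def test_matches_naive_loop(self):
        spec, data, params, re = self._setup()
        eta = linear_predictor(params, re, data)
        for i in range(data.n):
            expected = (re["beta_o"][data.pair_idx[i]]
                        + data.X_lat[i] * re["beta_lat"][data.taxon_idx[i]]
                        + data.X_len[i] * re["beta_len"][data.pair_idx[i]]
                        + re["zeta"][data.fish_idx[i]]
                        + data.U[i, 0] * re["gamma[year]"][data.taxon_idx[i]])
            assert eta[i] == pytest.approx(expected, abs=1e-12)

    def test_joint_nll_naive_accumulation(self):
        spec, data, params, re = self._setup()
        val = joint_nll(params, re, data)
        eta = linear_predictor(params, re, data)
        total = 0.0
        for i in range(data.n):
            phi = math.exp(re["log_phi"][data.taxon_idx[i]])
            total -= float(nb_logpmf(int(data.y[i]), math.exp(eta[i]), phi))
        prior_terms = [
            (re["beta_o"], params["mu_o"], 0.8),
            (re["beta_lat"], params["mu_lat"], 0.5),
            (re["beta_len"], params["mu_len"], 0.4),
            (re["zeta"], 0.0, 0.6),
            (re["gamma[year]"], params["mu_gamma[year]"], 0.3),
            (re["log_phi"], params["log_mu_phi"], 0.5),
        ]
        for block, m, s in prior_terms:
            total -= float(np.sum(stats.norm.logpdf(block, m, s)))
        assert val == pytest.approx(total, rel=1e-10)

    def test_additivity_under_duplication(self):
        # duplicating every fish (fresh ids, duplicated zeta) doubles the NB
        # data portion of the joint NLL; covariate-free spec so nothing is
        # rescaled by the duplication
        spec = ModelSpec(include_latitude=False, include_length=False,
                         random_dispersion=False)
        table = two_fish_table()
        dup = table.df.copy()
        dup["fish_id"] = dup["fish_id"] + "_b"
        big = CountTable(pd.concat([table.df, dup], ignore_index=True),
                         taxa=table.taxa)
        data1 = build_model_data(table, spec)
        data2 = build_model_data(big, spec)
        params = ParameterSet({"mu_o": 0.3, "log_sigma_o": math.log(0.8),
                               "log_sigma_zeta": math.log(0.6),
                               "log_mu_phi": 0.2})
        rng = np.random.default_rng(31)
        b_o = rng.normal(0.3, 0.5, data1.J)
        z1 = dict(zip(data1.fish_labels, rng.normal(0, 0.5, data1.F)))
        z2 = {f: z1[f.replace("_b", "")] for f in data2.fish_labels}
        re1 = RandomEffectSet({"beta_o": b_o,
                               "zeta": np.array([z1[f] for f in data1.fish_labels])})
        re2 = RandomEffectSet({"beta_o": b_o,
                               "zeta": np.array([z2[f] for f in data2.fish_labels])})
        v1 = joint_nll(params, re1, data1)
        v2 = joint_nll(params, re2, data2)
        prior_fish = -float(np.sum(stats.norm.logpdf(re1["zeta"], 0, 0.6)))
        prior_rest = -float(np.sum(stats.norm.logpdf(b_o, 0.3, 0.8)))
        data_part = v1 - prior_fish - prior_rest
        assert v2 == pytest.approx(2 * data_part + 2 * prior_fish + prior_rest,
                                   rel=1e-9)


def single_effect_table(counts, years=None):
    rows = []
    for i, c in enumerate(counts):
        rows.append({"fish_id": "F0" if years is None else f"F{i:03d}",
                     "host_species": "SPA",
                     "taxon_code": f"T{i:03d}" if years is None else "T0",
                     "count": int(c),
                     "year": 2000 if years is None else int(years[i]),
                     "latitude": 48.0, "total_length_cm": 30.0})
    return CountTable(pd.DataFrame(rows))


def gh61_log_integral(negjoint):
    """Independent 61-point adaptive Gauss-Hermite marginal NLL (1-D)."""
    res = optimize.minimize_scalar(negjoint, bounds=(-8, 8), method="bounded",
                                   options={"xatol": 1e-11})
    zh = res.x
    h = (negjoint(zh + 1e-4) - 2 * negjoint(zh) + negjoint(zh - 1e-4)) / 1e-8
    x, w = np.polynomial.hermite.hermgauss(61)
    s = 1.0 / np.sqrt(h)
    vals = -np.array([negjoint(zh + np.sqrt(2) * s * xi) for xi in x])
    return -(logsumexp(vals + x ** 2 + np.log(w)) + np.log(np.sqrt(2) * s))


class TestLaplace:
    def test_degenerate_sd_limit_pins_effects(self):
        # as every hyper-SD -> 0 the marginal collapses to the NB NLL with
        # all effects at their hyper-means
        rng = np.random.default_rng(5)
        counts = rng.poisson(2.0, 30)
        table = single_effect_table(counts)
        spec = ModelSpec(include_latitude=False, include_length=False,
                         random_intercept=True, random_dispersion=False,
                         include_fish=True)
        data = build_model_data(table, spec)
        mu_o, phi = math.log(2.0), 2.0
        params = ParameterSet({"mu_o": mu_o, "log_sigma_o": math.log(1e-4),
                               "log_sigma_zeta": math.log(1e-4),
                               "log_mu_phi": math.log(phi)})
        nll, modes, sds = laplace_marginal_nll(params, data)
        pinned = -float(np.sum(nb_logpmf(counts, math.exp(mu_o), phi)))
        assert nll == pytest.approx(pinned, abs=1e-2)

    def test_single_fish_matches_gauss_hermite(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(3.0, 80)
        table = single_effect_table(counts)
        spec = ModelSpec(include_latitude=False, include_length=False,
                         random_intercept=False, random_dispersion=False,
                         include_fish=True)
        data = build_model_data(table, spec)
        mu0, phi, sz = 3.0, 2.0, 0.5
        params = ParameterSet({"mu_o": math.log(mu0),
                               "log_mu_phi": math.log(phi),
                               "log_sigma_zeta": math.log(sz)})
        nll, _, _ = laplace_marginal_nll(params, data)

        def negjoint(z):
            mu = mu0 * np.exp(z)
            return -(stats.nbinom.logpmf(counts, phi, phi / (phi + mu)).sum()
                     + stats.norm.logpdf(z, 0, sz))

        assert nll == pytest.approx(gh61_log_integral(negjoint), abs=1e-3)

    def test_independent_fish_factorize(self):
        # the marginal NLL of two independent fish equals the sum of their
        # single-fish marginals
        rng = np.random.default_rng(9)
        counts = rng.poisson(2.0, 24)
        spec = ModelSpec(include_latitude=False, include_length=False,
                         random_intercept=False, random_dispersion=False,
                         include_fish=True)
        params = ParameterSet({"mu_o": math.log(2.0), "log_mu_phi": 0.0,
                               "log_sigma_zeta": math.log(0.5)})

        def table_for(fish_ids, cts):
            rows = [{"fish_id": f, "host_species": "SPA",
                     "taxon_code": f"T{i:02d}", "count": int(c),
                     "year": 2000, "latitude": 48.0, "total_length_cm": 30.0}
                    for i, (f, c) in enumerate(zip(fish_ids, cts))]
            return CountTable(pd.DataFrame(rows))

        half = len(counts) // 2
        both = table_for(["A"] * half + ["B"] * half, counts)
        one = table_for(["A"] * half, counts[:half])
        two = table_for(["B"] * half, counts[half:])
        nll_both, _, _ = laplace_marginal_nll(params, build_model_data(both, spec))
        nll_one, _, _ = laplace_marginal_nll(params, build_model_data(one, spec))
        nll_two, _, _ = laplace_marginal_nll(params, build_model_data(two, spec))
        assert nll_both == pytest.approx(nll_one + nll_two, abs=1e-6)

    def test_dispersion_dimension_close_to_quadrature(self):
        # the log-dispersion dimension is the least Gaussian; Laplace is
        # accurate to ~1e-2 here (documented), tighter for mean-type effects
        rng = np.random.default_rng(13)
        mphi, mu0, slp = 2.0, 3.0, 0.5
        counts = rng.negative_binomial(mphi, mphi / (mphi + mu0), 150)
        table = single_effect_table(counts, years=np.full(150, 2000))
        spec = ModelSpec(include_latitude=False, include_length=False,
                         random_intercept=False, random_dispersion=True,
                         include_fish=False)
        data = build_model_data(table, spec)
        params = ParameterSet({"mu_o": math.log(mu0),
                               "log_mu_phi": math.log(mphi),
                               "log_sigma_logphi": math.log(slp)})
        nll, _, _ = laplace_marginal_nll(params, data)

        def negjoint(lam):
            phi = np.exp(lam)
            return -(stats.nbinom.logpmf(counts, phi, phi / (phi + mu0)).sum()
                     + stats.norm.logpdf(lam, np.log(mphi), slp))

        assert nll == pytest.approx(gh61_log_integral(negjoint), abs=1e-2)


class TestAicc:
    def test_zero_k(self):
        assert aicc(100.0, 0, 50) == pytest.approx(200.0)

    def test_direct_formula(self):
        assert aicc(100.0, 5, 50) == pytest.approx(200 + 10 + 60 / 44)
        assert aicc(100.0, 5, 50) == pytest.approx(211.3636, abs=1e-3)

    def test_large_n_limit(self):
        assert aicc(100.0, 5, 10 ** 9) == pytest.approx(210.0, abs=1e-6)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(10.0, 5, 6)


class TestFitModel:
    def test_intercept_only_matches_log_mean(self):
        rng = np.random.default_rng(17)
        counts = rng.poisson(4.0, 200)
        table = single_effect_table(counts, years=np.full(200, 2000))
        spec = ModelSpec(include_latitude=False, include_length=False,
                         random_intercept=False, random_dispersion=False,
                         include_fish=False)
        data = build_model_data(table, spec)
        fit = fit_model(data, options=FitOptions(n_starts=1, compute_se=False))
        assert fit.params["mu_o"] == pytest.approx(math.log(counts.mean()),
                                                   abs=1e-3)

    def test_row_permutation_invariance(self, small_filtered):
        table, _, _ = small_filtered
        spec = ModelSpec(predictors=("year",))
        shuffled = table.copy()
        shuffled.df = shuffled.df.sample(frac=1.0, random_state=99).reset_index(drop=True)
        d1 = build_model_data(table, spec)
        d2 = build_model_data(shuffled, spec)
        opts = FitOptions(n_starts=1, compute_se=False, maxiter=150)
        f1 = fit_model(d1, options=opts)
        f2 = fit_model(d2, options=opts)
        assert f1.nll == pytest.approx(f2.nll, abs=1e-6)

    def test_year_offset_invariance(self, small_filtered):
        # adding a constant to calendar year is absorbed by standardization
        table, _, _ = small_filtered
        spec = ModelSpec(predictors=("year",))
        shifted = table.copy()
        shifted.df["year"] = shifted.df["year"] + 37
        opts = FitOptions(n_starts=1, compute_se=False, maxiter=150)
        f1 = fit_model(build_model_data(table, spec), options=opts)
        f2 = fit_model(build_model_data(shifted, spec), options=opts)
        assert f1.nll == pytest.approx(f2.nll, abs=1e-6)

    def test_aicc_consistent_with_stored_nll(self, small_m2_fit):
        fit, _, _ = small_m2_fit
        assert fit.aicc == pytest.approx(aicc(fit.nll, fit.k_fixed, fit.n))

    def test_convergence_recorded(self, small_m2_fit):
        fit, _, _ = small_m2_fit
        assert fit.convergence["success"]
        assert fit.convergence["seed"] == 20230109

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            table = single_effect_table([1, 2])
            spec = ModelSpec(include_latitude=False, include_length=False)
            data = build_model_data(table, spec)
            data.y = data.y[:0]
            fit_model(data)


class TestWaldSE:
    def test_matches_finite_difference_oracle(self):
        # 1-D NB intercept model: SE from an independently coded FD Hessian
        rng = np.random.default_rng(23)
        counts = rng.negative_binomial(2.0, 2.0 / (2.0 + 3.0), 300)
        table = single_effect_table(counts, years=np.full(300, 2000))
        spec = ModelSpec(include_latitude=False, include_length=False,
                         random_intercept=False, random_dispersion=False,
                         include_fish=False)
        data = build_model_data(table, spec)
        fit = fit_model(data, options=FitOptions(n_starts=1, compute_se=True))
        mu_hat, lphi_hat = fit.params["mu_o"], fit.params["log_mu_phi"]

        def nll(mu_o, lphi):
            phi = math.exp(lphi)
            return -float(np.sum(stats.nbinom.logpmf(
                counts, phi, phi / (phi + math.exp(mu_o)))))

        h = 1e-4
        H = np.empty((2, 2))
        H[0, 0] = (nll(mu_hat + h, lphi_hat) - 2 * nll(mu_hat, lphi_hat)
                   + nll(mu_hat - h, lphi_hat)) / h ** 2
        H[1, 1] = (nll(mu_hat, lphi_hat + h) - 2 * nll(mu_hat, lphi_hat)
                   + nll(mu_hat, lphi_hat - h)) / h ** 2
        H[0, 1] = H[1, 0] = (nll(mu_hat + h, lphi_hat + h) - nll(mu_hat + h, lphi_hat - h)
                             - nll(mu_hat - h, lphi_hat + h) + nll(mu_hat - h, lphi_hat - h)
                             ) / (4 * h * h)
        se = np.sqrt(np.diag(np.linalg.inv(H)))
        assert fit.se["mu_o"] == pytest.approx(se[0], abs=1e-4)
        assert fit.se["log_mu_phi"] == pytest.approx(se[1], abs=1e-4)

    def test_delta_method_consistency(self, small_m2_fit):
        fit, _, _ = small_m2_fit
        for name, val in fit.params.items():
            if name.startswith("log_") and np.isfinite(fit.se.get(name, np.nan)):
                assert fit.se_natural[name[4:]] == pytest.approx(
                    math.exp(val) * fit.se[name], rel=1e-9)


class TestFitSerialization:
    def test_save_load_roundtrip(self, small_m2_fit, tmp_path):
        from paraburden import load_fit_result

        fit, _, _ = small_m2_fit
        fit.save(tmp_path / "fit")
        back = load_fit_result(tmp_path / "fit")
        assert back.spec == fit.spec
        assert back.nll == pytest.approx(fit.nll)
        assert back.aicc == pytest.approx(fit.aicc)
        for name, val in fit.params.items():
            assert back.params[name] == pytest.approx(val)
        for block, modes in fit.re_modes.items():
            np.testing.assert_allclose(back.re_modes[block], modes)
            assert back.re_labels[block] == [str(x) for x in fit.re_labels[block]]
        assert back.scaling["year"].sd == pytest.approx(fit.scaling["year"].sd)
        assert list(back.pair_labels) == [(h, t) for h, t in fit.pair_labels]
        np.testing.assert_allclose(back.taxon_meta["abundance"],
                                   fit.taxon_meta["abundance"])

    def test_loaded_fit_supports_outputs(self, small_m2_fit, tmp_path):
        from paraburden import load_fit_result, predict_group_average

        fit, _, _ = small_m2_fit
        fit.save(tmp_path / "fit")
        back = load_fit_result(tmp_path / "fit")
        curve = predict_group_average(back, np.arange(1930, 2010), "3+")
        ref = predict_group_average(fit, np.arange(1930, 2010), "3+")
        np.testing.assert_allclose(curve.predicted, ref.predicted)
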