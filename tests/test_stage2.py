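"""Stage-2 MET analysis: overall means, heritability, genetic correlation,
factor-analytic GxE, model selection and trait screening."""

import numpy as np
import pandas as pd
import pytest

from phenomet.metsim import SimConfig, YearSite, simulate_adjusted_means, simulate_trait_pair
from phenomet.stage2 import (
    GxEModelReport,
    env_correlations,
    fit_fa,
    fit_overall,
    genetic_correlation,
    heritability_cullis,
    screen_intermediate_traits,
    select_gxe_model,
)


def _means_from_cells(cells, se=0.1, sites=None):
    """AdjustedMeans table from an m x p matrix of cell means (unit-ish weights)."""
    m, p = cells.shape
    sites = sites or [f"ys{j}" for j in range(p)]
    recs = [
        (sites[j], f"g{i:03d}", "y", cells[i, j], se, 1 / se**2)
        for i in range(m)
        for j in range(p)
    ]
    return pd.DataFrame(recs, columns=["year_site", "genotype", "trait", "blue", "se", "weight"])


def test_identical_year_sites_give_zero_interaction():
    rng = np.random.default_rng(0)
    g = rng.normal(0, 1, 60)
    # two near-identical year-sites (tiny jitter keeps the likelihood regular)
    cells = np.column_stack([g, g]) + rng.normal(0, 1e-3, (60, 2))
    fit = fit_overall(_means_from_cells(cells), gxe="Id")
    assert fit.variance_params["interaction.s2"] < 1e-4
    assert fit.variance_params["genotype.s2"] == pytest.approx(g.var(ddof=1), rel=0.1)


def test_single_year_site_rejected():
    rng = np.random.default_rng(1)
    means = _means_from_cells(rng.normal(size=(10, 1)))
    with pytest.raises(ValueError, match="year-site"):
        fit_overall(means)


def test_genotype_blup_ranking_matches_weighted_means():
    rng = np.random.default_rng(2)
    cells = rng.normal(0, 1, (30, 1)) + rng.normal(0, 0.05, (30, 4))
    means = _means_from_cells(cells)
    fit = fit_overall(means, gxe="Id")
    blups = pd.Series(fit.random_effects["genotype"], index=fit.genotypes)
    wmeans = means.groupby("genotype")["blue"].mean()
    assert (blups.rank() == wmeans.loc[blups.index].rank()).all()


def test_diag_interaction_variance_ratio_recovered():
    """Two sites with interaction variances 1 and 4: the Diag fit recovers
    the ratio within a factor of two at m=200."""
    cfg = SimConfig(
        seed=3,
        n_genotypes=200,
        year_sites=[YearSite("a"), YearSite("b")],
        loadings_true=np.zeros((2, 1)),
        psi_true=np.array([1.0, 4.0]),
        sigma2_g=0.5,
        missing_fraction=0.0,
    )
    means, _ = simulate_adjusted_means(cfg)
    fit = fit_overall(means, gxe="Diag")
    v = [fit.variance_params[f"interaction.s2[{s}]"] for s in ("a", "b")]
    assert 2.0 <= v[1] / v[0] <= 8.0


def test_cullis_h2_against_pev_oracle():
    """Fitted Cullis H2 agrees with the oracle computed from the true
    variance parameters through a dense mixed-model-equation PEV."""
    cfg = SimConfig(
        seed=4, n_genotypes=200, sigma2_g=0.3,
        loadings_true=np.zeros((5, 2)), psi_true=np.full(5, 0.08), missing_fraction=0.0,
    )
    means, truth = simulate_adjusted_means(cfg)
    fit = fit_overall(means, gxe="Id")
    h2 = heritability_cullis(fit)

    # oracle: dense V at the true parameters, PEV = G - G Z' P Z G
    means = means.reset_index(drop=True)
    genotypes = sorted(means["genotype"].unique())
    gi = means["genotype"].map({g: i for i, g in enumerate(genotypes)}).to_numpy()
    sites = sorted(means["year_site"].unique())
    si = means["year_site"].map({s: j for j, s in enumerate(sites)}).to_numpy()
    n, m = len(means), len(genotypes)
    Z = np.zeros((n, m))
    Z[np.arange(n), gi] = 1.0
    X = np.zeros((n, len(sites)))
    X[:, 0] = 1.0
    for j in range(1, len(sites)):
        X[si == j, j] = 1.0
    V = cfg.sigma2_g * Z @ Z.T + np.diag(cfg.psi_true[0] + means["se"] ** 2)
    Vi = np.linalg.inv(V)
    P = Vi - Vi @ X @ np.linalg.solve(X.T @ Vi @ X, X.T @ Vi)
    G = cfg.sigma2_g * np.eye(m)
    C = G - G @ Z.T @ P @ Z @ G
    d = np.diag(C)
    vbar = (2 * m * d.sum() - 2 * C.sum()) / (m * (m - 1))
    h2_oracle = 1 - vbar / (2 * cfg.sigma2_g)
    assert h2 == pytest.approx(h2_oracle, abs=0.05)


def test_cullis_h2_information_monotonicity():
    rng = np.random.default_rng(5)
    cells = rng.normal(0, 1, (40, 1)) + rng.normal(0, 0.5, (40, 3))
    means = _means_from_cells(cells)
    fit1 = fit_overall(means, gxe="Id")
    doubled = pd.concat(
        [means, means.assign(year_site=means["year_site"] + "_bis")], ignore_index=True
    )
    fit2 = fit_overall(doubled, gxe="Id")
    assert heritability_cullis(fit2) > heritability_cullis(fit1)


def test_cullis_h2_null_calibration():
    """sigma2_g = 0: H2 stays near zero, up to the positive-part REML
    fluctuation of order sqrt(2/m) per seed."""
    vals = []
    for seed in range(5):
        cfg = SimConfig(
            seed=seed, n_genotypes=200, sigma2_g=0.0,
            loadings_true=np.zeros((5, 2)), psi_true=np.full(5, 0.05), missing_fraction=0.0,
        )
        means, _ = simulate_adjusted_means(cfg)
        vals.append(heritability_cullis(fit_overall(means, gxe="Id")))
    assert np.mean(vals) <= 0.1
    assert max(vals) <= 0.35


class TestGeneticCorrelation:
    def test_self_pair_with_jitter(self):
        cfg = SimConfig(seed=6, n_genotypes=100)
        m1, _ = simulate_trait_pair(cfg, r_g=0.99, genetic_sd=(1, 1), noise_sd=0.3)
        fit = genetic_correlation(m1, m1.assign(blue=m1["blue"] + 1e-4 * np.arange(len(m1))))
        assert fit.r_g >= 0.99

    def test_component_substitution(self):
        """Genetic variances 4 and 9 with covariance 3 give r_g = 0.5;
        checked by simulating exactly that covariance at large m."""
        cfg = SimConfig(seed=7, n_genotypes=800)
        m1, m2 = simulate_trait_pair(cfg, r_g=0.5, genetic_sd=(2.0, 3.0), noise_sd=0.3)
        fit = genetic_correlation(m1, m2)
        assert fit.genetic_cov[0, 1] / np.sqrt(fit.genetic_cov[0, 0] * fit.genetic_cov[1, 1]) == fit.r_g
        assert fit.r_g == pytest.approx(0.5, abs=0.08)

    def test_recovery_at_moderate_size(self):
        ests = []
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_genotypes=200)
            m1, m2 = simulate_trait_pair(cfg, r_g=0.6)
            ests.append(genetic_correlation(m1, m2).r_g)
        assert np.mean(ests) == pytest.approx(0.6, abs=0.1)

    def test_too_few_shared_units_rejected(self):
        cfg = SimConfig(seed=8, n_genotypes=20)
        m1, m2 = simulate_trait_pair(cfg, r_g=0.0)
        with pytest.raises(ValueError, match="year-sites"):
            genetic_correlation(m1[m1["year_site"] == m1["year_site"].iloc[0]], m2)


class TestFactorAnalytic:
    def test_k1_recovery(self):
        """Rank-1 truth with psi=0.1: implied covariance recovered within
        20% Frobenius at m=200."""
        lam = np.array([[0.6], [0.8], [0.5], [0.7], [0.4]])
        cfg = SimConfig(
            seed=9, n_genotypes=200, sigma2_g=0.0,
            loadings_true=lam, psi_true=np.full(5, 0.1), missing_fraction=0.0,
        )
        means, truth = simulate_adjusted_means(cfg)
        fa = fit_fa(means, k_f=1)
        perm = [truth.year_site_names.index(ys) for ys in fa.year_sites]
        Gt = (lam @ lam.T + np.diag(cfg.psi_true))[np.ix_(perm, perm)]
        G = fa.genetic_covariance()
        assert np.linalg.norm(G - Gt) / np.linalg.norm(Gt) <= 0.2

    def test_too_many_factors_rejected(self):
        cfg = SimConfig(seed=10, n_genotypes=30)
        means, _ = simulate_adjusted_means(cfg)
        with pytest.raises(ValueError, match="identifiable"):
            fit_fa(means, k_f=5)

    def test_loglik_nesting_id_diag_fa(self):
        cfg = SimConfig(seed=11, n_genotypes=100)
        means, _ = simulate_adjusted_means(cfg)
        ll = {}
        ll["Id"] = fit_overall(means, "Id").loglik_full
        ll["Diag"] = fit_overall(means, "Diag").loglik_full
        ll["FA1"] = fit_fa(means, 1).overall_fit.loglik_full
        ll["FA2"] = fit_fa(means, 2).overall_fit.loglik_full
        assert ll["Id"] <= ll["Diag"] + 1e-4
        assert ll["Diag"] <= ll["FA1"] + 1e-4
        assert ll["FA1"] <= ll["FA2"] + 1e-4


class TestEnvCorrelations:
    def test_rank1_positive_loadings_give_unit_correlations(self):
        from phenomet.stage2 import FAFit

        fa = FAFit(
            trait="y", genotypes=["a"], year_sites=list("ABC"),
            loadings=np.array([[0.5], [0.8], [1.1]]), specific_vars=np.zeros(3),
            scores=np.zeros((1, 1)), env_intercepts=np.zeros(3), overall_fit=None,
        )
        fa.overall_fit = type("F", (), {"converged": True})()
        C = env_correlations(fa).to_numpy()
        assert C == pytest.approx(np.ones((3, 3)))

    def test_unit_diagonal_symmetric_psd(self):
        cfg = SimConfig(seed=12, n_genotypes=100)
        means, _ = simulate_adjusted_means(cfg)
        C = env_correlations(fit_fa(means, 2)).to_numpy()
        assert np.diag(C) == pytest.approx(1.0)
        assert C == pytest.approx(C.T)
        assert np.linalg.eigvalsh(C).min() > -1e-8


class TestModelSelection:
    def test_intermediate_fa_minimal_is_discarded(self):
        cfg = SimConfig(seed=13, n_genotypes=200, sigma2_g=0.0)  # strong FA2 truth
        means, _ = simulate_adjusted_means(cfg)
        rep = select_gxe_model(means, role="intermediate")
        assert rep.selected in ("FA1", "FA2")
        assert rep.discarded and "GxE" in rep.reason

    def test_target_keeps_id_when_minimal(self):
        cfg = SimConfig(
            seed=14, n_genotypes=150, sigma2_g=0.3,
            loadings_true=np.zeros((5, 2)), psi_true=np.zeros(5),
        )
        means, _ = simulate_adjusted_means(cfg)
        rep = select_gxe_model(means, role="target")
        assert rep.selected == "Id"
        assert not rep.discarded

    def test_target_prefers_fa2_otherwise(self):
        cfg = SimConfig(seed=15, n_genotypes=200, sigma2_g=0.0)
        means, _ = simulate_adjusted_means(cfg)
        rep = select_gxe_model(means, role="target")
        assert rep.selected == "FA2"

    def test_crossover_flag_for_mixed_sign_loadings(self):
        lam = np.array([[0.8], [0.6], [-0.7], [0.5], [-0.6]])  # crossover truth
        cfg = SimConfig(
            seed=16, n_genotypes=200, sigma2_g=0.0,
            loadings_true=lam, psi_true=np.full(5, 0.05), missing_fraction=0.0,
        )
        means, _ = simulate_adjusted_means(cfg)
        rep = select_gxe_model(means, role="intermediate")
        assert rep.crossover


def _report(trait, discarded, reason=""):
    return GxEModelReport(
        trait=trait, role="intermediate", candidates={}, selected="Id",
        crossover=False, discarded=discarded, reason=reason,
    )


class TestTraitScreening:
    def test_ancestor_discard_propagates(self):
        reports = {"LA_max": _report("LA_max", True, "complex GxE"), "t_LA_max": _report("t_LA_max", False)}
        kept, discarded = screen_intermediate_traits(reports, {"t_LA_max": "LA_max"})
        assert kept == []
        assert "ancestor" in discarded["t_LA_max"]

    def test_no_discards_keeps_all(self):
        reports = {t: _report(t, False) for t in ("a", "b", "c")}
        kept, discarded = screen_intermediate_traits(reports, {})
        assert sorted(kept) == ["a", "b", "c"] and discarded == {}

    def test_chain_of_three_with_middle_discarded(self):
        reports = {t: _report(t, t == "b") for t in ("a", "b", "c")}
        kept, discarded = screen_intermediate_traits(reports, {"b": "a", "c": "b"})
        assert kept == ["a"]
        assert set(discarded) == {"b", "c"}

    def test_cycle_rejected(self):
        reports = {t: _report(t, False) for t in ("a", "b")}
        with pytest.raises(ValueError, match="cycle"):
            screen_intermediate_traits(reports, {"a": "b", "b": "a"})
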