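"""Stage 2: across-year-site mixed-model analysis of adjusted means.

Works on stage-1 output (genotype x year-site BLUEs with weights
``w = 1/se^2``) and provides:

* overall genotype BLUPs and Cullis generalized heritability under a
  uniform (Id) or per-year-site (Diag) interaction variance;
* bivariate genetic correlations between traits, with the interaction and
  residual confounded into one unstructured 2x2 covariance;
* factor-analytic (reduced-rank + diagonal lack-of-fit) GxE models with
  one or two factors;
* the environment-correlation matrix implied by an FA fit;
* BIC-based model selection over {Id, Diag, FA1, FA2} with the
  trait-screening rule for intermediate traits (complex GxE -> discard,
  and discard status propagates to derived traits).

All candidate models are compared on full-likelihood BICs so that fits
with different fixed parts remain comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .remlcore import DiagStruct, FAStruct, IdStruct, MixedModelFit, RandomTerm, reml_fit

__all__ = [
    "FAFit",
    "GxEModelReport",
    "fit_overall",
    "heritability_cullis",
    "genetic_correlation",
    "fit_fa",
    "env_correlations",
    "select_gxe_model",
    "screen_intermediate_traits",
]


def _check_means(means: pd.DataFrame):
    req = {"year_site", "genotype", "blue", "weight"}
    missing = req - set(means.columns)
    if missing:
        raise ValueError(f"adjusted means lack columns: {sorted(missing)}")
    if means.duplicated(subset=["year_site", "genotype"]).any():
        raise ValueError("duplicate (year_site, genotype) rows in adjusted means")
    if (means["weight"] <= 0).any():
        raise ValueError("weights must be positive")


def _designs(means: pd.DataFrame):
    genotypes = sorted(means["genotype"].unique())
    sites = sorted(means["year_site"].unique())
    gi = means["genotype"].map({g: i for i, g in enumerate(genotypes)}).to_numpy()
    si = means["year_site"].map({s: j for j, s in enumerate(sites)}).to_numpy()
    n = len(means)
    # fixed: intercept + year-site contrasts (first site as reference)
    X = np.zeros((n, len(sites)))
    X[:, 0] = 1.0
    for j in range(1, len(sites)):
        X[si == j, j] = 1.0
    Zg = np.zeros((n, len(genotypes)))
    Zg[np.arange(n), gi] = 1.0
    Zc = np.eye(n)  # one interaction/lack-of-fit effect per observed cell
    return genotypes, sites, gi, si, X, Zg, Zc


def fit_overall(means: pd.DataFrame, gxe: str = "Diag", sigma2="free") -> MixedModelFit:
    """Overall genotype means model: genotype random (Id), genotype x
    year-site interaction random (Id or Diag per-site variances), weighted
    residual.  Year-site intercepts are fixed."""
    _check_means(means)
    if gxe not in ("Id", "Diag"):
        raise ValueError("gxe must be 'Id' or 'Diag'")
    means = means.reset_index(drop=True)
    genotypes, sites, gi, si, X, Zg, Zc = _designs(means)
    if len(sites) < 2:
        raise ValueError("at least two year-sites are required; interaction inestimable")
    if gxe == "Id":
        inter = IdStruct(Zc, "s2")
    else:
        inter = DiagStruct(Zc, [sites[j] for j in si], "s2")
    terms = [RandomTerm("genotype", IdStruct(Zg, "s2")), RandomTerm("interaction", inter)]
    fit = reml_fit(
        means["blue"].to_numpy(float),
        X,
        terms,
        weights=means["weight"].to_numpy(float),
        sigma2=sigma2,
        pev_terms=["genotype"],
    )
    fit.genotypes = genotypes
    fit.year_sites = sites
    return fit


def heritability_cullis(fit: MixedModelFit) -> float:
    """Generalized heritability H2 = 1 - vbar_delta / (2 s2g), where
    vbar_delta is the mean prediction-error variance of pairwise genotype
    BLUP differences.  Clipped to [0, 1]."""
    s2g = fit.variance_params.get("genotype.s2")
    if s2g is None or "genotype" not in fit.pev:
        raise ValueError("fit lacks a random genotype term with PEV")
    if s2g <= 1e-10:
        return 0.0
    C = fit.pev["genotype"]
    m = C.shape[0]
    d = np.diag(C)
    # mean over ordered pairs i != i' of C_ii + C_i'i' - 2 C_ii'
    vbar = (2 * m * d.sum() - 2 * C.sum()) / (m * (m - 1))
    return float(np.clip(1.0 - vbar / (2.0 * s2g), 0.0, 1.0))


# ---------------------------------------------------------------------------
# bivariate genetic correlation


def _chol_params_to_cov(xi):
    """(log l11, l21, log l22) -> SPD 2x2 matrix L L'."""
    l11, l21, l22 = np.exp(xi[0]), xi[1], np.exp(xi[2])
    L = np.array([[l11, 0.0], [l21, l22]])
    return L @ L.T


@dataclass
class BivariateFit:
    r_g: float | None
    reason: str
    genetic_cov: np.ndarray
    residual_cov: np.ndarray  # confounded interaction + residual
    loglik_reml: float
    converged: bool


def genetic_correlation(means_t1: pd.DataFrame, means_t2: pd.DataFrame) -> BivariateFit:
    """Genetic correlation between two traits from their year-site BLUEs.

    Bivariate mixed model with per-trait fixed intercepts and year-site
    effects, an unstructured 2x2 genotype covariance Sg, and an
    unstructured 2x2 covariance Sc for the confounded interaction +
    residual term.  Only cells observed for both traits enter.  Because
    genotypes share no random effects, the marginal covariance is block
    diagonal per genotype, V_i = Sg (x) J_{p_i} + Sc (x) I_{p_i}, which the
    REML likelihood exploits directly.

    r_g = Cov(g1, g2) / sqrt(Var(g1) Var(g2)); returned as None with a
    reason when either genetic variance vanishes.
    """
    for m_ in (means_t1, means_t2):
        _check_means(m_)
    merged = means_t1.merge(
        means_t2, on=["year_site", "genotype"], suffixes=("_1", "_2"), how="inner"
    )
    if merged["year_site"].nunique() < 2:
        raise ValueError("traits share fewer than two year-sites")
    if merged["genotype"].nunique() < 3:
        raise ValueError("traits share fewer than three genotypes")

    sites = sorted(merged["year_site"].unique())
    si = merged["year_site"].map({s: j for j, s in enumerate(sites)}).to_numpy()
    p_env = len(sites)
    Y = merged[["blue_1", "blue_2"]].to_numpy(float)

    # per-trait fixed design: intercept + site contrasts
    Xs = np.zeros((len(merged), p_env))
    Xs[:, 0] = 1.0
    for j in range(1, p_env):
        Xs[si == j, j] = 1.0

    gcodes, _ = pd.factorize(merged["genotype"], sort=True)
    m_gen = gcodes.max() + 1
    counts = np.bincount(gcodes, minlength=m_gen).astype(float)
    n_obs = 2 * len(merged)
    p_fixed = 2 * p_env

    # Sufficient statistics.  In the eigenbasis of each genotype block the
    # covariance splits into a 2x2 "genotype mean" block A_i = p_i Sg + Sc
    # and p_i - 1 copies of Sc on the within-genotype contrasts, so every
    # GLS quantity reduces to aggregates of per-genotype means and
    # within-genotype residuals, grouped by the distinct cell counts p_i.
    ybar = np.zeros((m_gen, 2))
    xbar = np.zeros((m_gen, p_env))
    np.add.at(ybar, gcodes, Y)
    np.add.at(xbar, gcodes, Xs)
    ybar /= counts[:, None]
    xbar /= counts[:, None]
    ry = Y - ybar[gcodes]
    rx = Xs - xbar[gcodes]
    Rxx = rx.T @ rx
    Rxy = rx.T @ ry  # p_env x 2
    Ryy = ry.T @ ry  # 2 x 2
    stats = {}
    for c in np.unique(counts):
        sel = counts == c
        xb, yb = xbar[sel], ybar[sel]
        stats[float(c)] = (
            xb.T @ xb,  # Sxx
            xb.T @ yb,  # Sxy (p_env x 2)
            yb.T @ yb,  # Syy (2 x 2)
            int(sel.sum()),
        )

    def neg_reml(xi):
        Sg = _chol_params_to_cov(xi[:3])
        Sc = _chol_params_to_cov(xi[3:])
        sign_c, ld_c = np.linalg.slogdet(Sc)
        if sign_c <= 0:
            return 1e10
        Sc_inv = np.linalg.inv(Sc)
        logdetV = float((counts - 1).sum() * ld_c)
        XtViX = np.kron(Sc_inv, Rxx)
        XtViy = (Rxy @ Sc_inv).T.reshape(-1)  # trait-major stacking
        ytViy = float(np.sum(Sc_inv * Ryy))
        for c, (Sxx, Sxy, Syy, n_g) in stats.items():
            A = c * Sg + Sc
            sign_a, ld_a = np.linalg.slogdet(A)
            if sign_a <= 0:
                return 1e10
            A_inv = np.linalg.inv(A)
            logdetV += n_g * ld_a
            XtViX += c * np.kron(A_inv, Sxx)
            XtViy += c * (Sxy @ A_inv).T.reshape(-1)
            ytViy += c * float(np.sum(A_inv * Syy))
        sign, ldx = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return 1e10
        beta = np.linalg.solve(XtViX, XtViy)
        qform = ytViy - XtViy @ beta
        ll = -0.5 * ((n_obs - p_fixed) * np.log(2 * np.pi) + logdetV + ldx + qform)
        return -ll if np.isfinite(ll) else 1e10

    v1, v2 = Y[:, 0].var(), Y[:, 1].var()
    x0 = np.array(
        [0.5 * np.log(max(v1 / 2, 1e-8)), 0.0, 0.5 * np.log(max(v2 / 2, 1e-8))] * 2
    )
    res = optimize.minimize(
        neg_reml, x0, method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-7},
    )
    Sg = _chol_params_to_cov(res.x[:3])
    Sc = _chol_params_to_cov(res.x[3:])
    converged = bool(res.success)
    if Sg[0, 0] <= 1e-8 * max(v1, 1e-12) or Sg[1, 1] <= 1e-8 * max(v2, 1e-12):
        return BivariateFit(None, "a genetic variance is ~0; r_g undefined", Sg, Sc, -res.fun, converged)
    r_g = float(Sg[0, 1] / np.sqrt(Sg[0, 0] * Sg[1, 1]))
    return BivariateFit(r_g, "", Sg, Sc, -res.fun, converged)


# ---------------------------------------------------------------------------
# factor-analytic models


@dataclass
class FAFit:
    """Factor-analytic GxE fit: loadings (p x k), specific variances psi,
    genotype scores (m x k BLUPs), environment intercepts and the
    underlying mixed-model fit."""

    trait: str
    genotypes: list
    year_sites: list
    loadings: np.ndarray
    specific_vars: np.ndarray
    scores: np.ndarray
    env_intercepts: np.ndarray
    overall_fit: MixedModelFit
    rotated: bool = False

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    def genetic_covariance(self) -> np.ndarray:
        return self.loadings @ self.loadings.T + np.diag(self.specific_vars)

    def fitted_gxe(self) -> np.ndarray:
        """m x p matrix of fitted common GxE effects Lambda F' (transposed)."""
        return self.scores @ self.loadings.T


def _fa_start(means: pd.DataFrame, genotypes, sites, k: int, struct: FAStruct):
    """Eigen-based warm start: factor part from the leading eigenpairs of
    the empirical across-environment covariance of cell means."""
    M = means.pivot_table(index="genotype", columns="year_site", values="blue")
    M = M.reindex(index=genotypes, columns=sites)
    M = M.fillna(M.mean(axis=0), axis=0) - M.mean(axis=0)
    S = np.cov(M.to_numpy(float), rowvar=False)
    w, U = np.linalg.eigh(S)
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    lam0 = U[:, :k] * np.sqrt(np.maximum(w[:k], 1e-4))[None, :]
    # rotate into the identified lower-triangular form via LQ
    q, r = np.linalg.qr(lam0.T)
    lam0 = r.T
    for l in range(k):
        if lam0[l, l] < 0:
            lam0[:, l] *= -1
    psi0 = np.maximum(np.diag(S) - np.diag(lam0 @ lam0.T), 0.05 * np.diag(S))
    psi0 = np.maximum(psi0, 1e-6)
    return struct.pack(lam0, psi0)


def fit_fa(means: pd.DataFrame, k_f: int, sigma2="free") -> FAFit:
    """Reduced-rank(k_f) + Diag lack-of-fit GxE model on adjusted means.

    The common GxE part is Lambda f_i (loadings per year-site, scores per
    genotype, identified by zero upper triangle in Lambda); the lack-of-fit
    term supplies per-year-site specific variances psi, so the implied
    genetic covariance across environments is Lambda Lambda' + diag(psi).
    There is no separate genotype main-effect term: a common positive
    loading direction plays that role.
    """
    _check_means(means)
    means = means.reset_index(drop=True)
    genotypes, sites, gi, si, X, Zg, Zc = _designs(means)
    p = len(sites)
    if k_f >= p:
        raise ValueError(f"k_f={k_f} not identifiable with p={p} year-sites")
    struct = FAStruct(si, gi, p=p, m=len(genotypes), k=k_f, name="fa")
    start = np.concatenate([_fa_start(means, genotypes, sites, k_f, struct), [np.log(0.5)]])
    if sigma2 != "free":
        start = start[:-1]
    fit = reml_fit(
        means["blue"].to_numpy(float),
        X,
        [RandomTerm("gxe", struct)],
        weights=means["weight"].to_numpy(float),
        sigma2=sigma2,
        start=start,
    )
    lam = np.zeros((p, k_f))
    psi = np.zeros(p)
    for j in range(p):
        psi[j] = fit.variance_params[f"gxe.fa.psi[{j}]"]
        for l in range(k_f):
            lam[j, l] = fit.variance_params[f"gxe.fa.lambda[{j},{l}]"]
    scores = fit.random_effects["gxe"].reshape(len(genotypes), k_f)
    env_int = np.copy(fit.fixed_estimates[:p])
    env_int[1:] += env_int[0]  # intercept + contrasts -> per-site means
    return FAFit(
        trait=str(means["trait"].iloc[0]) if "trait" in means else "",
        genotypes=genotypes,
        year_sites=sites,
        loadings=lam,
        specific_vars=psi,
        scores=scores,
        env_intercepts=env_int,
        overall_fit=fit,
    )


def env_correlations(fa: FAFit) -> pd.DataFrame:
    """Environment-correlation matrix implied by the FA covariance
    Lambda Lambda' + diag(psi), with unit diagonal."""
    if not fa.overall_fit.converged:
        raise ValueError("FA fit did not converge")
    G = fa.genetic_covariance()
    d = np.diag(G)
    if np.any(d <= 0):
        raise ValueError("zero diagonal entry in FA genetic covariance")
    C = G / np.sqrt(np.outer(d, d))
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=fa.year_sites, columns=fa.year_sites)


# ---------------------------------------------------------------------------
# model selection and trait screening


@dataclass
class GxEModelReport:
    trait: str
    role: str
    candidates: dict  # model id -> {"bic", "loglik_full", "converged"}
    selected: str
    crossover: bool
    discarded: bool
    reason: str = ""
    fits: dict = field(default_factory=dict)


def _first_factor_mixed_signs(fa: FAFit) -> bool:
    from .fast import rotate_loadings

    lam = rotate_loadings(fa).loadings[:, 0]
    return bool((lam > 1e-8).any() and (lam < -1e-8).any())


def select_gxe_model(means: pd.DataFrame, role: str = "intermediate", trait: str = "") -> GxEModelReport:
    """Fit Id, Diag, FA1 and FA2 to the same adjusted means and select by
    full-likelihood BIC among converged candidates.

    Intermediate traits with a BIC-minimal FA model are flagged as
    discarded (complex GxE makes them unreliable predictors).  For target
    traits an Id winner is kept; any other winner is replaced by FA2,
    which permits the performance/stability dissection.
    """
    if role not in ("intermediate", "target"):
        raise ValueError("role must be 'intermediate' or 'target'")
    trait = trait or (str(means["trait"].iloc[0]) if "trait" in means else "")
    candidates, fits = {}, {}
    for mid in ("Id", "Diag", "FA1", "FA2"):
        try:
            if mid in ("Id", "Diag"):
                fit = fit_overall(means, gxe=mid)
                fits[mid] = fit
            else:
                fa = fit_fa(means, k_f=int(mid[-1]))
                fit = fa.overall_fit
                fits[mid] = fa
            candidates[mid] = {
                "bic": fit.bic,
                "loglik_full": fit.loglik_full,
                "converged": fit.converged,
            }
        except (ValueError, np.linalg.LinAlgError) as exc:
            candidates[mid] = {"bic": np.nan, "loglik_full": np.nan, "converged": False}
    conv = {mid: c for mid, c in candidates.items() if c["converged"]}
    if not conv:
        raise RuntimeError(f"no GxE candidate model converged for trait {trait!r}")
    best = min(conv, key=lambda mid: conv[mid]["bic"])

    crossover = False
    fa_for_sign = None
    if best in ("FA1", "FA2"):
        fa_for_sign = fits[best]
    elif "FA1" in conv:
        fa_for_sign = fits.get("FA1")
    if fa_for_sign is not None:
        crossover = _first_factor_mixed_signs(fa_for_sign)

    if role == "intermediate":
        discarded = best in ("FA1", "FA2")
        reason = f"BIC-minimal model {best} indicates complex GxE" if discarded else ""
        selected = best
    else:
        discarded = False
        reason = ""
        if best == "Id":
            selected = "Id"
        else:
            selected = "FA2" if candidates["FA2"]["converged"] else best
    return GxEModelReport(
        trait=trait,
        role=role,
        candidates=candidates,
        selected=selected,
        crossover=crossover,
        discarded=discarded,
        reason=reason,
        fits=fits,
    )


def screen_intermediate_traits(reports: dict, derivations: dict | None = None):
    """Propagate discard decisions through trait derivations.

    ``derivations`` maps a trait to the trait it is computed from; a trait
    is discarded when its own report discards it or any ancestor is
    discarded.  Returns ``(kept, discarded)`` where ``discarded`` maps
    trait -> reason.
    """
    derivations = derivations or {}
    # cycle check
    for start in derivations:
        seen, node = {start}, derivations.get(start)
        while node is not None:
            if node in seen:
                raise ValueError(f"cycle in trait derivations at {node!r}")
            seen.add(node)
            node = derivations.get(node)

    discarded = {}

    def is_discarded(trait):
        if trait in discarded:
            return True
        rep = reports.get(trait)
        if rep is not None and rep.discarded:
            discarded[trait] = rep.reason or "complex GxE"
            return True
        parent = derivations.get(trait)
        if parent is not None and is_discarded(parent):
            discarded[trait] = f"ancestor trait {parent!r} discarded"
            return True
        return False

    kept = [t for t in reports if not is_discarded(t)]
    return kept, discarded
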