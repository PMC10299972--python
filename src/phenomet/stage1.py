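"""Stage 1: per-year-site spatial analysis of plot data.

Model per year-site and trait:

    value_k = genotype_(i(k)) + f(x_k, y_k) + row_(r(k)) + col_(c(k)) + e_k,
    var(e_k) = sigma2 / w_k,   w_k = 1 / se_k^2

with f a smooth bivariate surface represented as a tensor-product cubic
B-spline with second-order difference penalties in mixed-model form (the
penalty null space — the bilinear polynomial — enters the fixed part, the
penalized complement enters as an iid random term after whitening by the
penalty eigenvalues).  Row and column numbers get independent iid random
effects.

Two modes:

* ``BLUE`` — genotype fixed; yields adjusted means with SEs from the
  fixed-effect covariance diagonal and stage-2 weights ``w = 1/se^2``.
* ``repeatability`` — genotype random; the Oakey-style generalized
  repeatability is computed from the genotype prediction-error-variance
  matrix on the mean-centered contrast space (the direction confounded
  with the trial mean carries no information about genotype differences
  and is removed before averaging).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .remlcore import IdStruct, MixedModelFit, RandomTerm, reml_fit

__all__ = ["Stage1Fit", "fit_stage1", "stage1_blues", "repeatability_oakey"]


def _bspline_basis(v: np.ndarray, n_inner: int, degree: int = 3) -> np.ndarray:
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        hi = lo + 1.0
    inner = np.linspace(lo, hi, n_inner)
    knots = np.concatenate([np.full(degree, lo), inner, np.full(degree, hi)])
    B = BSpline.design_matrix(np.clip(v, lo, hi), knots, degree).toarray()
    return B


def _difference_penalty(K: int, order: int = 2) -> np.ndarray:
    D = np.diff(np.eye(K), n=order, axis=0)
    return D.T @ D


def tensor_spline_parts(x: np.ndarray, y: np.ndarray, max_knots: int = 20):
    """Mixed-model decomposition of a penalized tensor-product surface.

    Returns ``(X_poly, Z_smooth)``: centered bilinear fixed columns
    [x, y, x*y] and the whitened, column-centered random smooth basis.
    Knot density is one inner knot per two distinct coordinate values,
    capped at ``max_knots``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nkx = int(np.clip(len(np.unique(x)) // 2, 4, max_knots))
    nky = int(np.clip(len(np.unique(y)) // 2, 4, max_knots))
    Bx = _bspline_basis(x, nkx)
    By = _bspline_basis(y, nky)
    Kx, Ky = Bx.shape[1], By.shape[1]
    B = (Bx[:, :, None] * By[:, None, :]).reshape(len(x), Kx * Ky)
    P = np.kron(_difference_penalty(Kx), np.eye(Ky)) + np.kron(np.eye(Kx), _difference_penalty(Ky))
    w, U = np.linalg.eigh(P)
    keep = w > 1e-8 * w.max()
    Z = B @ (U[:, keep] / np.sqrt(w[keep])[None, :])
    Z -= Z.mean(axis=0, keepdims=True)
    xc, yc = x - x.mean(), y - y.mean()
    X_poly = np.column_stack([xc, yc, xc * yc])
    return X_poly, Z


@dataclass
class Stage1Fit:
    year_site: str
    trait: str
    mode: str  # "BLUE" or "repeatability"
    genotypes: list
    fit: MixedModelFit
    surface_values: np.ndarray  # fitted smooth surface at plot coordinates
    n_fixed_poly: int

    @property
    def sigma2_e(self) -> float:
        return self.fit.sigma2

    def genotype_effects(self) -> pd.Series:
        if self.mode == "BLUE":
            vals = self.fit.fixed_estimates[: len(self.genotypes)]
        else:
            vals = self.fit.random_effects["genotype"]
        return pd.Series(vals, index=self.genotypes)

    def row_effects(self) -> np.ndarray:
        return self.fit.random_effects.get("row", np.empty(0))

    def col_effects(self) -> np.ndarray:
        return self.fit.random_effects.get("col", np.empty(0))


def fit_stage1(plots: pd.DataFrame, mode: str = "BLUE", max_knots: int = 20) -> Stage1Fit:
    """Fit the stage-1 spatial model to one year-site's plots of one trait."""
    if mode not in ("BLUE", "repeatability"):
        raise ValueError("mode must be 'BLUE' or 'repeatability'")
    required = {"year_site", "genotype", "row", "col", "x", "y", "trait", "value", "se"}
    missing = required - set(plots.columns)
    if missing:
        raise ValueError(f"plot table lacks columns: {sorted(missing)}")
    if plots["year_site"].nunique() != 1 or plots["trait"].nunique() != 1:
        raise ValueError("fit_stage1 expects plots of a single year-site and trait")
    if plots.duplicated(subset=["row", "col"]).any():
        raise ValueError("duplicate (row, col) plot records in year-site")
    if (plots["se"] <= 0).any():
        raise ValueError("plot SEs must be positive")

    plots = plots.reset_index(drop=True)
    genotypes = sorted(plots["genotype"].unique())
    g_idx = plots["genotype"].map({g: i for i, g in enumerate(genotypes)}).to_numpy()
    reps_per_geno = plots.groupby("genotype").size()
    if mode == "repeatability" and reps_per_geno.max() < 2:
        raise ValueError("repeatability needs replicated genotypes; all have a single plot")

    y = plots["value"].to_numpy(float)
    w = 1.0 / plots["se"].to_numpy(float) ** 2
    Zg = np.zeros((len(plots), len(genotypes)))
    Zg[np.arange(len(plots)), g_idx] = 1.0

    X_poly, Z_smooth = tensor_spline_parts(plots["x"].to_numpy(float), plots["y"].to_numpy(float), max_knots)

    def indicator(labels):
        codes, uniq = pd.factorize(labels, sort=True)
        Z = np.zeros((len(codes), len(uniq)))
        Z[np.arange(len(codes)), codes] = 1.0
        return Z

    Zr = indicator(plots["row"])
    Zc = indicator(plots["col"])
    terms = [
        RandomTerm("surface", IdStruct(Z_smooth, "s2")),
        RandomTerm("row", IdStruct(Zr, "s2")),
        RandomTerm("col", IdStruct(Zc, "s2")),
    ]
    if mode == "BLUE":
        X = np.hstack([Zg, X_poly])
        fit = reml_fit(y, X, terms, weights=w)
        n_poly = X_poly.shape[1]
    else:
        X = np.hstack([np.ones((len(plots), 1)), X_poly])
        terms = [RandomTerm("genotype", IdStruct(Zg, "s2"))] + terms
        fit = reml_fit(y, X, terms, weights=w, pev_terms=["genotype"])
        n_poly = X_poly.shape[1]

    # IdStruct BLUPs are on the natural scale u = sqrt(s2) a while the factor
    # columns already carry sqrt(s2), so fitted surface = Z_white @ a
    s2s = fit.variance_params["surface.s2"]
    fitted_surface = Z_smooth @ (fit.random_effects["surface"] / np.sqrt(s2s)) if s2s > 0 else np.zeros(len(y))

    return Stage1Fit(
        year_site=str(plots["year_site"].iloc[0]),
        trait=str(plots["trait"].iloc[0]),
        mode=mode,
        genotypes=genotypes,
        fit=fit,
        surface_values=fitted_surface,
        n_fixed_poly=n_poly,
    )


def stage1_blues(s1: Stage1Fit) -> pd.DataFrame:
    """Adjusted genotype means (BLUEs) with SEs and stage-2 weights."""
    if s1.mode != "BLUE":
        raise ValueError("stage1_blues requires a fit with mode='BLUE'")
    m = len(s1.genotypes)
    blue = s1.fit.fixed_estimates[:m]
    se = np.sqrt(np.diag(s1.fit.fixed_cov)[:m])
    return pd.DataFrame(
        {
            "year_site": s1.year_site,
            "genotype": s1.genotypes,
            "trait": s1.trait,
            "blue": blue,
            "se": se,
            "weight": 1.0 / se**2,
        }
    )


def repeatability_oakey(s1: Stage1Fit, variant: str = "mean") -> float:
    """Generalized within-year-site repeatability from genotype BLUP PEV.

    ``variant='mean'`` (default): h2 = 1 - tr(Q C Q) / ((m-1) s2g) with C
    the genotype PEV matrix and Q the centering projector — the mean PEV of
    genotype contrasts relative to the genetic variance.  ``'eigen'``
    averages the nonzero eigenvalues of I - C/s2g instead; the two agree on
    balanced designs.
    """
    if s1.mode != "repeatability":
        raise ValueError("repeatability requires a fit with mode='repeatability'")
    if not s1.fit.converged:
        raise ValueError("stage-1 fit did not converge")
    s2g = s1.fit.variance_params["genotype.s2"]
    if s2g <= 1e-10:
        return 0.0
    C = s1.fit.pev["genotype"]
    m = C.shape[0]
    if variant == "mean":
        tr_centered = np.trace(C) - C.sum() / m
        h2 = 1.0 - tr_centered / ((m - 1) * s2g)
    elif variant == "eigen":
        lam = np.linalg.eigvalsh(np.eye(m) - C / s2g)
        lam = np.sort(lam)[1:]  # drop the mean-confounded (smallest) one
        h2 = float(np.mean(lam))
    else:
        raise ValueError("variant must be 'mean' or 'eigen'")
    return float(np.clip(h2, 0.0, 1.0))
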