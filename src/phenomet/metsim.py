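"""Synthetic multi-environment-trial (MET) generator with known ground truth.

Emulates the structure of an elite winter-wheat variety-testing series: a
few dozen genotypes grown with replication in a handful of year-site
combinations, on row/column field grids with smooth spatial trend, row and
column effects, heteroscedastic plot errors with reported standard errors,
a factor-analytic genotype-by-environment (GxE) covariance across
year-sites, correlated secondary (high-throughput phenotyping) traits
linked to the target traits, and ordinal breeder selection decisions.

Every stochastic draw is governed by ``SimConfig.seed``; identical configs
produce identical tables, so downstream estimators can be tested against
the stored truth.

The default configuration mirrors the trial series the pipeline is
meant for: 45 genotypes, 5 year-sites, 4 replicates, 20% of genotypes
missing per year-site, and a rank-2 GxE covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "YearSite",
    "TraitLink",
    "SimConfig",
    "SimTruth",
    "simulate_met",
    "simulate_adjusted_means",
    "simulate_features",
    "simulate_trait_pair",
    "simulate_decisions",
    "gdd",
    "true_op_rmsd",
]

DECISION_LABELS = ["discarded", "sister_repeated", "repeated", "sister_selected", "selected"]


@dataclass
class YearSite:
    name: str
    n_rows: int = 18
    n_cols: int = 10
    n_reps: int = 4


@dataclass
class TraitLink:
    """Secondary trait generated as ``coef * g_target + own genetic + noise``."""

    coef: float
    genetic_var: float = 0.5
    error_var: float = 0.25


def _default_year_sites():
    return [YearSite(n) for n in ["SiteA_2019", "SiteB_2019", "SiteC_2019", "SiteA_2020", "SiteB_2020"]]


def _default_loadings():
    # 5 environments x 2 factors; first factor dominant and all-positive
    # (non-crossover), second factor mixed-sign.
    return np.array(
        [
            [0.55, 0.20],
            [0.60, -0.15],
            [0.50, 0.25],
            [0.65, -0.20],
            [0.45, 0.10],
        ]
    )


def _default_trait_links():
    return {
        "n_tiller": TraitLink(0.8, 0.4, 0.2),
        "PH_max": TraitLink(0.5, 0.6, 0.2),
        "t_PH_start": TraitLink(-0.4, 0.7, 0.3),
    }


@dataclass
class SimConfig:
    """Ground-truth parameters of the synthetic MET.

    Variances are on the trait scale (t/ha for a yield-like trait).  The
    reported plot SE is ``sqrt(sigma2_e)`` jittered by a lognormal factor
    with log-sd ``se_lognorm_sd`` so that weights ``w = 1/SE^2`` are
    genuinely heterogeneous.
    """

    n_genotypes: int = 45
    year_sites: list = field(default_factory=_default_year_sites)
    sigma2_g: float = 0.25
    loadings_true: np.ndarray = field(default_factory=_default_loadings)
    psi_true: np.ndarray = field(default_factory=lambda: np.full(5, 0.05))
    mu: float = 6.0
    env_effect_sd: float = 0.8
    sigma2_spatial: float = 0.15
    sigma2_row: float = 0.05
    sigma2_col: float = 0.05
    sigma2_e: float = 0.20
    se_lognorm_sd: float = 0.25
    trait_links: dict = field(default_factory=_default_trait_links)
    protein_link: float = -0.6
    protein_mu: float = 13.0
    protein_genetic_var: float = 0.4
    missing_fraction: float = 0.2
    # breeder decision model: latent = w_op * z(OP) - w_rmsd * z(RMSD) + noise
    decision_weights: tuple = (1.0, 0.5)
    decision_noise_sd: float = 0.5
    decision_thresholds: tuple = (-1.0, -0.3, 0.4, 1.1)
    trait: str = "yield"
    seed: int = 0

    def __post_init__(self):
        self.loadings_true = np.atleast_2d(np.asarray(self.loadings_true, dtype=float))
        self.psi_true = np.asarray(self.psi_true, dtype=float)
        p, k = self.loadings_true.shape
        if p != len(self.year_sites):
            raise ValueError("loadings_true must have one row per year-site")
        if p < 2:
            raise ValueError("at least two year-sites are required")
        if k > 2:
            raise ValueError("at most two GxE factors are supported")
        if len(self.psi_true) != p:
            raise ValueError("psi_true must have one entry per year-site")
        if np.any(self.psi_true < 0):
            raise ValueError("specific variances must be non-negative")
        for v in (self.sigma2_g, self.sigma2_spatial, self.sigma2_row, self.sigma2_col, self.sigma2_e):
            if v < 0:
                raise ValueError("variances must be non-negative")


@dataclass
class SimTruth:
    """True effects behind one simulated MET, keyed like the output tables."""

    genotypes: list
    year_site_names: list
    genotype_values: np.ndarray  # main effects g_i
    scores_true: np.ndarray  # m x k factor scores
    env_effects: np.ndarray  # year-site intercepts u_j (incl. global mean)
    lack_of_fit: np.ndarray  # m x p specific draws delta_ij
    cell_values: np.ndarray  # m x p: u_j + g_i + lambda_j' f_i + delta_ij
    present: np.ndarray  # m x p bool, genotype observed in year-site
    protein_values: np.ndarray  # genotype-level true protein (%)
    decision_latent: np.ndarray | None = None

    def cell_frame(self) -> pd.DataFrame:
        recs = []
        for i, g in enumerate(self.genotypes):
            for j, ys in enumerate(self.year_site_names):
                recs.append((ys, g, self.cell_values[i, j], bool(self.present[i, j])))
        return pd.DataFrame(recs, columns=["year_site", "genotype", "true_value", "present"])


def _rotate_principal(lam: np.ndarray, scores: np.ndarray):
    """Principal-axis rotation (shared with the FAST module's convention)."""
    U, s, Vt = np.linalg.svd(lam, full_matrices=False)
    lam_rot = U * s
    scores_rot = scores @ Vt.T
    for l in range(lam_rot.shape[1]):
        if lam_rot[:, l].sum() < 0:
            lam_rot[:, l] *= -1
            scores_rot[:, l] *= -1
    return lam_rot, scores_rot


def true_op_rmsd(truth: SimTruth, config: SimConfig):
    """Ground-truth overall performance and stability per genotype.

    OP is on the trait scale (grand mean + env mean + genotype main effect
    + first-factor regression); RMSD averages squared higher-factor
    contributions over the p year-sites.
    """
    lam_rot, f_rot = _rotate_principal(config.loadings_true, truth.scores_true)
    lam1_bar = lam_rot[:, 0].mean()
    op = truth.env_effects.mean() + truth.genotype_values + lam1_bar * f_rot[:, 0]
    if lam_rot.shape[1] > 1:
        dev = f_rot[:, 1:] @ lam_rot[:, 1:].T  # m x p
        rmsd = np.sqrt((dev**2).mean(axis=1))
    else:
        rmsd = np.zeros(len(op))
    return op, rmsd


def _draw_truth(config: SimConfig, rng: np.random.Generator) -> SimTruth:
    m = config.n_genotypes
    p = len(config.year_sites)
    k = config.loadings_true.shape[1]
    genotypes = [f"G{i + 1:03d}" for i in range(m)]
    g = rng.normal(0.0, np.sqrt(config.sigma2_g), size=m)
    f = rng.normal(0.0, 1.0, size=(m, k))
    u = config.mu + rng.normal(0.0, config.env_effect_sd, size=p)
    delta = rng.normal(0.0, np.sqrt(config.psi_true)[None, :], size=(m, p))
    cells = u[None, :] + g[:, None] + f @ config.loadings_true.T + delta

    present = np.ones((m, p), dtype=bool)
    n_drop = int(round(config.missing_fraction * m))
    for j in range(p):
        if n_drop > 0:
            drop = rng.choice(m, size=n_drop, replace=False)
            present[drop, j] = False

    protein = config.protein_mu + config.protein_link * g + rng.normal(
        0.0, np.sqrt(config.protein_genetic_var), size=m
    )
    return SimTruth(
        genotypes=genotypes,
        year_site_names=[ys.name for ys in config.year_sites],
        genotype_values=g,
        scores_true=f,
        env_effects=u,
        lack_of_fit=delta,
        cell_values=cells,
        present=present,
        protein_values=protein,
    )


def _spatial_surface(xx: np.ndarray, yy: np.ndarray, sigma2: float, rng: np.random.Generator):
    """Smooth low-order trend: random combination of sinusoid products,
    rescaled to the requested empirical variance over the plots."""
    if sigma2 <= 0:
        return np.zeros_like(xx, dtype=float)
    lx = xx.max() - xx.min() + 1.0
    ly = yy.max() - yy.min() + 1.0
    surf = np.zeros_like(xx, dtype=float)
    for fx in (0.5, 1.0):
        for fy in (0.5, 1.0):
            a, b = rng.normal(size=2)
            surf += a * np.sin(2 * np.pi * fx * xx / lx) * np.cos(2 * np.pi * fy * yy / ly)
            surf += b * np.cos(2 * np.pi * fx * xx / lx) * np.sin(2 * np.pi * fy * yy / ly)
    surf -= surf.mean()
    sd = surf.std()
    if sd > 0:
        surf *= np.sqrt(sigma2) / sd
    return surf


def simulate_met(config: SimConfig):
    """Generate plot-level records for the target trait in every year-site.

    Returns ``(plots, truth)`` where ``plots`` is a long-format table with
    columns year_site, genotype, row, col, x, y, replicate, trait, value,
    se — one row per plot — and ``truth`` stores every true effect.

    Plot value = cell value + spatial surface + row effect + column effect
    + N(0, se^2) noise, with the reported ``se`` drawn from the SE model
    (sqrt(sigma2_e) times a lognormal factor).
    """
    rng = np.random.default_rng(config.seed)
    truth = _draw_truth(config, rng)
    m = config.n_genotypes

    records = []
    for j, ys in enumerate(config.year_sites):
        idx_present = np.flatnonzero(truth.present[:, j])
        n_plots = len(idx_present) * ys.n_reps
        if n_plots > ys.n_rows * ys.n_cols:
            raise ValueError(
                f"{ys.name}: grid {ys.n_rows}x{ys.n_cols} too small for "
                f"{len(idx_present)} genotypes x {ys.n_reps} reps"
            )
        rows, cols = np.unravel_index(np.arange(n_plots), (ys.n_rows, ys.n_cols))
        xx = cols.astype(float)
        yy = rows.astype(float)
        surf = _spatial_surface(xx, yy, config.sigma2_spatial, rng)
        row_eff = rng.normal(0.0, np.sqrt(config.sigma2_row), size=ys.n_rows)
        col_eff = rng.normal(0.0, np.sqrt(config.sigma2_col), size=ys.n_cols)
        # randomized complete blocks: one shuffled copy of the genotype set per rep
        order = np.concatenate([rng.permutation(idx_present) for _ in range(ys.n_reps)])
        rep_of_plot = np.repeat(np.arange(1, ys.n_reps + 1), len(idx_present))
        se = np.sqrt(config.sigma2_e) * rng.lognormal(0.0, config.se_lognorm_sd, size=n_plots)
        noise = rng.normal(0.0, se)
        vals = truth.cell_values[order, j] + surf + row_eff[rows] + col_eff[cols] + noise
        for t in range(n_plots):
            records.append(
                (
                    ys.name,
                    truth.genotypes[order[t]],
                    int(rows[t]),
                    int(cols[t]),
                    float(xx[t]),
                    float(yy[t]),
                    int(rep_of_plot[t]),
                    config.trait,
                    float(vals[t]),
                    float(se[t]),
                )
            )
    plots = pd.DataFrame(
        records,
        columns=["year_site", "genotype", "row", "col", "x", "y", "replicate", "trait", "value", "se"],
    )
    return plots, truth


def simulate_adjusted_means(config: SimConfig, truth: SimTruth | None = None, se_mean: float = 0.12):
    """Generate stage-2 input directly: genotype x year-site BLUEs with SEs.

    Emulates the output of a stage-1 analysis without simulating plots:
    blue = true cell value + N(0, se^2) with heterogeneous reported SEs.
    Useful for fast tests of the across-year-site models.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    if truth is None:
        truth = _draw_truth(config, np.random.default_rng(config.seed))
    recs = []
    for j, ysn in enumerate(truth.year_site_names):
        for i in np.flatnonzero(truth.present[:, j]):
            se = se_mean * float(rng.lognormal(0.0, config.se_lognorm_sd))
            blue = truth.cell_values[i, j] + rng.normal(0.0, se)
            recs.append((ysn, truth.genotypes[i], config.trait, blue, se, 1.0 / se**2))
    means = pd.DataFrame(recs, columns=["year_site", "genotype", "trait", "blue", "se", "weight"])
    return means, truth


def simulate_features(config: SimConfig, truth: SimTruth, se: float = 0.15):
    """Genotype x year-site table of secondary-trait BLUEs linked to the
    target trait's genotype values, plus the target BLUE and protein.

    Each secondary trait t is ``coef_t * g_i + own genetic + noise`` with
    environment shifts, giving realistically imperfect predictors.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    m = config.n_genotypes
    p = len(truth.year_site_names)
    own = {
        name: rng.normal(0.0, np.sqrt(link.genetic_var), size=m)
        for name, link in config.trait_links.items()
    }
    env_shift = {name: rng.normal(0.0, 0.3, size=p) for name in config.trait_links}
    recs = []
    for j, ysn in enumerate(truth.year_site_names):
        for i in np.flatnonzero(truth.present[:, j]):
            row = {
                "year_site": ysn,
                "genotype": truth.genotypes[i],
                config.trait: truth.cell_values[i, j] + rng.normal(0.0, se),
                "protein": truth.protein_values[i] + rng.normal(0.0, se),
            }
            for name, link in config.trait_links.items():
                row[name] = (
                    link.coef * truth.genotype_values[i]
                    + own[name][i]
                    + env_shift[name][j]
                    + rng.normal(0.0, np.sqrt(link.error_var))
                )
            recs.append(row)
    return pd.DataFrame(recs)


def simulate_trait_pair(
    config: SimConfig,
    r_g: float,
    genetic_sd: tuple = (1.0, 1.0),
    noise_sd: float = 0.4,
    se_mean: float = 0.12,
):
    """Adjusted-means tables for two traits with a known genetic correlation.

    Genotype effects are bivariate normal with correlation ``r_g``; each
    trait adds year-site intercepts and independent interaction+residual
    noise (sd ``noise_sd``), giving the generative model the bivariate
    stage-2 analysis assumes.  Returns ``(means_1, means_2)``.
    """
    if not -1.0 <= r_g <= 1.0:
        raise ValueError("r_g must lie in [-1, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 41]))
    m = config.n_genotypes
    p = len(config.year_sites)
    s1, s2 = genetic_sd
    cov = np.array([[s1**2, r_g * s1 * s2], [r_g * s1 * s2, s2**2]])
    g = rng.multivariate_normal(np.zeros(2), cov, size=m)
    u = config.mu + rng.normal(0.0, config.env_effect_sd, size=(2, p))
    genotypes = [f"G{i + 1:03d}" for i in range(m)]
    frames = []
    for t in range(2):
        recs = []
        for j, ys in enumerate(config.year_sites):
            for i in range(m):
                se = se_mean * float(rng.lognormal(0.0, config.se_lognorm_sd))
                val = g[i, t] + u[t, j] + rng.normal(0.0, noise_sd)
                recs.append((ys.name, genotypes[i], f"trait{t + 1}", val, se, 1.0 / se**2))
        frames.append(
            pd.DataFrame(recs, columns=["year_site", "genotype", "trait", "blue", "se", "weight"])
        )
    return frames[0], frames[1]


def simulate_decisions(truth: SimTruth, config: SimConfig) -> dict:
    """Ordinal breeder decisions from a latent performance/stability index.

    latent_i = w_op * z(OP_i) - w_rmsd * z(RMSD_i) + N(0, noise_sd), cut at
    ``decision_thresholds`` (ascending) into the five-level scale
    discarded < sister repeated < repeated < sister selected < selected.
    The latent values are stored on ``truth.decision_latent``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 29]))
    op, rmsd = true_op_rmsd(truth, config)

    def z(v):
        s = v.std()
        return (v - v.mean()) / s if s > 0 else v * 0.0

    w_op, w_rmsd = config.decision_weights
    latent = w_op * z(op) - w_rmsd * z(rmsd) + rng.normal(0.0, config.decision_noise_sd, size=len(op))
    truth.decision_latent = latent
    thresholds = np.asarray(config.decision_thresholds, dtype=float)
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("decision thresholds must be strictly increasing")
    idx = np.searchsorted(thresholds, latent, side="right")
    return {g: DECISION_LABELS[i] for g, i in zip(truth.genotypes, idx)}


def gdd(hourly_temps: pd.Series, t_base: float = 0.0) -> pd.Series:
    """Cumulative growing degree days from an hourly temperature series.

    Daily mean temperature minus ``t_base``, clamped at zero, cumulatively
    summed (units degC * day).  The index must be a DatetimeIndex without
    duplicate timestamps.
    """
    if len(hourly_temps) == 0:
        raise ValueError("empty temperature series")
    if not isinstance(hourly_temps.index, pd.DatetimeIndex):
        raise TypeError("hourly_temps must have a DatetimeIndex")
    if hourly_temps.index.has_duplicates:
        raise ValueError("duplicate timestamps in temperature series")
    daily = hourly_temps.resample("1D").mean().dropna()
    return (daily - t_base).clip(lower=0.0).cumsum()
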