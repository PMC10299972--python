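# Methods

This note documents the statistical models, the numerical choices, the
synthetic-data generator and the known limitations of `phenomet`.

## REML engine (`remlcore`)

The engine fits y = Xβ + Σ_t Z_t u_t + e with var(e) = σ²W⁻¹ by
restricted maximum likelihood. Covariance structures:

* **Id** — u ~ N(0, s²I); one parameter (log s²).
* **Diag** — one variance per group of levels (e.g. per year-site for the
  interaction term); parameters log s²_g.
* **RR + Diag (factor-analytic)** — environment-indexed genotype effects
  with per-genotype covariance ΛΛ' + diag(ψ), Λ a p×k loading matrix
  identified by zeros in its upper triangle (k(k−1)/2 constraints), ψ
  per-environment specific variances. The reduced-rank part enters the
  likelihood as factor columns carrying genotype scores with unit prior
  variance; ψ is absorbed on the residual diagonal because each cell is
  observed at most once.

Likelihood evaluations use the Woodbury identity. Terms whose design is a
one-hot row indicator with unique columns contribute only to the diagonal;
remaining factor columns form the capacitance matrix C = I + FᵀD⁻¹F. In
all stage-2 models the factor columns partition by genotype, so C is block
diagonal with k×k blocks and one evaluation costs O(nk²); the dense path
(used by stage 1, where the spline basis shares rows across columns) was
verified equal to the blocked path and to an explicit dense-V oracle.

Optimization: L-BFGS-B on log variances / free loadings, ftol 1e−13,
followed by a central-difference polish (forward-difference gradient noise
otherwise limits parameter accuracy to ~1e−5 relative; the acceptance
oracle requires 1e−6). When line searches abort with parameters at the
variance floor (exp(−34.5) ≈ 1e−15, the effective zero), optimality is
certified directly: a fit is flagged converged only if no ±10% coordinate
step improves the objective. Negative variance estimates are therefore
represented as the floor, not as signed values; for the stage-2 interaction
term this clamps what unconstrained REML would estimate as negative, which
is also what keeps all downstream covariances positive semidefinite.

Model comparison uses the full Gaussian log-likelihood evaluated at the
REML variance estimates and GLS fixed effects (the information-criterion
construction for REML fits), with
BIC = −2·loglik_full + n_params·log(n_obs) and n_params counting variance
parameters plus fixed coefficients; n_obs is the number of observations.
Only the model *ranking* is meaningful; the magnitudes depend on
likelihood constants.

## Stage 1 (`stage1`)

Per year-site and trait: genotype + smooth bivariate surface + random row
and column effects + weighted residual (w = 1/SE² from the reported plot
SEs). The surface is a tensor-product cubic B-spline (one inner knot per
two distinct coordinate values, capped at 20 per axis) with second-order
difference penalties, brought to mixed-model form by eigendecomposition of
the penalty: the null space (bilinear polynomial, centered) joins the
fixed part, the whitened complement becomes an iid random term with a
single smoothing variance. Columns are centered so the fitted surface has
mean zero over the trial.

BLUE mode reports genotype SEs from the fixed-effect covariance diagonal
(the vcov-diagonal convention; pairwise-contrast SEs are not used) and
stage-2 weights 1/SE². Repeatability mode computes the generalized
repeatability from the genotype PEV matrix **on the genotype-contrast
space**: h² = 1 − tr(QCQ)/((m−1)σ̂²_g) with Q the centering projector.
The centering matters: the raw PEV diagonal contains the fixed-intercept
uncertainty, which inflates v̄ and (on the balanced one-way toy) would
give 0.625 where the plot-basis value is σ²g/(σ²g+σ²e/r) = 0.9375. An
eigenvalue variant (mean of the nonzero eigenvalues of I − C/σ̂²_g) is
available behind a flag; the two agree on balanced designs.

Null behaviour worth knowing: with σ²_g = 0 the positive-part REML
fluctuation makes the estimated repeatability of order √(2/m) per trial,
independent of the noise level — near-zero repeatabilities on ~45
genotypes are only meaningful on average, not per trial.

Traits measured at genotype level only (e.g. grain protein from merged
probes) skip stage 1 and enter stage 2 with unit weights.

## Stage 2 (`stage2`)

Overall model: fixed intercept + year-site effects, random genotype (Id),
random interaction (Id or Diag), residual σ²w⁻¹ with w from stage 1
(diagonal of the stage-1 vcov only; off-diagonals are deliberately not
propagated). σ² is freely estimated by default; `sigma2=1.0` gives the
fixed-residual two-stage convention.

Cullis heritability: H² = 1 − v̄_Δ/(2σ̂²_g) with v̄_Δ the mean PEV of
pairwise genotype BLUP differences (immune to the intercept term),
clipped to [0, 1].

Genetic correlation: bivariate model on complete (genotype, year-site)
cases with per-trait fixed intercept + year-site effects, unstructured
2×2 genotype covariance Σ_g and one unstructured 2×2 covariance Σ_c for
the confounded interaction + residual. Because the two traits share
random effects only at genotype level, the marginal covariance is block
diagonal per genotype, V_i = Σ_g⊗J + Σ_c⊗I; the implementation reduces
the REML likelihood to sufficient statistics (per-genotype means and
within-genotype residuals grouped by cell count), making a fit at 500
genotypes take well under a second. Stage-1 weights are not used here —
the combined term is homoscedastic, consistent with confounding e and
(θu) into one structure. r_g = Σ_g,12/√(Σ_g,11 Σ_g,22); returned as
missing with a reason when a genetic variance collapses.

FA models: reduced-rank RR(k) + Diag lack-of-fit, k ∈ {1, 2} (five
environments admit at most two factors; k is validated against the
identifiability bound pk − k(k−1)/2 + p ≤ p(p+1)/2). Warm starts come
from the eigendecomposition of the empirical across-environment
covariance of cell means, rotated into the identified triangular form;
ψ starts at the residual diagonal floored at 5% of the total. Scores are
BLUPs; environment correlations are the correlation matrix of ΛΛ'+diag(ψ).

Model selection fits {Id, Diag, FA1, FA2} on the same means and picks the
BIC minimum among converged fits (non-convergence is recorded, not
silently dropped). Intermediate traits with an FA winner are discarded
(complex G×E disqualifies them as environment-robust predictors) and the
discard propagates through the trait-derivation graph; target traits keep
an Id winner and otherwise take FA2, which enables the OP/RMSD
dissection. The crossover flag reports mixed signs in the first rotated
factor. Power at realistic trial sizes is limited: with ~45 genotypes the
BIC often prefers Id even under genuine two-factor truth; the selection-
power guarantees are stated at 200 genotypes.

## FAST (`fast`)

Loadings are rotated to principal-axis form via SVD (Λ = U S Vᵀ →
Λ* = U S, F* = F V), signs fixed so each factor's loading sum is
non-negative; fitted effects ΛFᵀ are invariant and the map is idempotent.
OP_i = λ̄₁ f*_{i1}, by default re-centered by the fitted grand mean
(intercept + average year-site effect) so OP lands on the trait scale
(t/ha); `include_mean=False` gives the centered version. RMSD averages
the squared higher-factor contributions over the p fitted environments —
the training set's population of environments, with no extrapolation. OP
is equivariant under scaling of the loadings (including sign), RMSD is
absolutely homogeneous.

## Synthetic MET generator (`metsim`)

The generator emulates an elite winter-wheat variety-testing series: by
default 45 genotypes, five year-sites (three 2019, two 2020), four
replicates in randomized complete blocks on row×column grids, 20% of
genotypes missing per year-site (cells dropped whole, mirroring sets that
differ between years), genotype main effects (σ²_g = 0.25), a rank-2
factor-analytic G×E covariance with an all-positive dominant factor,
per-environment lack-of-fit ψ = 0.05, a smooth spatial trend built from
low-order sinusoid products scaled to σ²_spatial = 0.15, random row and
column effects (0.05 each), and heteroscedastic plot errors: the reported
SE is √σ²_e times a lognormal factor (log-sd 0.25), and the plot noise is
drawn with exactly that SE, so weights 1/SE² are correct by construction.
Trait values sit on a t/ha-like scale around a grand mean of 6.

Secondary (HTFP) traits are generated directly at the genotype ×
year-site adjusted-means level as linear functions of the target
genotype value plus independent genetic and residual components, with
environment shifts — the plot/imagery level is out of scope. Grain
protein is genotype-level with a negative link to yield genetic values.
Breeder decisions arise from a latent index (standardized true OP minus
weighted true RMSD plus noise) cut into the five-level scale; with the
default thresholds all five labels occur at 200 genotypes.

What passing tests on these data do **not** show: real HTFP traits are
nonlinear functionals of growth curves with non-Gaussian errors, real
field trend is not a sinusoid sum, real SEs are estimated (not known),
and real breeder decisions incorporate disease and quality traits absent
here. The generator validates estimator correctness and calibration, not
agronomic realism.

`gdd` converts an hourly temperature series to cumulative growing degree
days (daily mean minus base temperature, clamped at zero, base 0 °C by
default).

## Prediction (`phenopred`)

Feature tables carry up to 11 intermediate traits in categories C
(r_max, T_min, lrc), T (t_PH_start, t_PH_stop, t_dLA_max, t_LA_max) and Q
(PH_max, LA_tPH15, LA_max, n_tiller). Preprocessing for the yield task
removes the tiller-count outlier rule (n_tiller > 8000) and rows with any
missing C trait (dose–response fits that failed upstream); the decision
task maps the five-level scale to the ordinal response (3, 2, 1, 0, −1)
treated as a regression target.

Schemes: unseen E (one fold per year-site), unseen G (one per genotype),
unseen G and E (one fold per observed cell; training excludes the whole
year-site *and* the whole genotype — asserted on every fold), and
repeated k-fold (default 8-fold × 5 repeats, seeded; the repeat count is
a package choice). PLS runs on standardized features inside each training
fold (scaling is part of the pipeline, so no leakage); its single
component count is tuned once per task by ten-fold CV with the
one-standard-error parsimony rule — plain minimum-RMSE systematically
over-selects components on noisy collinear features. RF tunes
ntree ∈ {100, 250, 500, 750, 1000} × mtry ∈ [1, min(11, p)] per outer
fold by inner ten-fold CV (leave-one-out for the fully crossed scheme).
Metrics are computed on pooled out-of-fold predictions; nRMSE is
normalized by the mean of the observed response (this reproduces the
canonical pairing RMSE 1.23 t/ha ↔ nRMSE 20.80% at mean 5.913 t/ha).

Feature importance: for PLS the signed per-feature score Σ_c w_fc q_c
(x-weights × y-loadings, the decomposition of the regression coefficient
onto components) with a leave-one-out jackknife 95% interval; for RF the
mean increase in squared error over 50 permutations per feature with a
percentile interval from the runs.

## Selection efficiency (`decision`)

A line kept by the breeders counts as a success when its observed
performance reaches the evaluated threshold; efficiency is successes over
kept lines (the total-candidates denominator is also reported). The
enhanced selection removes kept lines whose *predicted* OP falls below
the threshold; false exclusions (pruned lines whose observed value
reached the threshold) are counted. Threshold optimization maximizes the
efficiency **increase** over midpoints of the predicted and observed
values of the kept set — maximizing the raw enhanced efficiency is
degenerate (any threshold far below the predictions yields trivial
efficiency 1), and the increase is exactly the quantity the retrospective
evaluation reports. Ties keep the lower threshold.
`protein_per_area(yield, protein%) = yield·protein/100` supplies the
protein-per-hectare trade-off curves.

## Problem sizes and tolerances

The test suite and the acceptance script run at desk scale, chosen so
estimator guarantees are sharp while a full run stays in minutes:
stage-2 recoveries at 200 genotypes × 5 year-sites (20 seeds),
genetic-correlation bias at 500 genotypes, model-selection rates at 200
genotypes, stage-1 checks on 40–100 genotypes × 4 replicates. Observed
performance: FA2 covariance recovery ≤ 0.16 Frobenius relative error
(bound 0.2), environment correlations ≤ 0.10 max deviation (bound 0.15),
r_g bias < 0.01 (bound 0.05), Cullis and Oakey errors < 0.01 (bounds
0.05 / 0.02), selection rates 100% (bound 90%).

## Limitations

* No autoregressive residuals or other spatial correlation structures in
  stage 1; no one-stage joint MET analysis; at most two FA factors.
* Variances are constrained non-negative; truly negative Diag estimates
  are clamped at the floor.
* The bivariate model ignores stage-1 weights (see above).
* No genomic data, no environmental-covariate regression, no economic
  cost modelling.
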