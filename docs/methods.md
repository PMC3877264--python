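# Methods

This note documents the statistical model, the defaults and why they were
chosen, the numerical choices, and what the synthetic-data generator does
and does not emulate.

## The trait reduction

Each species enters the analysis as one row: ln dry mass (mg), ln minimum
development time (days), optimal developmental temperature T_opt (°C), and
taxonomic order.

**T_dev / T_opt extraction.** The reaction norm is reduced to its empirical
minimum over the measured constant temperatures — no thermal-performance
curve is fitted, so sparse norms cannot move T_opt through interpolation.
Ties in development time break to the lowest tied temperature
(deterministic and conservative: never a warmer optimum than the data
force; configurable). When several independent estimates exist for one
species, the smallest minimum wins and its temperature is carried along.
Norms whose minimum sits at the warmest measured temperature get the QC
flag `t_opt_at_warm_boundary`: development may still have been
accelerating, so the optimum could be censored. Because the reduction is a
minimum, pooling measurements before extraction and extracting per source
then merging commute.

**Mass conversion.** Published length–mass equations are stored in log
form (ln a, b) for `mass_mg = a·length_mm^b`, so equations published as
either ln m = ln a + b ln L or m = aL^b map exactly without refitting.
Order-specific equations are preferred; orders lacking them fall back to
the general all-insect equations, and an order with neither raises. The
consensus is an arithmetic mean on the mg scale (a mean of mass estimates,
not of logs; a geometric-mean option exists). The SD uses the n−1
denominator — the ensemble members are treated as draws from independent
model populations — and this SD parameterizes the resampling study.

## Bivariate estimators

Both estimators are expressed through the five bivariate moments, so the
robust variants substitute Huber M-estimates of those moments into
unchanged slope and CI formulas:

* OLS: b = s_xy/s_xx; SE from the correlation; CI by the t quantile on
  n − 2 df.
* SMA: b = sign(r)·s_y/s_x through the means; CI
  b·(√(B+1) ± √B), B = (1−r²)·F(1−α; 1, n−2)/(n−2); the test of a
  hypothesized slope b₀ is the correlation t-test between y − b₀x and
  y + b₀x, which inverts the CI.

The robust moments use per-axis Huber location/scale (IRLS with the
chi-consistency correction, tuning constant 1.345·scale, ~95% Gaussian
efficiency) and a correlation from Huber-downweighted products of
standardized residuals with weights min(1, c√2/d) on the bivariate radius;
that correlation is self-normalizing, so no further consistency factor is
needed. The tuning constant is exposed. The r² reported for SMA is the
squared Pearson correlation — the convention of standard SMA tooling — not
an explained variance of a prediction.

## Phylogenetic GLS

Residual covariance among species is induced by the phylogeny under one of
four candidate structures: {BM, OU} × branch lengths {all = 1, Grafen}.

* **BM** covariance is the shared root-path length to the MRCA. For
  candidate fitting it is normalized to a correlation matrix: on
  non-ultrametric trees (the unit-branch convention makes tip depths
  unequal) this is what standard mixed-model GLS machinery fits — the
  structure carries correlation only, with a single profiled σ². This
  choice was verified to reproduce R's `nlme::gls` with `ape::corBrownian`
  exactly (coefficients, ML and REML log-likelihoods, σ²) on a small
  fixture during development.
* **OU** uses the Martins–Hansen correlation exp(−α·d) on patristic
  distances with unit diagonal — a valid correlation matrix on
  non-ultrametric trees, unlike the nonstationary OU covariance.
* **Grafen's transform** sets node heights to
  ((descendant tips − 1)/(N − 1))^ρ with ρ = 1 (exposed for sensitivity
  analysis); tips at height 0, root at 1, all branches nonnegative.
* Polytomies are handled natively by the covariance constructions; no
  arbitrary dichotomization.

Estimation whitens through the Cholesky factor of V (one diagonal jitter
of 10⁻⁸·mean(diag) is attempted on failure, then the error names the
problem). ML profiles σ²; REML is computed on the residual contrast space
and is what α maximizes. The α search runs on ln α with a 40-point grid
scan before bounded refinement, because the REML surface can carry a
spurious plateau at the independence limit (α → ∞) that traps a purely
local optimizer. A degeneracy flag is raised when the optimum pins at a
bound or the surface is flat — on a star tree with an intercept the
equicorrelation is absorbed entirely and REML is exactly constant in α.

AIC is −2·lnL_ML + 2k with k counting coefficients, σ², and α when
estimated; because likelihood constants differ across toolchains, AIC
comparisons are meaningful by rank, not absolute value. PGLS R² follows
the likelihood-ratio form 1 − exp(−2(lnL_full − lnL_null)/n) against the
intercept-only model under the same structure, clipped to [0, 1).

Factorial designs with sparse cells (e.g. single-species orders) are
inherently rank-deficient; the factorial path drops aliased columns and
records their names (the pivoting convention of standard linear-model
tooling), while the low-level GLS raises by default.

## Factorial inference

The full model is ln T_dev ~ ln m × T_opt × order with treatment contrasts
(alphabetically first order as reference); order coefficients are
coding-dependent, so downstream checks rely on F-tests, partial R², and
predictions, which are coding-invariant. Predictors are not centered. The
PGLS factorial excludes the T_opt:order interaction (and with it the
three-way, by marginality): order membership is itself a clade effect and
the term is singular against the phylogenetic structure.

Backward elimination removes the highest-order removable interaction with
the largest partial-F p-value above α (default 0.05), refits, and repeats;
main effects are never dropped and marginality is preserved throughout.
Sequential (Type-I) partial R² divides each term's sequential SS by the
null-model SS, so rows sum exactly to the model R²; it is defined for OLS
only — a sequential SS decomposition of a PGLS fit has no agreed-upon
definition here. The covariate-independence check regresses T_opt on
ln m plus order and reports the partial F for the mass term. T_opt-binned
SMA slopes use lower-closed bins with default edges 28, 30, 33 °C (the
boundary convention is configurable). Standardized predictions evaluate
the final model at ln(1 mg) = 0 — zeroing every mass term — for orders
with ≥ 10 species, with delta-rule SEs and t CIs.

## Mass-error resampling

Per replicate, each species' mass is drawn from Normal(mean, sd) on the mg
scale; nonpositive draws are redrawn rather than truncated (truncation at
an epsilon spikes the ln tail), with a 1000-round cap that names offending
species. Replicates use child seeds spawned from the master seed, so
growing n_reps never changes earlier replicates, and reruns are
bit-identical. Defaults: 10,000 replicates, OLS refit (SMA available),
summaries as mean and 2.5/97.5 percentiles.

## Synthetic-data generator

The generator emulates a compiled comparative dataset of insect
development with known truth:

    ln T_dev = a + b·ln m + c·(T_opt − t_ref) + d·ln m·(T_opt − t_ref)
               + u_order + ε

The T_opt terms are centered on t_ref = 30 °C so that `true_exponent` b is
the mass slope at a typical optimum; with the defaults b = 0.25,
c = −0.055/°C, d = −0.022/(ln mg·°C), the implied mass slope falls from
~0.38 for cool-adapted species (T_opt 24 °C) to ~0.12 for warm-adapted
ones (36 °C), the qualitative pattern the factorial machinery is built to
detect. Defaults mirror the study scale: 361 species in 16 orders with
skewed (Dirichlet 0.4) richness; ln mass uniform over 10^−2.5–10^3.2 mg
(~6 orders of magnitude); T_opt centered at 30 °C with order offsets
(SD 2 °C), tip noise (SD 1.5 °C), half-degree rounding, and one
hot-shifted (+5 °C) order; order intercept offsets SD 0.8; residual SD
1.35 with Brownian-motion phylogenetic correlation by default (iid and OU
available), which together put the bivariate mass-only R² near 0.25 and
the full-model R² near 0.6. Reaction norms are piecewise-quadratic around
the optimum with the upper limb twice as curved (development deteriorates
faster above T_opt than below), measured at 2–11 constant temperatures
with 5% multiplicative noise. Length–mass ensembles per order contain 2–7
equations scattered (ln-intercept SD 0.25, exponent SD 0.04) around an
order-specific true model near m = 0.03·L^2.7; one order receives no
specific equations and must use the general fallback. Trees are pure-birth
topologies with monophyletic order clades and unit branch lengths by
default.

What the generator does **not** emulate: real taxon sampling (its richness
skew is random, not the actual order counts), literature heterogeneity in
measurement protocols, correlation between body mass and T_opt or
latitude, non-quadratic reaction-norm shapes, and uncertainty in the tree
topology itself. Tests passing on synthetic data therefore demonstrate
correctness of the estimators and pipeline plumbing under a known model,
not robustness to every failure mode of compiled literature data.

## Calibration experiments and their design

* **Slope-CI coverage**: b = 0.25 at n = 361 with residual SD set by
  `residual_sd_for_r2` to give R² ≈ 0.26; the 95% CI covers truth in ~95%
  of 200 replicates.
* **Structure recovery**: traits simulated under each of the four
  structures on a 200-tip tree are assigned to their generating structure
  by AIC in the majority of 100 replicates. The generating OU α is
  depth-scaled (0.35 on unit branches, 2.0 on Grafen trees) so the prior
  correlation at typical within-clade distances sits midway between
  independence and identity; with α mismatched to tree depth, OU is
  genuinely near-indistinguishable from BM and no selector could recover
  it.
* **OU α recovery**: REML recovers α = 1 within a factor of 2 in ≥ 90% of
  replicates on a 200-tip tree with exponential branch lengths. Close tip
  pairs identify α; a known limitation is that on unit-branch trees (no
  pair closer than two edges) α is only weakly identified and a
  substantial minority of replicates prefer the independence plateau.
* **Elimination calibration**: with truly null interactions, the
  three-way term is dropped in ~(1 − α) of replicates.
* **Attenuation**: increasing relative mass error monotonically attenuates
  the mean resampled OLS slope (classical errors-in-variables), and
  resampled R² averages below the noiseless R².

Problem sizes throughout (200-tip trees, 100–500 replicates, 10,000
resamples) were chosen so the full acceptance computation completes in
about two minutes while keeping Monte-Carlo error well inside the asserted
bands.

## Known limitations

* The OU form is a correlation on patristic distances; it does not model
  the nonstationary variance profile of an OU process from a root state.
* Robust SMA/OLS use one specific Huber construction; other robust
  bivariate estimators in the literature differ in detail, so robust and
  standard slopes should be compared at printed precision only.
* Sequential partial R² is entry-order dependent by construction
  (orthogonal predictors excepted) and is not available for PGLS.
* The Wald CI of an individual factorial coefficient and the partial-F
  p-value of its term can disagree (different null parameterizations);
  both are reported rather than reconciled.
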