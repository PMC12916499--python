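# Methods

This note documents the statistical model behind `factorverse`, the choices
made where the design was genuinely open, and what the synthetic benchmark
does and does not establish.

## The measurement model

Item-level questionnaire responses are treated as ordinal manifestations of
continuous latents: item i has a standard-normal latent variate
x*ᵢ = λᵢ′f + εᵢ, with f ~ N(0, Φ) the oblique common factors, λᵢ the pattern
loadings, and εᵢ unique normal noise scaled so Var(x*ᵢ) = 1. The observed
response is the count of the item's ordered thresholds lying below x*ᵢ.
Standardising the item latents to unit variance means that, under orthogonal
factors, loadings are item–factor correlations and the population polychoric
correlation between items i and j is λᵢ′Φλⱼ — which is what makes the
generator's recovery tests analytically checkable.

### Polychoric estimation

Pairwise correlations use the common two-step estimator: thresholds from the
marginal cumulative proportions via the inverse normal CDF, then ρ by
maximising the bivariate-normal likelihood of the contingency table
(bounded scalar optimisation over (−0.999, 0.999); rectangle probabilities
via Owen's T function, exact to ~1e-14 against quadrature). Joint ML of
thresholds and ρ would differ negligibly at these sample sizes and is not
implemented. Empty cells get +0.5 added (only when some cell is empty;
switchable) to avoid −∞ log-likelihoods. Item pairs where either item shows
more than 10 observed categories fall back to Pearson correlations; the
battery's Likert items never trigger this in practice. Pairwise estimation
does not guarantee a positive semi-definite matrix, so `ensure_psd` floors
eigenvalues at ε (default 1e-8) and rescales to a unit diagonal; because
pairwise estimates do not depend on which other items are present,
questionnaire-subset analyses slice the full matrix and re-repair rather
than re-estimating.

### Factor extraction and rotation

Extraction minimises the ML discrepancy by profiling out the loadings: for
fixed uniquenesses Ψ, the optimal Λ follows from the eigenstructure of
Ψ^{-1/2}RΨ^{-1/2}, leaving a p-dimensional L-BFGS-B problem over Ψ with
bounds [0.005, 1]. The 0.005 floor is the Heywood guard: improper solutions
are flagged, not fatal, so multiverse sweeps of thousands of fits keep
running. A vanishing ridge (1e-6 · Σ −log ψᵢ) prefers the
minimum-communality solution when the profile likelihood is flat (e.g. no
common variance); its effect on regular fits is below 1e-10 in F. If ML
fails to converge the cell falls back to minres (least squares on
off-diagonal residuals) and the candidate is flagged. χ² = (n−1)·F_min;
RMSEA = √(max(χ²−df,0)/(df(n−1))); TLI is computed against the independence
model on the same matrix (the baseline is not otherwise identified).

Rotation uses the gradient-projection algorithm, oblique for direct
quartimin (the oblimin family with γ = 0, the common default) and orthogonal
for varimax, from the identity start plus eight seeded random starts, keeping
the lowest criterion value. Reporting convention: each factor is sign-flipped
so its largest-magnitude loading is positive, and factors are ordered by
explained variance; this makes cross-run and cross-rotation comparisons
well defined. Rotation never changes χ².

### Bifactor solution

The hierarchical solution follows the Schmid-Leiman route: fit the oblique
k-factor model, fit one factor to its factor correlations Φ (k = 3 is
just-identified, so the triad solution is exact; k = 2 uses the
equal-loading constraint), and decompose general = Λγ,
group = Λ·diag(√(1−γ²)). One consequence is exact and worth stating: the
combined SL loading matrix [general | groups] equals Λ[γ | diag(√(1−γ²))]
and therefore has rank k, not k+1 — the general factor adds no item-level
information beyond the group factors, and jointly orthogonal score estimates
cannot be built from it. Score weights for bifactor candidates are therefore
taken from a full-rank *direct* bifactor representation: k+1 ML factors
orthogonally Procrustes-rotated onto the SL pattern. The SL loadings
themselves (and the variance identity general² + Σ group² = oblique
communality, exact when the higher-order fit is exact) are unchanged by
this; only scoring uses the direct representation.

### Factor scores

Regression (Thurstone) weights W = R⁻¹ΛΦ serve all first-order candidates.
Anderson-Rubin scores orthogonalise the regression-type scores against their
own sample covariance (computed with 1/n on items standardised to mean 0),
which makes the returned scores' covariance the identity to machine
precision — the defining property — and reduces to the textbook
W = R⁻¹Λ(Λ′R⁻¹Λ)^{-1/2} when R is the sample correlation matrix of the
scored data.

## Scoring, effects and aggregation

A candidate's score in any dataset is Σ item × weight. By default items are
z-scored with the *discovery* sample's means and SDs before weighting
(`discovery_z`): raw responses on different Likert ranges would make weights
scale-incoherent across items, while within-dataset z-scoring would let each
dataset redefine the dimension. Both alternatives are implemented and
logged on the score object.

Effects are OLS regressions of the outcome on the focal score plus
conditioning dimensions plus covariates (age, gender by indicator contrasts
with the largest category as reference, IQ), with listwise deletion.
Cohen's f² = (R²_full − R²_without_focal)/(1 − R²_full), signed by the focal
coefficient; the R²-difference form and the partial-correlation identity
r²/(1−r²) agree to 1e-10, which the suite asserts on random designs.
Conditioning policy mirrors the study design: factor-number and rotation
candidates enter jointly with the sibling factors of their own solution
(oblique factors are correlated, so single-factor models would conflate
them); combination-arm candidates enter alone for planning, and for
confidence add the benchmark anxious-depression (overconfidence) or
compulsivity (underconfidence) dimension as a covariate. Because the
benchmark dimension is itself a member of the multiverse, a candidate that
(near-)duplicates it (score correlation above 0.999) has the aliased
covariate dropped, as fixed-effects solvers do silently. Cross-dataset
aggregation is the sample-size-weighted mean of the signed f² values —
fixed weights, as in a meta-analysis with known n.

Ranking is by weighted f² in the stated direction; ties share the smallest
rank (after an |f²| tie-break), and `percentile_beaten` reports the share of
strictly worse ranked candidates among the other m−1 (the alternative
(m − rank)/m convention is available as `percentile_convention="rank"`).
Non-converged cells are kept as rows, excluded from ranks, and counted.

## The supervised comparator

PLS uses the sequential-deflation (NIPALS, single-outcome) algorithm; the
first weight vector is proportional to X′y, which is invariant across PLS
variants and is the tested surface. The outcome is first residualised for
the covariates (and, in the confidence analyses, the opposing benchmark
dimension); the discovery sample is split 75/25 (training size ⌈0.75n⌉);
components are chosen by 10-fold cross-validation on the training set,
minimising RMSE in standardised-outcome units with ties resolved toward
fewer components. X is standardised with training moments. Scoring uses the
rotation weights W(P′W)⁻¹, which reproduce the internal component scores
exactly on training data (and equal the first weight vector for component
1). An independent cross-check against scikit-learn's PLS is part of the
suite; the comparator itself never delegates to it.

## The synthetic benchmark

`make_benchmark` simulates the study conditions the analysis assumes: nine
questionnaires with the standard item counts (18, 10, 30, 26, 24, 18, 43,
20, 20 — total 209), three oblique factors with correlations 0.4/0.5/0.3,
dominant loadings uniform in (0.45, 0.75) and cross-loadings in (0, 0.15),
four response categories with right-skewed thresholds (symptom endorsement
is rare) jittered per item, and demographic covariates matching a large
online sample (age ≈ N(33, 11), 58% female, IQ ≈ N(100, 10)). Outcomes are
linear in the true factor scores plus covariate effects (standardised
coefficients −0.10 age, +0.05 male, +0.10 IQ) and unit-SD noise. The
factor coefficients are solved in closed form from the planted signed
partial f²: with conditional factor variance v = 1/(Φ⁻¹)ⱼⱼ,
b = sign(f²)·σ·√(|f²|/v); a brute-force root-finding inversion confirms the
closed form to 1e-6. Planted values are the replication-scale effects the
procedure is meant to detect: f² = −0.014 (planning on compulsivity),
+0.038 and −0.030 (confidence on compulsivity and anxious-depression).

Problem sizes for the benchmark suite — three datasets of n = 2000, and a
scaled combination arm over five questionnaires (all 31 subsets × k = 1…3,
186 candidates) — were chosen so a full run completes in about a minute on
one CPU while keeping Monte-Carlo error on recovered f² near 0.003, well
inside the ±0.01 recovery tolerance.

What the passing benchmark shows: the full chain (ordinal simulation →
polychoric → ML + oblimin → cross-dataset scoring → signed f² →
sample-size weighting → ranking) recovers planted structure and planted
partial effects without material attenuation, and the planted
compulsivity-like factor out-ranks the 186 subset-derived competitors. What
it does not show: robustness to features real questionnaire data have and
the generator omits — missing responses, method factors and correlated item
residuals, acquiescence and other response styles, non-normal latents,
demographic confounding of the factors themselves, and cross-dataset
measurement non-invariance. Conclusions about real data rest on the
procedure, not on these simulations.

## Numerical and degenerate-input conventions

- Polychoric ρ is clamped to ±0.999 (duplicated items hit the bound and are
  recorded); a margin with one occupied category is an error naming the
  item.
- Identification requires (p−k)² ≥ p+k; under-identified multiverse cells
  are skipped and logged, never silently fitted.
- `ensure_psd` leaves already-PSD input untouched and records the smallest
  eigenvalue it saw.
- All simulation, rotation-start, split and CV randomness is seeded
  explicitly; regenerating with the same configuration is byte-identical,
  and derived seeds stay below 2³¹.
- Gender is simulated as binary but the effect machinery codes any number
  of categories by indicator contrasts against the largest category.

## Known limitations

- The bifactor path implements the Schmid-Leiman transform of a
  higher-order model, not an exploratory direct-bifactor rotation; with
  k = 2 group factors the higher-order loading is fixed by the equal-loading
  constraint.
- Polychoric standard errors are not computed (the pipeline consumes only
  the point estimates).
- The effect models are ordinary least squares; no robust or mixed-effects
  variants.
- Multiple-testing correction across the multiverse is deliberately absent:
  the procedure ranks by effect size rather than testing each cell.
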