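# Methods

This note documents the statistical procedures, the numerical choices and
the synthetic-data model behind `grazemulti`, and what the shipped tests do
and do not establish about real field data.

## Data model

Three plot-level tables define an experiment. The design table maps each
plot to its block and grazing treatment (NG, SG, CG, MG in the reference
design of 6 blocks × 4 treatments); the function table holds the 12 raw
ecosystem measurements; the richness table holds integer species/OTU counts
for 6 organism groups. `plot_id` is the only join key. Missing cells are
kept explicit and index computations refuse them unless the caller picks an
imputation policy (`drop_plot` or `column_mean`): the reference analysis
assumes complete data, and silent imputation would be invisible bias. Two
raw functions are derived quantities with their own formulas: resin-membrane
soil N availability, (NH₄ + NO₃ concentration in µg N/mL) × 70 mL extract /
(50 cm² strip × days deployed), and ectomycorrhizal relative abundance, the
per-plot sum of relative abundances of guild-annotated OTUs.

## Standardization and indices

All variables are min-max standardized once, over every plot of the
experiment (not per treatment), so that treatment comparisons of an index
compare like with like; a per-scope option exists for sensitivity analyses.
A constant column is a hard error naming the column. All 12 functions are
treated as desirable as measured; a per-function `reflect` flag exists but
defaults off. Bound checks tolerate 1e-9 of float round-off.

EMF and multidiversity are unweighted means of standardized columns. The
weighted EMF down-weights statistically redundant functions: pairwise
correlation (Spearman by default, for robustness to monotone nonlinearity)
is turned into the distance 1 − |r|; average-linkage clusters are cut at
height 0.5 (functions merging at |r| ≥ 0.5 share a cluster); each of the k
clusters receives weight 1/k split equally among members. The procedure is
deterministic — variables are processed in lexicographic order so linkage
ties cannot reorder across platforms — and reduces exactly to the
unweighted mean when every cluster is a singleton. This clustering scheme
is this package's concrete realization of correlation-based down-weighting;
other down-weighting variants exist in the multifunctionality literature,
so the weights report should accompany any weighted-EMF result.

The multithreshold profile defaults to counting standardized values
EF ≥ t (consistent with a pipeline in which standardization precedes every
index); a raw mode compares raw values against t × benchmark, where the
benchmark is the observed maximum or, for outlier robustness, the mean of
the top k = 2 values. The boundary is inclusive. Counts are non-increasing
in t and invariant to rescaling any single function.

## Blocked ANOVA and Tukey letters

The treatment test is the closed-form additive RCBD decomposition
SS_total = SS_block + SS_treatment + SS_residual with
F = MS_treatment/MS_residual on (t−1, (t−1)(b−1)) df. Block is treated as a
fixed additive factor: in a balanced complete-block design this yields the
identical treatment F-test to the random-block mixed model, which is the
inferential target, without estimating variance components. Unbalanced
layouts raise an error rather than silently switching sums-of-squares
types; with one observation per cell only the additive (no-interaction)
model is estimable. Tukey comparisons use
q = |mean_i − mean_j| / sqrt(MS_residual/b) against the studentized-range
distribution with (t, df_residual); the default alpha is 0.1, matching the
P < 0.1 convention for treatment contrasts in this literature. The compact
letter display uses the insert–absorb algorithm with treatments ordered by
descending mean; two treatments share a letter iff not separated at alpha.

## Associations

Diversity–function relationships are simple OLS fits reporting slope,
intercept, Pearson R (Spearman optional), and the two-sided slope test from
t with n − 2 df. Correlation-grid p-values are reported raw by default (a
Benjamini–Hochberg switch exists). The leave-one-group-out screen
recomputes multidiversity without each organism group in turn and refits,
to check that no single group drives the relationship.

## Random-forest screen

Predictors of EMF (livestock dummy, multidiversity or its components, soil
pH, electrical conductivity, bulk density) are ranked by a regression
random forest: multifunctionality is continuous, so regression is the
default and classification requires user-supplied bins. Importance is
permutation importance of the fitted forest (mean decrease in score over
predictor shuffles). Significance comes from an rfPermute-style null:
the response is permuted (breaking all predictor links at once), the forest
is refit `n_permutations` times, and p = (1 + #{null ≥ observed}) /
(n_permutations + 1) — the add-one rule keeps p ≥ 1/(n_permutations + 1),
so small permutation counts floor, never exaggerate, significance. A single
seed drives forest construction, importance shuffles and permutations;
identical seed and data give identical output.

## Path analysis

Models are DAGs over observed variables. For recursive models with
uncorrelated disturbances, ML estimation decomposes into one least-squares
solve per endogenous variable against its parents, performed directly on
the sample covariance S (n − 1 denominator); variables are standardized to
unit variance first so coefficients are standardized path coefficients.
The implied covariance is Σ̂ = (I−B)⁻¹Ψ(I−B)⁻ᵀ with Ψ holding the free
exogenous (co)variances and the diagonal disturbance variances; the fit
statistic is χ² = (n−1)(ln|Σ̂| − ln|S| + tr(SΣ̂⁻¹) − p) with
df = p(p+1)/2 − (#edges + #disturbances + #exogenous (co)variances).
A saturated model gives χ² = 0 at df = 0 exactly. RMSEA =
sqrt(max(χ²−df,0)/(df(n−1))); the close-fit probability is the tail of the
noncentral χ²(df, λ = 0.05²·df·(n−1)) at the observed statistic. The
Bollen–Stine bootstrap rotates the centered data by S^(−1/2)Σ̂^(1/2)
(symmetric square roots) so the fitted model holds exactly in population,
resamples rows with replacement, refits, and applies the add-one p rule;
degenerate resamples (singular covariance) are skipped, which can only make
the p conservative. Total effects (I−B)⁻¹ − I equal the sum over all
directed paths of coefficient products; direct, indirect and total satisfy
total = direct + indirect identically.

The shipped default model — livestock → {above-, below-ground diversity} →
EMF plus a direct livestock → EMF path, with uncorrelated diversity
disturbances — has df = 1: the single tested constraint is the residual
above/below covariance. Because the outcome equation is saturated,
exchanging EMF for a multithreshold count changes the coefficients but not
the fit statistic. This topology is a reconstruction; the model is
user-configurable as a YAML edge list. Block-residualization (subtracting
block means, the residuals of an ANOVA on block) is available as a
robustness preprocessing step, by default applied to whichever variables
the caller passes.

## Synthetic-data generator

The generator draws a randomized complete block layout and wires an
explicit causal chain with standardized coefficients: the MG indicator
(standardized) affects an above-ground and a below-ground diversity latent
(the below-ground livestock effect attenuated by `below_livestock_effect_scale`,
default 0.4, since soil communities respond more weakly to grazing
management than plants and insects); the pooled diversity signal and a
direct livestock path drive a function latent with coefficients (a, b, c′).
The above/below latent disturbances are correlated
(`above_below_latent_correlation`, default 0.3), representing shared
environmental drivers beyond the blocks; at the default coupling, the df = 1
path model above is an adequate description of most generated experiments
(median χ² ≈ 2 across seeds) while occasional draws reject it — mirroring a
borderline-fitting world rather than one where the model is exactly true.
Richness counts are affine images of their latent plus per-treatment
shifts, per-group block effects and noise, rounded half-even and clamped at
zero; functions are affine images of the function latent plus a
cluster-shared factor (four clusters of three functions, giving the
correlation structure the weighted EMF needs) plus noise, on arbitrary
positive measurement scales (min-max standardization removes them).
Soil covariates are drawn independent of treatment. Setting both
`block_sd` and `noise_sd` to zero switches off every stochastic
disturbance, giving the fully deterministic limit in which richness is
exactly base + treatment effect.

Default effect sizes (a, b, c′) = (0.5, 0.45, 0.15) with treatment shifts
of 0.25–0.6 latent SD above ground and 0.1–0.2 below were chosen so the
6 × 4 design is moderately powered: across 300 seeds the treatment F-test
at alpha = 0.1 rejects for 67% of draws on multidiversity, 87% on
above-ground diversity and 34% on EMF, so both significant and null
outcomes are routinely exercised. `null_scenario` zeroes every effect for
type-I-error and permutation-null calibration; `chain_scenario` zeroes the
treatment shifts and block effects and collapses the two latents into one
(coupling 1.0) so that fitting livestock → multidiversity → EMF to the
generated tables recovers (a, b, c′) asymptotically — at 1,000 plots the
recovered coefficients carry OLS sampling noise of about ±0.03, the reason
calibration checks at that size use a ±0.05 margin.

What the generator does not emulate: spatial autocorrelation within plots,
temporal dynamics across grazing seasons, non-Gaussian richness dispersion
(counts are rounded Gaussians, not negative binomial), treatment effects on
soil covariates, and nonlinear diversity–function shapes. Tests passing on
synthetic data therefore establish the correctness and calibration of the
*statistics*, not the field generality of the *ecology*.

## Problem sizes and runtimes

Calibration checks use sizes chosen to make Monte-Carlo error small
relative to the asserted margins while keeping the default test run brief:
500 null replicates for the ANOVA rejection rate (binomial SE ≈ 0.013
against a ±0.03 band), 1,000 replicates at n = 200 for the χ² reference
distribution (KS test), 20–30 seeded datasets for the random-forest checks
at reduced forest and permutation counts (the add-one floor makes reduced
counts conservative), and Bollen–Stine bootstraps of 300–2,000 depending on
context. The full suite runs in about two minutes; the acceptance script in
about one.
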