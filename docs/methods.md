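# Methods

`hissbrn` implements a complete analysis chain for repeated nest-defence
assays of breeding female great tits: a behavioural-reaction-norm (BRN)
mixed model for hissing behaviour, repeatability and permutation inference
for its variance components, a multivariate partition of trait covariances
into among-individual (ID) and residual (R) matrices, and path-model
comparison over the posterior ID matrices. Because no field dataset ships
with the package, a synthetic-data module reproduces the study design and
the generative structure the downstream models assume; every stage is
validated by parameter recovery against that generator.

## Study design emulated by the generator

Each female is scheduled for up to five 60-second predator-presentation
trials across the nesting cycle: incubation days 2, 5 and 9 and nestling
days 2 and 5. Days are coded relative to hatching (hatching day = 0);
with the 12-day incubation period this gives the schedule
(-10, -7, -3, +2, +5). The reference design has 104 females and 448
trials, with per-female trial counts {5: 48, 4: 45, 3: 8, 2: 1, 1: 2}.
Females with fewer than five trials keep the earliest trials, mimicking
censoring by nest failure; which females are short-schedule is a seeded
random draw. The histogram is treated as exogenous — the generator does
not model the failure process that produced it mechanistically.

## Reaction-norm model

The response is the number of hissing calls per trial, analysed throughout
on the mean-centred, unit-variance scale. The model is

    y_ij = x_ij' beta + u0_i + u1_i * d_ij + e_ij,
    (u0_i, u1_i) ~ N(0, G),   e_ij ~ N(0, sigma_e^2),

where `d_ij` is the day in the nesting cycle, `G` is the 2x2
among-individual covariance matrix (intercept variance = personality,
slope variance = plasticity) and the fixed effects are day, per-female
mean Julian test date, within-female mean test time and its per-trial
deviation, and age class (first-year reference; adult and unknown are
real levels, not dropped). Within-female time centring and the per-female
Julian mean are recomputed from the data at fit time rather than trusted
from input columns.

Generator defaults are the reference posterior means: `beta_day = 0.02`
per day, `G = [[0.85, 0.010], [0.010, 0.0014]]`, `sigma_e^2 = 0.19`, with
the remaining fixed effects applied to covariates standardized by their
theoretical (uniform) moments. Raw call counts are produced by the affine
calibration `count = round(clip(12.83 + 11.06 z, 0, 43))`, matching the
observed count moments and range; no Poisson/negative-binomial layer is
used because all analyses operate on the standardized Gaussian scale.
With these defaults the marginal mean and variance of the standardized
response are approximately 0.03 and 1.05 (the day trend and the small
slope-variance and covariance contributions almost cancel), which is close
enough to (0, 1) that re-standardization is left to the explicit
`standardize` step when starting from counts.

## Posterior computation

The BRN model is fitted by a blocked Gibbs sampler with conjugate updates:
inverse-Wishart for `G` (identity scale, minimal proper degrees of freedom
q + 1), inverse-gamma(1e-3, 1e-3) for the residual variance, and Gaussian
updates for the coefficients and female effects. The fixed effects are
drawn with the female effects integrated out (a collapsed update via the
Woodbury identity); without this the population intercept and the random
intercepts are nearly confounded and mix very slowly. With the collapsed
update, default chains (13 000 iterations, 3 000 burn-in, thinning 10;
1 000 retained draws) give lag-1 autocorrelations below 0.05 and
split-chain scale-reduction factors below 1.05 on the synthetic defaults;
non-convergence flags the posterior and warns rather than raising.

Priors are a declared design choice (the exact reference priors are not
available): all hyperparameters are exposed, and the `prior_scale` /
`prior_df` switches support sensitivity analysis. One consequence worth
knowing: the identity prior scale dominates the tiny slope variance
(generating value 0.0014), whose posterior mean sits near 0.014 at the
default settings. The intercept variance, residual variance, fixed
effects and repeatability — the quantities the package reports as primary
— are insensitive to this (recovered to within a few percent in the
acceptance experiments).

A fixed effect is reported as "supported" when its central 95% credible
interval excludes zero. Variance components cannot be tested that way
(their CrIs never reach zero), hence the permutation test below.

## Repeatability and permutation inference

Adjusted repeatability is computed per posterior draw as
`R_adj = V_id / (V_id + V_e)` and then summarized (posterior mean and 95%
CrI); the generating ratio at the defaults is 0.85/1.04 = 0.817.
Stage-specific repeatabilities come from random-intercept-only fits on
the incubation or nestling subset.

The permutation test reshuffles the response across *all* observations
(breaking female identity entirely; a within-female variant is
deliberately not offered), refits the full model, and records the
posterior mean of the component of interest. The p-value is the
exceedance proportion `#(null >= observed) / n_perm`; with zero
exceedances it is reported as "< 1/n_perm", the smallest level resolvable
with that many shuffles — e.g. "< 0.01" at 100 shuffles. No +1
small-sample correction is applied. Permutation refits use shorter chains
than the primary fit (default 3 000/500/5) since only posterior means are
consumed; failures are reshuffled and retried up to three times, then
excluded with a warning.

## Multivariate ID/R partition

For successful nests only, hissing behaviour (all repeated records) plus
the four single-record reproductive traits (lay date, clutch size,
fledgling number, mean fledgling mass), each standardized within the
analysed subset, enter a five-trait random-intercept model. The
among-individual matrix has an inverse-Wishart prior (identity scale,
d.f. = 6). Hissing's within-individual variance is estimated in R; the
single-record traits' residual variances are fixed at `fixed_resid = 1e-4`
(small enough to be "essentially zero", large enough for numerical
stability) and all residual covariances at zero, since within-individual
(co)variances involving single-record traits are not identifiable. A
sensitivity test (halving/doubling `fixed_resid`) verifies posterior mean
ID correlations move by less than Monte-Carlo noise. Fixed effects are
intercept-only: the traits are pre-standardized and no day covariate is
used at this stage, so part of the day trend and slope variation ends up
in the hissing residual — intentional, as this stage targets
among-individual covariances, not the reaction norm itself.

## Path analysis

Each candidate causal diagram (DAG) is fitted to every posterior draw of
the ID correlation matrix by minimizing the maximum-likelihood SEM
discrepancy

    F_ML = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - p,

with `Sigma(theta) = (I - B)^-1 Psi (I - B)^-T`. The optimizer (BFGS with
the analytic gradient) starts from zero coefficients and unit variances;
for recursive models with uncorrelated residuals the ML solution equals
per-equation least-squares partial regression coefficients, which the test
suite verifies to 1e-6 as an independent oracle. Fit statistics use
`chi2 = (n_obs - 1) F_ML` and `AIC = chi2 + 2 k` (k = free parameters:
edges + one variance per node + declared exogenous covariances). This is
the classical SEM AIC convention; only dAIC between models fitted to the
same matrices is interpreted, so the additive constant is immaterial.
`n_obs` is the number of females entering the multivariate model (77 at
the reference scale). Draws whose optimization fails are excluded; more
than 10% failures aborts the summary. dAIC > 2 flags a model as less
supported.

For model *ranking*, the default AIC is computed on the across-draw mean
correlation matrix rather than averaged over per-draw AICs. The reason
is a Jensen-gap artifact: each posterior draw carries the posterior's own
sampling noise, which edge-rich models can absorb into their coefficients
while sparse models pay for it in chi-square, so `mean(AIC(S_draw))`
systematically inflates the dAIC of sparse models — under an
independence generator the null model then loses to the saturated-ish
candidates about half the time, although no cross-trait effect exists.
Fitting the posterior-mean matrix removes that bias (the null model is
then correctly competitive under independence while the generating model
still wins decisively when effects are present). Averaging per-draw AICs
remains available (`aggregate="samples"`), and coefficient summaries are
always computed across draws so uncertainty propagation is unaffected.

The default candidate set reconstructs the competing scenarios: model 0
(all traits independent), model 1 (reproductive cascade only: lay date and
clutch size drive fledgling number and mass; nest defence isolated),
model 2 (model 1 + lay date -> nest defence) and model 3 (model 2 + nest
defence -> clutch size, the defence/clutch trade-off). The set is
config-driven, so users can declare any edge lists.

The preliminary nest-success stage is a logistic regression of nest
success on the standardized posterior-mean hissing level, lay date and
clutch size, with Wald 95% intervals; complete separation triggers a
Firth (Jeffreys-prior) penalized refit, recorded in the output.

## What the generator does and does not emulate

It reproduces: the trial design and missingness histogram; Gaussian
reaction-norm structure with configurable G and residual variance; count
calibration to the observed range; unit-variance trait generation from an
arbitrary DAG by path-tracing (so implied correlations are exact products
of path weights); coupling of the behavioural intercept to the
nest-defence trait; and Bernoulli (or exact-count) nest success
independent of traits by default.

It does not emulate: overdispersed/zero-inflated counts, seasonal or
spatial structure in covariates, selective disappearance (failure is
independent of traits unless an edge is declared), or any acoustic or
predator-encounter process. Passing tests therefore demonstrate correct
recovery under the model's own assumptions, not robustness to real-data
violations of them.

## Problem sizes and numerical choices

Recovery experiments use 20 replicate simulations at the full design with
2 500-4 000-iteration chains, permutation tests 100 shuffles with
1 200-1 500-iteration refit chains, and multivariate/path recovery 20
replicates with ~110-500 posterior ID draws; these sizes give Monte-Carlo
error comfortably inside the assertion tolerances. Degenerate inputs
(constant responses, single females, cyclic DAGs, non-positive-definite
matrices) raise typed errors early; near-singular posterior covariance
samples are ridge-jittered (1e-10 x trace) before correlation conversion,
with a warning.
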