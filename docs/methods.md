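# Methods

## The measurement problem

Given survey micro-data with a binary utilization outcome y, sampling
weights w, and a living-standards variable that ranks respondents, the
concentration index summarizes income-related inequality as

    CI = 2 cov_w(y_i, R_i) / ybar,

where R_i is the weighted fractional rank of respondent i in the income
distribution and ybar the weighted mean outcome. CI lies in [−1, 1]; it is
positive when utilization is concentrated among the better-off. For a
bounded outcome — in particular a binary one — the attainable range of CI
shrinks with ybar, so indices of groups with different means are not
comparable. Erreygers' correction

    E = 4 ybar / (y_max − y_min) · CI

restores the ±1 bounds and mirror symmetry. For binary utilization the
bounds are fixed at (0, 1) regardless of the observed minimum and maximum;
with that convention E = 4 ybar CI exactly.

## Fractional ranks

After a stable sort by the ranking variable, respondent i receives
R_i = (cumulative weight of strictly preceding respondents + w_i/2) / W.
Tied values all receive the midpoint rank of their tie group's total weight
mass. This equals the weighted average of the ranks the group members would
receive in any within-group order, so the index is invariant to within-tie
permutations — which matters here because imputed incomes take relatively
few distinct values. The weighted mean of the ranks is exactly 0.5, and the
ranks are invariant to any strictly monotone transform of income and to any
rescaling of the weights.

## Standard errors and index comparison

The CI equals the slope of a weighted least-squares regression of the
transformed outcome 2 var_w(R) y_i / ybar on R_i (the "convenient
regression"). The reported standard error is the HC1
heteroskedasticity-robust standard error of that slope, mapped through the
factor 4 ybar/(y_max − y_min) when it refers to the corrected index; the
outcome mean is treated as fixed in that mapping (delta method). This is
one of several estimators in common use; under the null of no
income-outcome association its nominal 95% intervals cover zero at close to
nominal rate (the acceptance suite requires 93–97% over 1,000 simulations
at n = 500). Indices from two independent cross-sections are compared with
difference = E_b − E_a, se = sqrt(se_a² + se_b²), and a two-sided normal
test — the combination rule that reproduces the published cross-wave
difference standard errors from the published per-wave values.

## Banded-income imputation

Survey income is observed only as one of ten bands (l, u]. On the log
scale, with covariates x (age group, education, region) and weights w, the
interval regression maximizes

    Σ w_i log[ Φ((log u_i − x_i'γ)/σ) − Φ((log l_i − x_i'γ)/σ) ],

with the bottom band's lower bound mapped to one currency unit (log 1 = 0)
and an open top band contributing the survival term. Optimization is BFGS
with the analytic gradient on the mean-scale likelihood; convergence
requires gradient max-norm below 1e-6 (relative log-likelihood change below
1e-10, at most 200 iterations); standard errors come from the inverse
observed information (finite differences of the analytic gradient). The
bottom band's log-difference is computed on the better-conditioned tail via
the symmetry Φ(b) − Φ(a) = Φ(−a) − Φ(−b).

Two predictions are exposed. The marginal prediction exp(x'γ), clamped
below at one currency unit, is the textbook point prediction. The pipeline
ranks respondents by the *band-conditional* prediction — the
truncated-normal mean exp(μ + σ(φ(a) − φ(b))/(Φ(b) − Φ(a))) — because it
retains the within-band information the marginal prediction discards. With
defaults where the covariates explain a minority of log-income variance,
only the conditional prediction keeps the imputed ranking faithful to the
latent income (Spearman ≈ 0.95 versus ≈ 0.4 marginal); it also breaks the
near-collinearity between imputed log income and the probit covariates that
would otherwise arise, since the marginal prediction is an exact linear
function of them.

Predicted income is divided by the modified OECD divisor
1 + 0.5(adults − 1) + 0.3·children and multiplied by CPI_base/CPI_year.
Both CPI values are user-supplied; the pipeline defaults to no rescaling
when no CPI table is given.

## Probit model and decomposition

Utilization is modelled as P(y=1|x) = Φ(x'β), maximized by Newton's method
with step-halving on the weighted log likelihood; the score uses the
generalized residual g_i = y_i φ/Φ − (1−y_i) φ/(1−Φ) and the observed
information Σ w_i g_i (g_i + x_i'β) x_i x_i'. Convergence requires relative
log-likelihood change below 1e-10 and mean-scale gradient max-norm below
1e-6 within 100 iterations. The coefficient covariance is the inverse
observed information with weights treated as frequency-type weights; the
significance stars in the output tables derive from it. Perfect separation
is detected (every observation classified correctly with |x'β| > 5) and
raised as an error rather than reported as a spuriously converged fit.

Partial effects at the sample means, β_k^m = β_k φ(x̄'β), are applied
uniformly to continuous and indicator regressors; a discrete-change variant
for indicators is available as an option but is not the default, because
the uniform derivative formula is what makes the elasticity
β_k^m x̄_k exact for the linearization at the means. Each regressor's
CI_k is the *standard* (uncorrected) concentration index of x_k over the
income ranks — the decomposition identity already carries the factor 4, and
this convention reproduces the published contribution arithmetic
(contribution = 4 × elasticity × CI_k) cell for cell. The residual is
defined as E − Σ contributions, which makes additivity exact by
construction; the generalized CI of the raw probability residuals
y − Φ(x'β) is reported alongside as a diagnostic (`residual_generalized_`).

Analyses are stratified by sex and survey year (four separate income
models, probits and decompositions), with reference categories: aged 75+,
never married, informal/no education, fair self-rated health, no chronic
disease, no mobility difficulty, CES-D below 10, no exercise in the past
two weeks, central region, middle physician-density band.

## Synthetic data generator

The generator emulates the elderly (65+) samples of two cross-sectional
health-interview waves:

- **Covariates** are drawn independently from categorical marginals matched
  to the published wave descriptives (e.g. 63.1% aged 65–74 and 48.4% with
  chronic disease in the 2005-like profile). CES-D is a negative-binomial
  count (shape 1.2, truncated at the scale maximum of 60) whose mean is
  solved so that P(score ≥ 10) matches the wave's depression-tendency rate;
  only the ≥ 10 dichotomy enters the model.
- **Income** is log-normal: log income = 9.2 + loadings·(education, age,
  region indicators) + 0.85·N(0,1), in currency units, reported only as one
  of ten geometric bands (upper bounds 2,000·2^k; the real survey's bounds
  are unpublished, so these are explicitly synthetic defaults held in the
  config, not constants). Household composition (1 + Poisson(0.8) adults,
  Poisson(0.3) children) drives the equivalence divisor.
- **Outcome**: a probit latent index over the same design the estimation
  stage uses, with the log of the *true* equivalised income as the income
  regressor; the intercept is solved numerically (large fixed-seed
  covariate draw, Brent root-finding) so the expected outpatient rate
  matches the wave target — 53.8% ("2005-like") and 46.5% ("2009-like").
  The income effect is 0.08 in the 2005-like profile and 0.30 in the
  2009-like profile, mimicking a strengthening income gradient.
- **Weights** are gamma with mean 1 and coefficient of variation 0.3,
  independent of everything else.

What this does and does not show: the generating model matches the
estimation pipeline's parametric assumptions (log-normal band-censored
income, probit outcome), so passing recovery tests demonstrates correctness
of the implementation, not robustness to misspecification. Real survey
features deliberately not emulated: multistage/PSU-stratified sampling
design (weights are the only design feature carried), item nonresponse,
correlation between covariates other than through income loadings, and
informative weights.

`true_decomposition` runs the full estimation pipeline on one very large
simulated sample (default 400,000; the recovery acceptance test uses
1,000,000) and serves as the oracle for small-sample recovery: 200
replicates at n = 5,000 must recover every probit coefficient,
interval-regression parameter and decomposition contribution within three
combined Monte-Carlo standard errors (replicate-mean error plus the
oracle's own simulation error, the latter scaled by the sample-size ratio).
The income regressor used in estimation is imputed rather than true income,
so the oracle targets the pipeline's own probability limit — attenuated
relative to the generating coefficients — which is the right benchmark for
an errors-in-variables pipeline.

## Numerical and degenerate-input conventions

- All-zero outcomes make the relative CI undefined and raise an error; a
  constant non-zero outcome gives CI = 0 with SE 0.
- Zero-mean regressors have an undefined relative CI_k; the column is
  flagged NaN and contributes 0 to the decomposition (their contribution is
  genuinely undefined in the mean-normalized formulation).
- Interval regression refuses single-band data (scale unidentified) and
  rank-deficient designs; probit refuses degenerate outcomes, rank
  deficiency, and separation.
- Splitting any record into duplicates with shared weight leaves every
  point estimate unchanged; replicating a sample behaves like an enlarged
  independent sample for standard errors.
- Chi-square statistics in the descriptive tables are Pearson without
  continuity correction, which is the variant that reproduces published
  descriptive statistics from their printed counts; both unweighted and
  weighted variants are available because published tables do not always
  say which was used.

## Problem sizes used in the test and acceptance suites

Unit tests run at n ≤ 5,000; the recovery suite uses 200 replicates of
n = 5,000 against a single n = 10⁶ oracle; coverage uses 1,000 simulations
at n = 500; the three-route agreement check uses 1,000 random samples of
n ≤ 50. These sizes give Monte-Carlo error comfortably below the tested
tolerances while keeping the full suite around two minutes on one CPU.
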