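# Methods

## The model

A subject's clavicular maturation is represented by a latent developmental
variable

&nbsp;&nbsp;y = β·t(age) + ε,&nbsp;&nbsp;ε ~ N(0, 1),

with t the age transform and β > 0 the developmental rate on the transformed
scale. Ordered cutpoints τ₁ < … < τ_{J−1} partition the latent scale into
the J = 6 analysis groups (1, 2, 3a, 3b, 3c, 4/5), giving the cumulative
probit

&nbsp;&nbsp;P(group ≤ j | age) = Φ(τⱼ − β·t(age)).

A single slope (common latent σ) is assumed; heteroskedastic and
group-specific-slope variants appear only as the alternative hypothesis of
the fit test. The *transition age* for boundary j is t⁻¹(τⱼ/β), the age at
which the crossing probability is one half.

**Age transform.** Default t = log, the usual choice in the
transition-analysis literature (developmental spread grows with age);
t = identity is available via `transform="identity"`. All reported ages are
back-transformed to years.

## Estimation

Maximum likelihood over the unconstrained parameter vector
(τ₁, log(τ₂−τ₁), …, log(τ_{J−1}−τ_{J−2}), log β), which enforces cutpoint
ordering and slope positivity without constrained optimisation. Interval
probabilities Φ(u_hi) − Φ(u_lo) are evaluated with a tail flip (both
arguments negated when their midpoint is positive) and floored at 1e−300 to
keep log-likelihoods finite near separation.

Starting values: cutpoints from probit-transformed empirical cumulative
group frequencies shifted by t(mean age), β = 1. L-BFGS-B with the analytic
gradient is followed by Newton polishing (numerical Hessian of the analytic
score) until the gradient max-norm is ≤ 1e−6; up to three deterministic
perturbed restarts precede a convergence warning. A parameter-magnitude
guard (β > 10³, cutpoint gap > 50) flags complete separation as a warning on
the results object rather than failing silently. The fit is deterministic
given data and starting values; row order is irrelevant.

The implementation is cross-checked in the test suite against statsmodels'
ordered probit on identical data (log-likelihood, slope, cutpoints); the
model code itself has no statsmodels dependency apart from the
finite-difference helpers.

## Fit diagnostics

**Score (Lagrange-multiplier) test.** The common-slope restriction is
tested against the cutpoint-specific-slope alternative
P(y = j) = Φ(τⱼ − βⱼ t) − Φ(τ_{j−1} − β_{j−1} t). The score (analytic) and
observed information (finite-difference Jacobian of the score) of the
alternative are evaluated at the restricted MLE; the statistic is
asymptotically χ² with J − 2 degrees of freedom. Simulation under the null
(500 cohorts of n = 338) puts the empirical size at the nominal 5% within
binomial error. With J = 2 the alternative adds no parameters and the test
is reported as untestable; the same applies when the information matrix is
numerically singular (condition number > 1e12). Which alternative a given
published analysis used is generally not recoverable from its reported
p-value; ours is documented here and is the only one implemented.

**Pseudo-R².** Cragg–Uhler: [1 − (L₀/L₁)^{2/n}] / [1 − L₀^{2/n}], where L₀
is the intercept-only (multinomial) likelihood, available in closed form
from the group frequencies.

## Prediction

The normed likelihood for group j is L_j(a)/max L_j over a regular age grid
on [sample min, sample max], step 0.01 y — fine enough that grid argmax
error is an order of magnitude below the 2-decimal reporting precision (a
refinement-stability test asserts this). The 95% prediction interval is the
superlevel set above exp(−χ²₁,₀.₉₅/2) ≈ 0.1465, with threshold crossings
refined by linear interpolation between grid points. The curve is a pure
likelihood; no age prior is applied.

Terminal conventions: the lowest and highest groups have monotone curves
over any realistic age range, so their point predictions are set to the
sample minimum/maximum age and their outer interval bounds clipped to the
sample range rather than extrapolated. Inside cross-validation the
substitution values are fold-local (training-fold min/max), avoiding
leakage. The adult call is MLA ≥ 18.0 y, with the boundary age itself
counting as adult (the tie rule must be fixed somewhere; it is fixed here
and asserted in tests). Coverage of the 95% intervals, checked by
simulating 2000 subjects from a known model and predicting with that model,
is ≈ 95–97%: the Wilks inversion is slightly conservative for a single
ordinal observation, which the calibration test's ±2-point band absorbs.

## Consensus staging and agreement

The final stage per clavicle is the majority vote of the three raters, with
"not evaluable" (NE) counting as an ordinary vote category — two NE votes
exclude the clavicle, not the subject. Three-way splits are decided by the
designated adjudicating rater's re-evaluated stage, supplied as a data
column so the pipeline stays deterministic. Side concordance and the paired
Wilcoxon test operate on the full 9-level scale; collapsing to the six
groups happens only at the transition-analysis boundary. Wilcoxon zero
differences are dropped by default (classic treatment; with ~80% ties the
choice is consequential, so Pratt's method is available via
`zero_method="pratt"`). Quartiles use numpy's linear interpolation
(configurable via `quantile_method`).

Agreement: Cohen's kappa with the Fleiss–Cohen–Everitt null variance
(normal-approximation p; Monte-Carlo permutation p behind
`p_method="permutation"` for small samples); Fleiss' kappa in the classic
unweighted form (Fleiss–Nee–Landis variance) and a mean
pairwise-weighted-agreement generalisation for linear weights, which
reduces exactly to the classic statistic under identity weights;
Krippendorff's alpha from the coincidence matrix with nominal, ordinal
(default, matching the ordered scale) or interval difference functions and
missing ratings simply absent from coincidences. Unweighted statistics
include NE as an extra nominal category; weighted statistics are computed
on clavicles staged by all raters.

## Validation design

Seven constellations: 10-fold CV of the right, left, merged and
half-set-max/min datasets plus the two cross-side train/test splits, all
restricted to subjects with both sides staged. Folds are assigned at the
subject level (both rows of a subject share a fold in the merged set),
stratified by stage group after merging fold-deficient groups into the
adjacent rank; errors are pooled across folds before MAE/RMSE, matching
single-number-per-constellation reporting. Whether the original design
stratified folds or averaged per-fold metrics is typically unreported;
these choices are ours. The fold seed defaults to 20221219.

## The synthetic cohort generator

Defaults emulate the study conditions the pipeline is built for: 338 male
subjects, ages uniform on [13, 25) (uniform rather than mildly bell-shaped
by design — transition analysis is meant to be robust to reference age
structure, and a non-uniform sampler is available precisely to test that),
one latent developmental value per subject, per-side independent
adjacent-group jitter with probability 0.105 (calibrated so ~80% of true
stage pairs are identical), true transition ages (16.0, 17.4, 19.3, 20.9,
22.2) y with slope 14 on the log-age scale (within-stage age SD ≈ 1.3–1.5 y,
matching published descriptive spreads), substage mix 2a:2b = 0.6:0.4 with
2c absent and 4:5 = 0.85:0.15, rater confusion ±1 rank on the 9-level scale
with probability 0.40 (calibrated by Monte-Carlo so ~13% of clavicles draw
three distinct ratings), clavicle-level non-evaluability 0.11 (3% motion,
8% shape variants, seen identically by all raters) plus a 3% per-rater
idiosyncratic NE rate, leaving ~81% of clavicles staged by all three
raters. Identical seeds give bit-identical cohorts.

**What the generator does not emulate**, hence what passing tests do not
show about real data: rater errors are independent and strictly adjacent,
with no systematic between-rater or between-institute bias, so consensus
voting is more error-cancelling than in practice and observed (consensus)
side concordance falls below the truth-level 80%; the max-of-two-sides
("half set max") construction applied to noisy stages induces mild
model misfit that the score test correctly detects on synthetic consensus
data, whereas a well-specified cohort passes at nominal size; no secular,
population or socioeconomic effects; anatomical variants exist only as an
exclusion label. Recovery, coverage and test-size batteries therefore run
on jitter-free cohorts drawn exactly from the generating model; the
end-to-end pipeline runs on the full noisy generator.

## Problem sizes

Recovery battery: 10 seeds × n = 600 (tolerance 0.3 y chosen from the
repeated-simulation spread of recovered transition ages at that n);
bias-shrinkage ladder at n ∈ {150, 600, 2400}; coverage at n = 2000;
score-test size over 500 null cohorts of n = 338; the synthetic study and
its 7-constellation validation at n = 338. These sizes keep every battery
well-resolved while the whole suite and the acceptance script each run in
well under a minute on one CPU.

## Known limitations

- Single-slope (common-σ) model only; no covariates other than age, no
  bilateral random effects (sides are handled through the validation
  constellations instead), no Bayesian estimation.
- The likelihood-ratio interval's finite-sample coverage is approximate
  (slightly conservative) — see Prediction above.
- Weighted multi-rater kappa has no standard closed-form null variance; its
  p-value is reported as undefined.
- No combination of clavicle evidence with dental or hand-bone evidence;
  single-factor pipeline only.
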