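# Methods

`setsim` implements a pooled-cohort analysis of acute drug response of the
kind used when raw data from many small experimental studies are combined:
repeated drug sessions nested in subjects, predictors measured by different
questionnaires in different studies (hence large, block-structured
missingness), and a dozen-plus bounded outcome scales.  This note documents
the statistical model, the procedure, the synthetic cohort the package uses
to test itself, and the numerical and design choices that were genuinely
open.

## The outcome model

For outcome scale $y$ measured at session $i$ of subject $j$,

$$ g(y_{ij}) = x_{ij}^\top \beta + b_j + \varepsilon_{ij}, \qquad
   b_j \sim \mathcal N(0, \tau^2), \quad
   \varepsilon_{ij} \sim \mathcal N(0, \sigma^2), $$

a linear mixed model with a random intercept per subject.  Random dose
slopes and study-level intercepts are deliberately out of scope: the
varying-intercept model is the supported structure.  $g$ is a Box-Cox
power transform chosen per outcome (below); after transformation the
outcome is z-scored within each completed dataset, and continuous
predictors are centred and divided by **two** standard deviations while
binary predictors stay on 0/1.  Since a non-degenerate binary variable has
SD ≈ 0.5, every coefficient is then the expected outcome change (in
outcome SDs) for a two-SD — or category — change of its predictor, making
coefficients comparable across predictors and across outcomes.

### Fitting

Writing $\theta = \tau^2/\sigma^2$, the marginal covariance of a subject
with $s$ sessions is $\sigma^2 (I_s + \theta J_s)$, whose inverse and
determinant are closed-form.  All fits profile $\beta$ and $\sigma^2$ out
of the (restricted) likelihood and optimize the one remaining parameter
$\theta \ge 0$ numerically, using group-wise sufficient statistics
($Z^\top Z$ plus sums of outer products of group-wise column sums bucketed
by group size).  A fit on any subset of predictors, or on any bootstrap
resample, is then a matrix slice plus a 1-D search — this is what makes
the resampling-based selection below affordable (hundreds of thousands of
fits per study).  The hot path is compiled with numba when available
(golden-section search on $\log\theta$ with the $\theta = 0$ boundary
checked explicitly); a scipy fallback produces the same results to
optimizer tolerance.  The implementation is cross-checked against
`statsmodels` `MixedLM` (ML and REML) in the test suite.

Wald tests use the Gaussian (z) reference rather than a t with
approximated denominator degrees of freedom: df are not well defined in
mixed models, final inference is posterior-based anyway, and the selection
procedure only needs a consistent ranking rule.

## Outcome transformation

The outcome scales are non-negative visual-analogue scores with
right-skewed residuals.  The Box-Cox power $\lambda$ is selected per
outcome by maximizing the profiled mixed-model log-likelihood of the
transformed response **plus the Jacobian term** $(\lambda-1)\sum\log y$,
over the grid $\{-1, -\tfrac12, 0, \tfrac12, 1\}$ refined by bounded
minimization between the bracketing grid points.  The optimum is snapped
to the nearest *named* transform within a radius of 0.1 — $\log y$,
$\sqrt y$, $-1/\sqrt y$, identity — because interpretable named transforms
are preferred over raw powers; the named forms are monotone affine
relabelings of the Box-Cox family and therefore likelihood-equivalent.
Exact zeros (legitimate on visual-analogue scales) are handled by adding
half the smallest positive observed value before log-type transforms; the
offset is recorded in the transform spec.  $\lambda$ is profiled jointly
over all sessions, not per study.  Predictors are never transformed.

## Missing data

Missingness in the emulated pool is driven almost entirely by study
design — a questionnaire not administered in a study is missing for every
one of its subjects — so the mechanism is missing at random given study
membership.  Imputation is by fully conditional specification (chained
equations): predictive mean matching (5 donors, type-1 matching with an
approximate Bayesian parameter draw) for continuous scales, a
proportional-odds model for the ordered drug-use category, logistic
regression for binary flags.  Conditional models receive an approximate
Bayesian draw of their parameters before each imputation so the m
completed datasets reflect parameter uncertainty ("proper" imputation).
Separation or singular conditional fits fall back to ridge-stabilized
estimation (logged); a failed proportional-odds fit falls back to an
empirical-frequency draw (logged).

Predictor sets for each conditional model are screened by pairwise
correlation on available cases, default threshold |r| ≥ 0.15, with
numerically coded categories; designated auxiliary scales (two convergent
personality inventories and an imagination scale) are always eligible for
their partner variable, and the outcomes participate in imputation via
subject-level summaries.  An empty post-screen set falls back to the five
most-correlated candidates.  Subject-level variables are imputed on the
one-row-per-subject table and broadcast to sessions, so a subject can
never carry two imputed values of a trait.

Defaults: m = 20 imputations in the full profile (5 in the scaled
profile), 15 chain iterations (block-missing designs stabilize in a
handful of sweeps; convergence is checked by the between/within-chain
variance ratio on imputed-value chain means, flagged above 1.2).
Multicollinearity is screened by variance inflation factors within every
completed dataset; the analysis expects max VIF < 3 and warns otherwise.

## Variable selection

Models are built by a two-step bootstrap wrapped around backward
elimination:

1. Within each of the m completed datasets, B bootstrap samples are drawn
   from individual **sessions** with replacement at the original n.
   Backward elimination runs on each sample: refit, drop the predictor
   with the largest Wald p among those exceeding α = 0.157, repeat.  That
   stopping rule makes Wald-based dropping of a 1-df predictor equivalent
   to AIC-based selection, since $P(\chi^2_1 > 2) = 0.157$.  The subject
   random intercept and the fixed intercept are never candidates.
   Predictors appearing in at least 50% of the m × B final models are
   retained.
2. The same procedure restarts from the retained set; exact final-model
   identities are recorded and the modal model is the *most stable model*.

Resampling sessions ignores the within-subject clustering; this is the
procedure as specified, and its consequences are visible in the package's
own calibration study: the per-predictor probability that a true-zero
predictor reaches the 50% cutoff is ≈ 0.11 per dataset, slightly above
the α-implied 0.10.  A subject-level resampling mode exists behind a flag
(default off).  Ties on the largest p are broken by dropping the term
later in the declared order; bootstrap seeds are derived per
(imputation, replicate) from the master seed, so runs are reproducible and
parallelizable.  The two sequential-difference dummies of the ordered
drug-use variable are eliminated individually.  Frequentist model
averaging over competing models is explicitly not performed.

First-order interactions between dose and every other retained predictor
are screened one at a time within the most stable model, with pooled
posterior p-values reported at 0.05 and 0.01; interactions are *reported,
never added*.  When dose varies little within a level of a binary partner
(within-level SD below half the overall SD), the row carries a
low-variability warning because the interaction is then poorly
identified.

## Inference after imputation

For the final model of each outcome, a Gibbs sampler draws from the
posterior of the mixed model on every completed dataset — flat prior on
β, half-Cauchy(2.5) priors on both SDs via inverse-gamma scale mixtures
(all conditionals stay conjugate); defaults 500 burn-in, thinning 2,
2000 retained draws per dataset, reproducible from seed, with an
effective-sample-size floor that raises on non-convergence.  Equal numbers
of draws are then mixed across the m datasets; the mixed draws approximate
the posterior of the pooled parameters, giving the posterior mean, the
narrowest 95% highest-posterior-density interval, and the two-tailed
posterior p-value $2\min(\Pr(\beta>0), \Pr(\beta<0))$ floored at
2/(total draws).  Significance stars at 0.05/0.01/0.001 annotate the
coefficient tables.

Rubin's rules on per-imputation posterior means and variances supply the
between/within decomposition: $T = \bar W + (1+1/m)B$, relative increase
in variance $\mathrm{RIV} = (1+1/m)B/\bar W$, and fraction of missing
information $\mathrm{FMI} = (\mathrm{RIV} + 2/(\nu+3))/(1+\mathrm{RIV})$
with $\nu = (m-1)(1+1/\mathrm{RIV})^2$.  When auxiliaries are informative,
FMI falls below the raw missing-data rate — a property the calibration
study verifies.

Model fit is summarized by the fixed-effects $R^2$ built from the joint
Wald F for all q non-intercept fixed effects:
$R^2 = (qF/\nu_2)/(1 + qF/\nu_2)$.  The denominator df use the residual
(containment-style) approximation $\nu_2 = n - q - 1$ rather than a
Kenward-Roger correction; at n ≈ 400 the difference is negligible and the
choice is recorded in the diagnostics object.  $R^2$ is reported for both
the full and the simplified (selected) model per outcome — the gap is the
selection-induced optimism — and pooled across imputations by the
arithmetic mean (median behind a flag).

## The synthetic cohort

Because the human data the analysis design comes from were never
deposited, the package carries a first-class generator that emulates the
pooled structure: 23 studies, 261 subjects, 409 sessions by default, with
1-5 sessions per subject.  Dose is sampled from the published five
category frequencies (115-315 µg/kg, represented continuously);
assessment time from its five categories (log-minutes enters every model
as a covariate); ~12% of sessions belong to PET-imaging studies, within
which only the two mid-range doses occur (so the dose×PET interaction is
genuinely poorly identified, as the screen's warning path expects).
Subject predictors follow the published descriptive statistics (Gaussian
scores with the reported means/SDs, Bernoulli flags, categorical
education and drug-use frequencies); the imagination scale correlates
0.77 with trait Absorption, the auxiliary personality scales 0.6 with
their partners, and the two pre-drug mood scales 0.5 with each other —
all other cross-correlations default to zero because no further structure
is documented.  The hallucinogen-naive flag can only switch from naive to
experienced across a subject's sessions.

Outcomes are generated on the transformed scale as
$\text{intercept} + x^\top\beta + b_j + \varepsilon$ with configurable
$\beta$ (per-two-SD units), $\tau$ = 0.5 and $\sigma$ = 0.7 by default
(ICC ≈ 0.34), then mapped through the inverse named transform — log for
five scales, $-1/\sqrt y$ for the anxiety scale, square root for the
rest.  Inverse-transform values outside the raw domain are clipped to the
raw-scale floor of 0 (and the $-1/\sqrt y$ linear predictor capped just
below zero), with counts logged.  The default generating hierarchy — dose
0.8, one pre-drug state scale 0.4, one trait scale 0.4, everything else
zero — mirrors the qualitative importance ordering such pooled analyses
report, so recovery tests are meaningful.

Block missingness assigns each instrument a set of non-administering
studies chosen to approximate the published per-instrument missing rates
(up to 72% for the trait-absorption scale); an extra cell-wise MCAR rate
is available.  What the generator does **not** emulate: questionnaire
items (only scale scores), placebo or receptor-blocker sessions, outcome
ceilings, non-Gaussian trait distributions, and any dependence of
missingness on unobserved values.  Passing tests therefore demonstrate
correctness of the machinery under a faithful-but-idealized data model,
not robustness to real-data pathologies.

## Reference simulation studies

The acceptance harness (also exposed as `setsim.recovery`) fixes the
package's reference operating conditions, chosen once at desk scale:

- **Selection recovery** — 50 replicates of 400 sessions / 200 subjects
  in 10 studies; ten candidates with effects {0.8, 0.4, 0.4}; m = 5,
  B = 50.  Block missingness is placed on null candidate scales (ZKPQ
  40%, distress 30%) and on the auxiliaries (25%/20%), leaving the
  true-effect predictors observed: this study measures selection power
  and HPD coverage, while the cost of missingness on a modelled predictor
  is quantified separately by the calibration study.  Measured (seed 1):
  mean step-1 inclusion 1.00 / 0.92 / 0.99 for the three true effects,
  null predictors below the 50% cutoff in 89% of predictor×replicate
  pairs, 93% HPD coverage of the generating coefficients.
- **Imputation calibration** — 30% MCAR on two scales with correlated
  auxiliaries, m = 10: pooled coefficients within 0.05 SD of the
  pre-deletion fit and FMI below the raw missing rate for both.
- **Box-Cox recovery** — λ̂ within 0.05 of 0 under a log link and within
  0.01 of 1 under an identity link at n = 400 (snapping disabled).
- **Interaction-screen null calibration** — 20 replicates × 23 dose
  interactions with none generated: 24 of 460 tests at p < 0.05
  (rate 0.052), inside the binomial 95% band.

All numbers above are recomputed, not stored, by `scripts/acceptance.py`
and the test suite.

## Numerical choices and edge cases

- θ search: coarse log-grid on $[e^{-8}, e^{9.2}]$ plus golden-section
  refinement to ~1e-5 on the log scale; θ = 0 always evaluated.
  Residual sums of squares floored at 1e-12 (perfect-fit designs).
- Singular designs raise an error naming the collinear columns; a
  singular bootstrap resample is redrawn (counted and reported).
- PMM donor pool truncated to the number of observed cases when smaller
  than 5.
- Proportional-odds draws use the packed-parameter covariance; a
  non-finite covariance triggers the logged fallback.
- HPD via the sorted-window minimizer (exact for unimodal samples);
  pooled p clamped to [2/N, 1].
- Zero-variance predictors are an error at rescaling time, named.

## Known limitations

Session-level resampling inside clustered data understates within-subject
dependence (documented above; subject-level mode available).  The Gibbs
sampler covers the random-intercept model only.  Edwards-type $R^2$ with
residual df is slightly liberal for small n.  Chain diagnostics summarize
imputed-value means only; with chains initialized from the observed
margin, a conditional model *missing* its informative predictors shows no
drift (it stays at the biased margin), so imputation quality under broken
dependencies is assessed by bias against pre-deletion truth in the test
suite, not by the drift statistic.
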