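# Methods

## The trajectory model

Per-click accuracy on the spatial-span task is modelled as an exponential
approach from a starting level S toward an asymptote A over trials:

    p(t, w) = A(w) + (S(w) − A(w)) · 2^(−(t − 1) / τ),   τ = 2^ρ + 2

with S and A inverse-logit transforms of linear predictors and t the
1-based trial index over the full 68-trial sequence (catch trials
included).  Base-2 decay makes τ exactly the 50%-of-change time constant:
at trial 1 + τ the curve has moved half of the way from S to A.  The +2
offset keeps τ > 2 trials, excluding degenerate instant-change solutions
and aiding convergence.  The binary-log scale for ρ gives the rate an
unbounded parameterization.

Linear predictors for S and A carry the mean-centred set-size covariate
(w − 6.5) with population-level slopes — per-participant psychometric
structure arises from participant intercepts plus the shared slopes — and
fixed effects of feedback condition and task order (coded ±0.5).  The
condition effects enter all three parameter-level predictors; placing them
on all three is the conservative superset and each defaults to zero in the
generator.  Participants have random intercepts on σ0 (start logit), α0
(asymptote logit) and ρ only.

Assumptions worth stating: clicks are conditionally independent given the
trial's predicted accuracy (no within-sequence position model — the first
and last item of a sequence share one probability); set-size slopes are
homogeneous across participants; and the trajectory is monotone (a single
exponential cannot represent warm-up followed by fatigue).

Catch trials (set size 3) are included in the likelihood with the same
centred covariate (3 − 6.5 = −3.5); `FitConfig(include_catch=False)`
excludes them.  Including them is the default because the data are fully
disaggregated and nothing in the design makes catch clicks qualitatively
different; the psychometric slope extrapolates to the very easy condition.

## Likelihood, priors, numerical choices

The likelihood is Bernoulli per click: Σ y·log p + (1−y)·log(1−p).  Linear
predictors are clipped at ±35 before the inverse logit (logged at debug
level when triggered) and p is clipped to [1e−12, 1−1e−12] inside the
fitter, so the objective is always finite; the standalone
`log_likelihood` raises a `SaturationError` instead of silently returning
−inf when a saturated probability disagrees with the outcome.

Priors are weakly informative on link scales: Normal(0, 5) on the three
population means, Normal(0, 2) on set-size slopes and condition effects,
half-Normal(1) on the three random-effect SDs.  All widths sit in
`PriorConfig` and are logged with every fit.

## Fitting

**map-fast.**  The joint posterior mode over participant deviations *and*
their SDs does not exist in the centred parameterization (the density is
unbounded as any SD → 0), so two measures are taken.  First, deviations
are stored non-centred (u = sd·z), where the funnel singularity
disappears.  Second, the SDs are not maximized jointly at all: a
Laplace-EM loop alternates (a) L-BFGS maximization over everything except
the SDs, using analytic gradients (verified against numerical
differentiation in the tests), and (b) an EM update of each SD from the
fitted deviations plus their Laplace posterior variances (3×3 Fisher
information per participant), solved in closed form together with the
half-normal hyperprior.  The loop stops when no log-SD moves by more than
1e−3 (cap 40 iterations).  A full 87-participant fit takes a few seconds.
Population-effect standard errors come from a finite-difference Hessian of
the population block at the mode, conditional on the modal random effects
— adequate for reporting, mildly anticonservative; interval-based claims
in the tests use the full-Bayes mode instead.

**full-bayes.**  Affine-invariant ensemble MCMC (emcee) over the same
posterior, initialized in a small ball around the map-fast solution.  The
default budget mirrors the reference analysis (4 chains × 5000 iterations,
first 3000 discarded); walkers are split into `chains` groups to compute
split-R̂ and ESS via arviz, with R̂ ≤ 1.05 as the convergence criterion
(non-convergence is reported, never hidden).  Because an ensemble needs
≥ 2·ndim walkers and ndim grows with the cohort (14 + 3n), full-Bayes is
practical for small-to-moderate cohorts; the test suite exercises it at
8–12 participants with 1200 iterations, where it agrees with map-fast in
rank (Spearman ≥ 0.9) — the package's own scaling choice for routine runs.

**Extraction.**  Participant-level point estimates are the participant's
posterior summaries at the centred set size with condition terms excluded:
initial accuracy logit⁻¹(σ0_i), final accuracy logit⁻¹(α0_i), rate ρ_i
(larger = slower), plus raw overall accuracy (click-level mean), the
field's conventional aggregate.

## Synthetic cohorts

The generator is the forward form of the model above: latent (σ0, ρ, α0)
per participant from independent normals on the link scales, clicks drawn
per trial over the fixed schedule, Gf built directly on the latent scales.

Defaults (frozen after a pilot identifiability calibration, before any
acceptance run): start mean −0.9 (≈ 0.29 accuracy at the centred set
size), asymptote mean 1.6 (≈ 0.83), rate mean 2.5 (τ ≈ 7.7 trials — half
the change inside the first series, near-asymptotic behaviour over the
back half), SDs 0.7 / 0.9 / 1.2, set-size slopes −0.30 / −0.35 logits per
item.  These give plausible span-task accuracy ranges (set-size-8 harder
than set-size-5, catch trials near ceiling) and make all three components
recoverable from 68 trials; the rate spread (sd 1.2) is the component with
the least per-participant information, and smaller spreads leave it poorly
identified.

Gf is β_asym·z(α0) + β_rate·z(ρ) + ε with ε ~ Normal(0, 1), then
standardized; there is no σ0 term, so the start→Gf path is exactly null
(and the partial correlation of Gf with σ0 given the other two latents is
zero).  The loadings are solved in closed form so the population
correlations are r(α0, Gf) = +0.33 and r(ρ, Gf) = −0.30:
β = target·D with D = 1/√(1 − (0.33² + 0.30²)), giving 0.3687 and −0.3352.
A 500-replicate Monte-Carlo check in the tests confirms the calibration at
the study size.

What the generator does *not* emulate: within-sequence position effects,
serial dependence between trials, fatigue or break effects, item-level
matrix-reasoning responses (Gf is generated as a score because the
analysis consumes one standardized composite per participant), and
non-normal latent distributions.  Passing tests therefore demonstrate that
the estimator chain is correct and well-calibrated *under the model's own
assumptions*, not that real span data satisfy those assumptions.

## Screening

Matrix-reasoning chance screening uses the exact binomial test: the
threshold is the largest score k with P(X ≥ k | n_items, 12.5%) ≥ α, so
scores ≤ k are excluded ("not significantly above guessing"); exactness
(not a normal approximation) matters at small item counts.  Item counts
are configuration inputs — they are properties of the instruments, and the
instrument sizes are not fixed by the analysis.  Catch-trial screening
excludes accuracy strictly below 50%; the boundary case (exactly 0.5) is
retained — the criterion excluded nobody in the reference cohort, so the
boundary is unconstrained and the lenient reading is documented here.

## Associations

- **Gf composite**: mean of the two within-task z-scores (cohort mean/SD).
- **Correlations**: Pearson (optionally Spearman), with seeded paired
  bootstrap percentile 95% intervals, 10,000 resamples by default — the
  simplest reproducible bootstrap; coverage at n = 87 is verified to sit
  in [0.92, 0.97] in the tests.
- **Bayes factor**: two-sided default prior, stretched-beta on the
  correlation with width 1/3 (the conventional "medium" default; the
  width is a config field).  Computed by numerical integration of the
  reduced likelihood of the sample correlation in log space, cross-checked
  against the closed hypergeometric form of the same integral (which also
  takes over near |r| = 1, where quadrature loses relative accuracy).
  Reported as log base 3 so ±1 are the 3:1 evidence thresholds.
- **Joint regression**: OLS of Gf on rate and final accuracy, classical
  t-based 95% CIs, and ΔR² per predictor defined semi-partially (drop in
  R² when that predictor is removed) — the standard reading of "remains
  reliable when controlling for the other".
- **Robust check**: Huber M-estimation (default tuning) of the same model.
- **Power**: Fisher-z approximation with the small-sample mean-bias term,
  power = Φ(√(n−3)·(atanh r + r/(2(n−1))) − z_{1−α/2}) plus the opposite
  rejection tail (so the null case equals α exactly).  The bias-corrected
  form, used by the standard power tools, reproduces the design value
  0.295 at n = 87 and 80% power; the uncorrected form gives 0.296.
  Inversion to the minimum detectable correlation is by root-finding.

## Problem sizes and runtime choices

Routine test fits use map-fast at the full study size (87 participants,
37,236 clicks; seconds per fit).  The end-to-end dissociation check runs
10 replicate studies with 500 bootstrap resamples each; the bootstrap
coverage check uses 1000 replications × 600 resamples; full-Bayes tests
use 8–12 participants × 1200 iterations.  These sizes are the package's
own choices for routine verification; every size is a parameter and can
be raised.

## Known limitations

- map-fast reports no participant-level posterior SDs (point estimates
  only); use full-bayes when participant-level uncertainty matters.
- The Laplace-EM SD estimates are approximate; weakly identified SDs
  (especially the rate) tend to be shrunk below the generating value,
  which over-shrinks participant rate estimates without changing their
  ranking materially.
- The ensemble sampler's split-R̂ groups walkers rather than independent
  restarts; pathological multimodality could in principle evade it.
- With population correlations of ±0.3 at n = 87, single-study sample
  correlations of estimated components fluctuate by ≈ 0.1; any single
  synthetic study can miss one element of the dissociation pattern, which
  is why the end-to-end property is evaluated over replicates.
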