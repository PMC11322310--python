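# Methods

This note records the modelling conventions, numerical choices and design
decisions behind `gazeddm`, in the spirit of a model-documentation page for
a statistical package.

## Task representation and exclusions

Options are small lotteries over non-negative outcomes; the designs this
package targets pair a safe option (one outcome, p = 1) with a risky option
(one non-zero outcome with probability p, else 0). Problems are classified
as `risky.better` or `safe.better` by which option has the higher EV;
EV ties are detected with an absolute tolerance of 1e-9 (outcomes are
integers or simple grid fractions, so ties are intended ties). Equal-EV and
safe-vs-safe problems carry no decision-quality signal and are excluded, as
are trials with no fixation in either option AOI. Exclusion logs partition
the removed records by reason. Monetary amounts are plain floats in
experimental-currency points; screen layout (left/right, top/bottom) is
carried as metadata only and never affects analysis.

## The simulator

`simulate.py` integrates the aDDM at 1-ms resolution. Each accumulator
receives an independent N(0, σ) sample per step, so the relative decision
variable RDV = DV_A − DV_B has per-step noise SD σ√2; the simulator
integrates RDV directly with that SD, which is distributionally identical
to simulating the two accumulators and much faster. Termination uses
|RDV| ≥ α/2 with a `>=` comparison; under continuous noise an exact tie at
zero has probability zero, so no further tie-break is needed. The
non-decision time t₀ is added to the step count after termination rather
than simulated. Runs exceeding `max_steps` (default 20,000 steps = 20 s)
raise a truncation error carrying the current |RDV|; wide boundaries
genuinely produce multi-second tails, so analyses that push α upward should
raise `max_steps`.

The fixation process is an explicit model component only for simulation
(estimation conditions on observed fixations): the first fixation lands on
either option with equal probability, fixations then alternate, and dwell
durations are discretized Gamma draws (shape 2, mean 400 ms per option by
default). Dwell-time bias toward one option is implemented by scaling the
two options' mean dwells; a replay process re-plays recorded fixation
sequences (extending by alternation if the sequence runs out), which is the
default posterior-predictive mode.

## Likelihood and unit conventions

`wfpt.py` evaluates the first-passage-time density of a constant-drift
Wiener process between two absorbing boundaries with relative start 0.5,
unit diffusion coefficient, and time in seconds. The zero-drift kernel uses
the small-time (image sum) and large-time (eigenfunction) series, switched
at scaled time tt = t/α² = 0.35 with 7 terms each; at that switch point both
truncations are converged to ~1e-10 (verified against an 80-term reference),
so the density is exact to machine precision over rt − t₀ ∈ [1e-4, 60] s.
Times at or below t₀ yield log-density −inf rather than an exception. The
absorption probability at the upper boundary has the closed form
1/(1 + exp(−δ·α)) at relative start 0.5 and is used for posterior
predictive choices.

The trial drift is assembled from gaze proportions and EVs as

    δ = β₀ + β₁(gaze_B·V_B − gaze_A·V_A) + β₂(gaze_A·V_B − gaze_B·V_A).

Averaging the simulator's per-step RDV increments over a trial shows this
expression equals the mean drift *toward option B*. Because the upper
boundary is defined as the higher-EV option, the likelihood relabels the
options per trial so that B is the higher-EV option; β₀ thereby becomes a
drift bias toward the higher-EV option. This orientation is pinned by a
simulate→fit round-trip test and recorded in each fit's metadata.

Conversions between simulator units (ms steps, per-accumulator σ, boundary
α_sim on the RDV scale) and likelihood units (seconds, unit diffusion):

    β₁ = d·√1000 / (σ√2)        α = α_sim / (σ√2·√1000)       t₀ = t₀_ms/1000

These ship as `sim_to_likelihood_units` / `likelihood_to_sim_units` and are
covered by round-trip and closed-form tests. Note the likelihood treats the
within-trial time-varying drift as its gaze-weighted constant average; this
approximation (standard for this estimation approach) is exact for
constant-gaze trials and introduces a small attenuation of θ estimates for
strongly alternating gaze, visible as a modest negative bias in recovery
studies while leaving rank-order recovery strong.

## Per-participant estimation

Each participant is fitted separately and in a single step: free parameters
are β₀, β₁ (shared across problem types), β₂, and α split by problem type,
plus t₀ — seven parameters. θ = β₂/β₁ is computed per posterior draw and
then summarized, separately per problem type. Numeracy never enters the
fit. Priors: β's ~ Normal(0, 5) on the likelihood drift scale; α ~ Gamma(2,
1) truncated to α > 0.1; t₀ ~ Uniform(0, min observed RT − 1 ms) — weakly
informative choices that comfortably support the plausible ranges of all
parameters.

The sampler is differential-evolution Metropolis (DE-MC): a population of
chains proposing jumps along scaled difference vectors of other chains,
which self-adapts to the strong β₁–β₂ posterior correlation induced by the
drift regressors. Defaults are 12 chains × 8,000 steps with the first half
discarded, which brings split-R̂ below 1.01 on default synthetic fits in
about 6 s per participant; heavier, publication-style settings (e.g., 30
chains × 10,000 draws) are a config away. The population needs at least
~2× the parameter count of chains to mix, which is why the default chain
count is 12 rather than a smaller conventional value. Initialization draws
a finite-posterior population around a plausible center with jitter,
re-drawing as needed; a hard error is raised if no finite starting
population is found. R̂ is computed with arviz's split-R̂; parameters with
R̂ > 1.01 are flagged. θ intervals straying outside [−0.25, 1.5] set a QC
flag rather than being constrained: the ratio is reported as-is.

Posterior predictive checking computes, per trial, the closed-form choice
probability at the posterior-mean parameters given the observed gaze, and
either predicts the modal choice (default) or samples choices; the reported
match rate is the fraction of trials where the prediction equals the
observed choice.

## Bayesian GLMs and mediation

All mediation models place Normal(0, 1) priors on slope coefficients and
Normal(0, 5) on the intercept; credibility means the two-sided 95%
posterior interval excludes zero. Continuous predictors are z-standardized
(sample-SD, n−1 convention) within each analyzed subset (all /
risky.better / safe.better), since subset models report distinct scales.
No multiple-comparison correction is applied; the shrinkage priors are the
only regularization.

Posterior computation is deterministic: logistic models use the MAP under
the Gaussian prior with a Laplace (inverse-Hessian) Gaussian posterior;
Gaussian models with a participant random intercept estimate variance
components by REML (statsmodels MixedLM, with a one-way ANOVA moment
estimator as fallback for degenerate small-group designs) and then use the
exact conjugate Gaussian posterior for the fixed effects; the optional
logistic random-intercept variant profiles the random-intercept SD through
the Laplace marginal. At the sample sizes involved (hundreds to thousands
of rows) these approximations are indistinguishable from long MCMC for the
reported quantities, and interval calibration is verified by simulation
(93–97% coverage). Draws from the approximate posterior provide pointwise
log-likelihoods for PSIS-LOO (arviz); loo-IC = −2·elpd_loo. For
random-intercept Gaussian models the LOO pointwise likelihood uses the
marginal per-row variance σ_e² + σ_u².

Model roles: the TEM regresses choice of the higher-EV option on numeracy
(logistic, trial level, no random intercept by default — matching the
original analysis scheme; a switch adds one). MMs regress each process
measure on numeracy × problem type with a participant random intercept,
`risky.better` as reference level; attention is modelled at trial level, θ
and α at their native participant-by-type grain, ignoring the estimation
uncertainty of the posterior means. DEMs add z-standardized process
measures to the TEM; constant measures are dropped with a warning so the
model stays well-posed (and the numeracy coefficient is then exactly the
TEM's). `mediation_summary` reports absolute and relative reduction of the
numeracy coefficient versus the TEM and requires identical outcome rows.
Note that trial-level TEMs without random intercepts are anti-conservative
for participant-level predictors (numeracy is constant within participant),
so null-calibration checks of the whole pipeline use the random-intercept
variant.

## Synthetic-data generator

The generator emulates the study design the analysis assumes, and its
defaults are the package's study conditions: 80 participants × 100
safe-vs-risky problems; integer outcomes in [1, 95]; risky-outcome
probabilities from a 0.05 grid (mimicking experienced relative frequencies
under a yoked design); ≈49% risky.better problems; numeracy from a
discretized Normal(3.7, 1.6) truncated to 0..7 (matching the reported
sample mean/median). Equal-EV and safe-safe problems are emitted only when
injection rates are set, to exercise the filters.

Generative parameters live on the likelihood scale and are converted for
simulation. Per participant: θ is a clipped linear function of
z-standardized numeracy (intercept 0.44; slopes 0.09 risky.better / 0.03
safe.better; between-participant SD 0.18, matching the wide spread of
individual θ estimates reported for this task class; clipped to [0, 1.3]
with clip counts logged); α is log-normal (median 3.2, log-SD 0.20) with
log-linear numeracy slopes 0.05 and a +0.09 log offset for safe.better; the
attention target (gaze share on the higher-EV option) is a clipped linear
link (intercept 0.543, slopes +0.012 / −0.018) realized through dwell-time
bias; β₁ is log-normal around 0.06 and t₀ around 0.35 s. Decision quality
is linked to numeracy *only* through these process parameters — there is no
direct numeracy → choice path — which is what makes the generator the
ground truth for mediation-recovery experiments. Intercepts and slopes were
placed so that cohort-level numeracy–parameter correlations land in a
plausible 0.2–0.6 band and fitted mediator-model coefficients have the
order of magnitude reported for this task class.

What the generator does *not* emulate: saccade dynamics and fixation counts
beyond a simple alternating Gamma-dwell process, within-trial non-decision
variability, post-error slowing or other sequential effects, response
biases tied to screen layout, and measurement error in numeracy. Passing
tests therefore certify the pipeline's statistical machinery under the
model's own assumptions, not the behavior of any real dataset.

## Problem sizes used in the shipped checks

The validation suite runs desk-scale versions of the package's standing
experiments: density-vs-simulation equivalence on a 3×3×3 (δ, α, t₀) grid
with 1e5 bridge-corrected random-walk simulations per point; parameter
recovery with 40 participants × 150 trials at the default sampler settings;
GLM calibration with 200 replications per family at n = 2,000; and
mediation recovery with 20 replications of 64-participant × 100-problem
cohorts at a lightened sampler setting (8 chains × 1,200 steps) — cohorts
much smaller than 64 lack the between-participant power that carries the
total-effect model, so the participant count is scaled down only modestly
from the 80 of the study conditions. The
acceptance script runs the full 80 × 100 study conditions once. These sizes
were chosen as the smallest at which the targeted statistical properties
are decisively measurable.

## Known limitations

- The constant-drift (gaze-averaged) likelihood is an approximation to the
  aDDM's time-inhomogeneous process; θ point estimates are mildly
  attenuated when gaze alternates strongly within trials.
- Gaze is endogenous in the aDDM (the final fixation is truncated at the
  boundary crossing), and the estimation conditions on it as if exogenous —
  a property inherited from the estimation approach itself.
- Posterior means of θ and α enter the mediation GLMs as known quantities;
  their posterior uncertainty is not propagated.
- The θ = β₂/β₁ ratio is weakly identified for participants whose gaze
  hovers near 0.5 on most trials; the QC flag marks the widest intervals.
- No hierarchical pooling across participants, collapsing boundaries,
  starting-point bias, or across-trial drift variability.
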