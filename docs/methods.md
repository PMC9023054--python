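# Methods

`dualsource` models choice behaviour in a two-source probabilistic
learning task: on every trial an agent chooses between two options using
a *primary* information source (the option directly indicated by reward
feedback) and a *secondary* source (advice whose correctness must be
inferred from feedback). Both sources follow independent schedules that
alternate stable phases (reward probability constant for more than 30
trials) and volatile phases (probability reversing every 10–20 trials).

## Task schedules

A session is 120 trials by default. Each source's schedule is a list of
blocks; the default splits the session into one stable and one volatile
block of 60 trials each, with the high probability level q = 0.8 (stable
blocks hold q; volatile blocks alternate between q and 1 − q). Reversal
intervals inside volatile blocks are drawn uniformly from {10, …, 20},
with the admissible range of each draw narrowed so that the final run
also respects the bounds — no truncated short runs. Because block order
confounds phase type with session position (the first trials after a
flat prior always show fast adaptation), cohort- and benchmark-level
simulations rotate four counterbalanced block orders (stable or volatile
first, for each source), emulating random assignment to
pseudo-randomised schedules.

Advice is coded relative to the primary-congruent option: 0 = the advice
endorses it. The advice-correctness indicator is therefore
`r XOR advice`, which is exactly the inference available to a
participant after feedback; no additional noise is added to it.

## The dual-source Rescorla–Wagner model

Two delta-rule predictors run in parallel:

    V(i+1) = V(i) + α · (outcome(i) − V(i))

one on the reward outcomes r(i) (primary belief V_p), one on the
advice-correctness indicator (secondary belief V_s). Each predictor
switches its learning rate with the phase label of its own schedule,
giving four rates: α_primary_stable, α_primary_volatile,
α_secondary_stable, α_secondary_volatile. The response model converts
the secondary belief through the advice weighting
`V_aw = |advice − V_s|`, mixes the sources with the weight ζ ∈ (0, 1),

    V_c = ζ · V_aw + (1 − ζ) · V_p

and maps the combined belief to a choice probability with the
unit-square sigmoid

    P(y = 1 | V_c) = V_c^β / (V_c^β + (1 − V_c)^β)

where β > 0 is the inverse decision temperature. Beliefs start at
v0 = 0.5 (not fitted) and are clipped to [1e−6, 1 − 1e−6] before the
sigmoid and after each update; the sigmoid is evaluated in log space so
that large β never overflows. Trials with a missing choice still update
beliefs (feedback was shown) but contribute nothing to the likelihood.

The model family is the 2 × 2 × 2 factorial of {α split by source} ×
{α split by phase volatility} × {ζ free vs fixed at 0.5}; the full model
has six free parameters (4 α, ζ, β).

## Bayesian optimal learner

The normative benchmark is a grid filter over three latents: the reward
probability p, its volatility v (how fast p moves) and a trend
parameter k (how fast v moves). One step applies a Gaussian random walk
to log v (sd k), then a beta diffusion to p (mean p, concentration 1/v,
so Var ≈ p(1−p)·v), then the Bernoulli likelihood of the outcome. The
prior is uniform over the grid, which makes predictions exactly
antisymmetric under relabelling of the two options. `p_hat(t)` is the
posterior-predictive mean computed *before* trial t's outcome, so
`p_hat(1) = 0.5`.

Defaults: 50 midpoint cells for p, 30 log-spaced points for
v ∈ [5e−4, 0.25] and k ∈ [0.05, 5]. Transition kernels are discretised
by integrating the density over destination cells (CDF differences) and
averaging over source positions within a cell (4-point Gauss–Legendre),
and are cached per grid specification.

Numerical accuracy: on a 120-trial sequence, doubling all grid
resolutions changes per-trial predictions by up to ~2e−2 at the default
resolution and ~6e−3 at a 4× finer one. The slow (first-order)
convergence is a property of the hierarchical filter itself: the
volatility posterior is sensitive to boundary-cell discretisation, and
small differences in inferred volatility feed back into the prediction.
The default resolution is a deliberate accuracy/speed trade-off; all
downstream quantities (regression weights, optimal learning rates) are
averages that are insensitive at this scale, and the test suite records
the sharper convergence bound as an open numerical limitation.

## Fitting and model comparison

MAP estimation works in transformed space (logit for α and ζ, log for
β) with independent Normal priors: mean logit(0.3), variance 1 for each
α; mean 0, variance 1 for ζ; mean log 4, variance 1 for β. These are
weakly informative defaults in the style of hierarchical-filter
toolboxes and are fully configurable. Optimisation is L-BFGS-B from the
prior mean plus random prior draws (10 starts by default; ties broken by
first occurrence), deterministic given the seed.

Log model evidence uses the Laplace approximation at the MAP
(finite-difference Hessian, step 1e−4, in transformed space), falling
back to −BIC/2 with a logged warning when the Hessian is not positive
definite; a model with no free parameters reports its log-likelihood.
Group-level model selection is random-effects variational Bayes over a
Dirichlet(1) prior (fixed-point iteration to 1e−6, at most 10,000
iterations); exceedance probabilities are Monte-Carlo estimates from
100,000 seeded Dirichlet draws.

Learning rates are reported untransformed; a reporting-layer option
adds square-root-transformed columns for variance-stabilised group
statistics.

## Optimal learning rates and αdiff

`compute_optimal_alphas` simulates datasets in which choices come from
the Bayesian optimal learner: its primary prediction series and its
advice-converted secondary series are mixed with ζ = 0.5 and passed
through the unit-square sigmoid with β = 10 (near-deterministic;
"trajectories" mode instead stores the probabilities as soft targets).
The full dual-source model is MAP-fitted to each dataset and the four
learning rates are averaged over 100 datasets (standard errors across
datasets are reported). With the default counterbalanced schedules the
four averages fall near 0.19 with between-dataset SEs below 0.02; the
stable/volatile separation of the benchmark values depends on the exact
schedule realisations, which are configurable. `alpha_diff` subtracts
these benchmarks slot-wise from fitted learning rates.

`optimal_learner_betas` regresses a session's choices on each optimal
prediction series (standardised within session) in two separate
single-predictor binomial logistic regressions; under perfect
separation the slope is capped at ±10 and flagged.

## Synthetic cohorts

`generate_cohort` produces a two-group (individual-primary /
social-primary; 16 + 15 subjects), two-session (placebo / haloperidol,
order alternating by subject) crossover. Per source × phase slot, a
subject's learning rate is logit-normal: the location is solved by
quadrature so the natural-space mean equals the reported group mean for
that drug condition, and the logit-scale sd matches the cross-subject
SD (SEM × √31) via the delta method. Subjects keep one random intercept
per slot across sessions, so the drug effect is the within-subject
shift of the condition locations — a decrease of the primary-source
rates under haloperidol with essentially unchanged secondary-source
rates. ζ is logit-normal around 0.45 (sd 0.5); β is log-normal with
mean 8 and sd 0.3 (log scale), chosen so that 120-trial sessions are
informative enough for the eight-model family to be discriminable —
with markedly noisier choices the simplest variant wins the
random-effects comparison regardless of the generating process, which
would defeat the cohort's purpose as a pipeline testbed. Each subject
keeps the same pseudo-randomised schedule pair on both days; outcomes
and choices are re-realised per session.

What the generator does *not* emulate: participant exclusions,
dropouts, response omissions, side/colour biases, session-order
learning transfer, or any systematic deviation from the fitted model
family. Passing end-to-end tests therefore demonstrates that the
pipeline is self-consistent (it recovers what the generator programmed)
— not that the model family is the true account of human behaviour.

## Problem sizes and determinism

Default study sizes follow the task design: 120-trial sessions, 31
subjects × 2 sessions, 100 optimal-learner datasets, 50-agent recovery
studies (long-session recovery uses 1,200-trial concatenations of the
default schedule). Every stochastic routine takes an explicit seed and
is bit-reproducible given it; optimiser restarts, Dirichlet sampling
and schedule randomisation all derive their streams from that seed.

## Known limitations

- The grid filter's per-trial predictions carry ~1e−2 discretisation
  sensitivity at default resolution (see above); averaged quantities
  are robust to this, individual-trial trajectories less so.
- The four benchmark learning rates are reproduced as a band (±0.05),
  not point-wise: the exact stable/volatile ordering depends on
  schedule realisations that are not part of the package defaults.
- The Laplace evidence is a local approximation; for strongly
  multimodal posteriors the BIC fallback can rank models differently.
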