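# dualsource

Computational modelling toolkit for two-source probabilistic learning
tasks, in which people learn simultaneously from a **primary**
information source (the option directly indicated by reward feedback)
and a **secondary** source (advice — social or otherwise — whose
accuracy must be inferred from feedback), under schedules that alternate
stable and volatile phases. It is aimed at computational-psychiatry and
decision-neuroscience researchers who want a tested, reusable pipeline
for this family of paradigms, e.g. for studying how dopaminergic
manipulations shift learning rates toward or away from normative
values.

The package provides:

- **Schedules** — stable/volatile reward schedules for two independent
  sources, with trial realisation and a plain-CSV trial format.
- **Dual-source Rescorla–Wagner model** — two delta-rule predictors
  (`V ← V + α(r − V)`) with phase-specific learning rates
  (α_primary_stable, α_primary_volatile, α_secondary_stable,
  α_secondary_volatile), an advice weighting `V_aw = |advice − V_s|`, a
  ζ-weighted combination `V_c = ζV_aw + (1 − ζ)V_p`, and the
  unit-square-sigmoid response rule
  `P(y=1) = V_c^β / (V_c^β + (1 − V_c)^β)`.
- **Bayesian optimal learner** — a grid filter that tracks a reward
  probability together with its volatility, used both as a regression
  benchmark (β_optimal weights) and to derive optimal learning rates
  (α_optimal) and optimality scores `αdiff = α − α_optimal`.
- **Fitting and model comparison** — multi-start MAP estimation with
  priors in transformed space, Laplace-approximate log evidence,
  random-effects Bayesian model selection over the 2×2×2 model family
  (exceedance probabilities), and parameter-recovery studies.
- **Synthetic cohorts** — crossover cohorts (two groups × two drug
  sessions) whose generative learning rates reproduce published group
  means, for end-to-end validation without any participant data.

## Worked example

```python
import dualsource as ds

# a 120-trial session: stable + volatile blocks for two independent sources
schedule = ds.generate_schedule(ds.ScheduleConfig(seed=11))
trials = ds.sample_trials(schedule, seed=7)

# simulate an agent and fit the full model to its choices
truth = ds.RWParams(alpha_primary_stable=0.2, alpha_primary_volatile=0.3,
                    alpha_secondary_stable=0.15, alpha_secondary_volatile=0.25,
                    zeta=0.4, beta=5.0)
data = ds.simulate_choices(truth, trials, seed=13)
fit = ds.fit_map(data, seed=0)
print({k: round(v, 3) for k, v in fit.natural.items()})
```

prints

```
{'alpha_primary_stable': 0.116, 'alpha_primary_volatile': 0.323,
 'alpha_secondary_stable': 0.189, 'alpha_secondary_volatile': 0.336,
 'zeta': 0.372, 'beta': 5.047}
```

— MAP estimates of the six free parameters from a single session: the
four learning rates (weight of each trial's prediction error, per
source × phase), the source weight ζ (0.37 ≈ slight preference for
directly learned values over advice) and the inverse decision
temperature β (≈ 5: choices follow beliefs fairly deterministically).
At 120 trials single-session estimates carry substantial noise;
`run_recovery` quantifies exactly how much.

The optimality benchmark works the same way from the library or the
CLI (`dualsource simulate | fit | compare | recover | optimal`):

```python
bench = ds.compute_optimal_alphas(n_datasets=100, seed=1)
print({k: round(v, 2) for k, v in bench.as_dict().items()})
# {'alpha_primary_stable': 0.2, 'alpha_primary_volatile': 0.19,
#  'alpha_secondary_stable': 0.19, 'alpha_secondary_volatile': 0.19}
```

These are the learning rates an ideal volatility-tracking learner
*appears* to have when described by the delta-rule model — the yardstick
against which fitted participant learning rates are scored
(`ds.alpha_diff`).

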