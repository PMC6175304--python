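# revlearn

Reinforcement-learning analysis of two-choice **probabilistic reversal
learning** — the task in which a subject (typically a mouse in a two-port
operant chamber) chooses between two alternatives rewarded with 80% vs 20%
probability, with the assignment reversing mid-session. The package
provides the full computational chain used to ask *which latent decision
variable a manipulation (e.g. a genotype) changes*: trial-by-trial
generative models, hierarchical Bayesian fitting, information-criterion
model selection, model-free behavioral statistics, and posterior-predictive
simulation.

## Models

Three nested Rescorla–Wagner variants, all with outcomes coded
r_t ∈ {+1, −1} and a softmax choice rule. With prediction error
PE_t = r_t − V_c,t for the chosen option c:

- learning rate η⁺ applies when PE_t ≥ 0, η⁻ when PE_t < 0:
  V_c,t+1 = V_c,t + η± · (r_t − V_c,t)
- under **fictitious updating** the unchosen option u moves toward the
  negated outcome with the same rate:
  V_u,t+1 = V_u,t + η± · (−r_t − V_u,t)
- choice: P(choose A) = 1 / (1 + exp(−β · (V_A − V_B))), with inverse
  temperature β ≥ 0.

Model 1 (`Model.RP`) uses η⁺/η⁻ and updates the chosen option only;
model 2 (`Model.FICT`) uses a single η with fictitious updating; model 3
(`Model.FICT_RP`) combines both and nests the other two exactly.

Fitting is hierarchical per group: unconstrained parameters get
Normal(μ_k, σ_k) subject effects with μ_k ~ Normal(0, 1),
σ_k ~ HalfNormal(1), mapped onto (0, 1) for rates and (0, 10) for β.
Group effects are judged by the 95% highest-density interval (HDI) of the
difference of hypermean draws; models are ranked by LOOIC
(−2 × PSIS-LOO expected log predictive density). A synthetic-cohort
generator reproduces the task schedule (120 trials × 15 sessions, reversal
after trial 60, cohorts of 8 controls + 6 mutants) with group differences
expressed through the β hypermean.

## Worked example

```python
import revlearn as rl
from revlearn.inference import McmcSettings, fit_hierarchical, group_difference

cohort = rl.generate_cohort(rl.default_group_specs(),
                            rl.TaskConfig(n_sessions=8), master_seed=11)
fits = fit_hierarchical(rl.Model.FICT_RP, cohort, McmcSettings(), seed=11)
for param in ("eta_pos", "eta_neg", "beta"):
    d = group_difference(fits["mutant"], fits["control"], param)
    print(param, (round(d.interval.lower, 3), round(d.interval.upper, 3)), d.excludes_zero)
```

prints

```
eta_pos (-0.158, 0.085) False
eta_neg (-0.269, 0.148) False
beta (-0.755, -0.137) True
```

— the mutant group (generated with a lower β hypermean and identical
learning rates) shows a credible deficit *only* in β: its choices are more
random, not slower-learning. The posterior-predictive check
(`examples/04_posterior_predictive_wsls.py`) closes the loop: agents
re-simulated from individual posterior means reproduce the cohort's
win-stay deficit (simulated t = 2.19, p = 0.049) without a credible
lose-shift difference (t = −1.05, p = 0.31).

The `examples/` directory has one short script per capability (task
simulation, model comparison, group differences, posterior-predictive
WSLS). A thin CLI mirrors the pipeline stages:
`revlearn simulate | fit | compare | metrics | ppsim | run-all |
make-fixtures`.

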