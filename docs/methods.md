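# Methods

## Task and data model

The package analyzes (and synthesizes) trial-by-trial event logs from a
two-alternative probabilistic reversal-learning task. Each session has
`trials_per_session` trials (default 120); the two ports carry reward
probabilities `p_high`/`p_low` (defaults 0.8/0.2), assigned at random at
session start and swapped once, after `reversal_trial` trials (default 60).
A subject runs `n_sessions` sessions (default 15, i.e. 1800 trials). Every
trial yields exactly one choice; trial timing, omissions and early session
termination are not modeled. The atomic record is
(subject, session, trial, current high side, choice, rewarded), stored as a
plain CSV event log (options "A"/"B", rewarded 0/1, 1-based indices).

## Generative models

All three models are asymmetric Rescorla–Wagner learners with outcomes
coded ±1 and a logistic (softmax) choice rule in the value difference,
`P(A) = expit(β (V_A − V_B))`. The prediction error of the chosen option,
`PE = r − V_c`, selects the learning rate: η⁺ if PE ≥ 0 (ties use η⁺),
η⁻ otherwise. The *same* rate then applies to the fictitious update of the
unchosen option toward −r (models 2 and 3); model 1 leaves the unchosen
value untouched; model 2 constrains η⁺ = η⁻. Initial values are (0, 0) —
the symmetric convention, which also makes the first-trial likelihood
parameter-free — and values carry across session boundaries by default
(`reset_per_session` is exposed but off, consistent with treating one
subject's 1800 trials as a single trajectory). With values initialized in
[−1, 1] and ±1 outcomes, values remain in [−1, 1]; under fictitious
updating, V_A + V_B contracts by (1 − η) per trial.

The logistic is evaluated in log space (`log_expit`) so likelihoods are
finite for arbitrarily large |β·ΔV|.

## Hierarchical Bayesian estimation

One hierarchy is fit **per group** (the design compares independently
characterized genotype groups). On the unconstrained scale each parameter
k has subject values θ_sk ~ Normal(μ_k, σ_k), with priors
μ_k ~ Normal(0, 1) and σ_k ~ HalfNormal(1). Monotone logistic transforms
map the real line onto (0, 1) for learning rates and (0, β_max) for the
inverse temperature; β_max = 10 (an explicit finite bound stabilizes the
hierarchy when choices are near-deterministic and is configurable).

Sampling is a numba-compiled Metropolis-within-Gibbs scheme in the
centered parameterization:

1. adaptive componentwise random-walk Metropolis on each subject's θ_s
   against that subject's trial likelihood (target acceptance 0.44;
   adaptation during warmup only);
2. exact conjugate draws of each hypermean given θ and σ;
3. short log-scale Metropolis updates of each hyper-SD;
4. an interweaved non-centered (ASIS) update proposing (μ_k, σ_k) jointly
   while holding the standardized subject effects fixed, accepted against
   the full group likelihood — this removes the slow mixing that the
   centered scheme shows when a parameter is weakly identified at the
   subject level.

Defaults: 4 independent chains, 1000 warmup + 1000 kept sweeps per chain,
initialized overdispersed around per-subject penalized maximum-likelihood
estimates; retained draws are thinned evenly to ≤ 2000. Convergence is
summarized by split-R̂ and ESS (arviz) on the hyperparameters across
chains; fits warn (and set `converged=False`) above R̂ = 1.05. The
hypermeans that all downstream comparisons use typically sit at R̂ ≤ 1.005
at default budgets; hyper-SD chains of weakly identified rates are the
slowest quantities and motivated the 1.05 working threshold.

Group effects: hypermean draws of two independent fits are paired by draw
index and differenced (mutant − control), by default after mapping the
hypermean through the constrained-scale transform (the scale on which
hyperposterior densities are usually plotted); the summary is the shortest
interval containing ⌈0.95 n⌉ sorted draws (HDI) and whether it excludes 0.
Draw pairing vs full cross-product differencing is immaterial for
independent samples beyond Monte-Carlo noise.

## Model selection

Per-trial log-likelihoods of the retained draws feed PSIS-LOO
(leave-one-*trial*-out, the pointwise unit of the likelihood): importance
weights are Pareto-smoothed (arviz `psislw`, standard tail fraction
min(0.2 S, 3√S)), per-trial elpd terms are summed, and LOOIC = −2·elpd.
Trials with tail-shape k > 0.7 are flagged but returned. Trials whose
likelihood is constant across draws (each subject's first trial, where
values are symmetric) have zero-variance weights; their elpd term is exact
and k is reported as −∞ rather than a spurious flag. Model ranking reports
pairwise elpd differences with standard errors from the paired pointwise
contributions. The validation oracle for PSIS-LOO is brute-force exact
refitting with one trial's likelihood term omitted while the value
recursion still consumes that trial (`fit_group(..., skip_trial=i)`) —
the correct leave-one-out scheme for a likelihood with sequential state.

## Behavioral metrics

"Correct" always means the side currently carrying `p_high`, including the
immediately post-reversal trials. Win-stay is the fraction of rewarded
*predecessor* trials whose successor repeats the choice; lose-shift the
fraction of unrewarded predecessors whose successor switches. Pairs do not
cross session boundaries by default (no overnight-memory assumption; a
switch is provided); a zero denominator yields a missing value, never 0.
The moving-average smoother uses a centered window with truncated edges so
the trace spans all trials.

## Posterior-predictive simulation

Each fitted subject is re-simulated as an agent whose point parameters are
the posterior means of its constrained individual parameters, for its full
trial count on a freshly drawn task schedule (no access to the subject's
actual choice or outcome history). Win-stay/lose-shift is compared between
real and simulated cohorts per subject, and between groups on the simulated
cohort by a two-sided unpaired t test (two metrics, reported raw).

## Synthetic study conditions

The default cohort is 8 controls + 6 mutants with constrained hypermeans
η⁺ = 0.4, η⁻ = 0.1 and β = 0.9 (control) vs 0.6 (mutant), and
unconstrained hyper-SDs 0.3 (η⁺), 1.0 (η⁻), 0.25 (β). These were fixed
once, by calibration to what well-trained mouse cohorts on this schedule
show: win-stay ≈ 0.65–0.8 against lose-shift ≈ 0.5 (higher sensitivity to
wins than losses, i.e. η⁺ > η⁻); a credible genotype effect on β of about
−0.3 with no learning-rate effect; and between-animal dispersions of about
0.04–0.05 (win-stay) and 0.07 (lose-shift), which pins the large η⁻
spread — loss-driven learning is the least consistent trait across
animals. In this regime win-stay is roughly three times as sensitive to a
β shift as lose-shift, which is exactly the asymmetric behavioral
signature the group comparison is designed to detect.

What the generator does *not* emulate: within-session drift or fatigue,
response-time structure, omissions, satiety, or any non-RL choice
perseveration. Passing tests therefore show that the estimation and
model-selection machinery is correct and well calibrated *under the model
family*, not that the model family captures every feature of real mice.

## Numerical and design choices

- Per-subject random streams are spawned from the master seed keyed by
  (group index, subject index), so enlarging a cohort never perturbs
  existing subjects' data.
- The subject-level MLE initialization uses Nelder–Mead with a weak ridge
  (0.125‖x‖²) on the unconstrained scale so degenerate subjects (e.g. all
  one choice) cannot push starts to infinity.
- HDI of constant draws is the zero-width interval, not an error.
- Event-log validation reports the first offending CSV line by number.
- PSIS requires ≥ 100 draws and finite log-likelihoods; zero-variance
  pointwise matrices are flagged as degenerate.

## Problem sizes in the test suite

The validation suite runs at sizes chosen for a single CPU: hypermean
recovery uses 10 replicates at the full 8 × 1800 study scale; group-
difference specificity uses 6 effect and 6 null replicates at 8+6 subjects
× 8 sessions (with a wider β gap, 0.9 vs 0.5, for the detection check, as
a detection criterion warrants); model recovery uses 10 replicates at
4 × 600; the exact-LOO comparison uses 2 subjects × 60 trials (120
refits); the end-to-end posterior-predictive check uses 5 replicates at
full scale. Statistical thresholds (≥ 80% coverage, majority patterns,
≤ 1 null false positive) are independent of these sizes.

## Known limitations

- The sampler is MCMC-exact but not gradient-based; very large cohorts or
  β_max ≫ 10 would benefit from a NUTS backend.
- LOOIC is computed per group; cross-group pooling or model averaging is
  out of scope.
- The posterior-mean point-parameter simulation understates individual
  posterior uncertainty; `simulate_from_fit(..., draw_index=i)` replays a
  single joint posterior draw instead, but the mean-based check is the
  default reporting path.
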