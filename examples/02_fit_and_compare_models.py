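"""Fit the three candidate learning models to one group and rank them.

Data are generated from the full model (asymmetric learning rates +
fictitious updating of the unchosen option), so the LOOIC comparison
should select model 3.  Lower LOOIC is better; `elpd_diff` is the
difference in expected log predictive density to the best model, with a
standard error from the paired per-trial contributions.
"""

import revlearn as rl
from revlearn.inference import McmcSettings, fit_group
from revlearn.selection import compare_models, loo_from_fit

spec = rl.GroupSpec.from_constrained(
    "demo", 4, {"eta_pos": 0.4, "eta_neg": 0.1, "beta": 2.0}, 0.2
)
cohort = rl.generate_cohort([spec], rl.TaskConfig(n_sessions=5), master_seed=3)
print(f"fitting 3 models to {len(cohort.trials)} trials from 4 agents...")

results = []
for model in (rl.Model.RP, rl.Model.FICT, rl.Model.FICT_RP):
    fit = fit_group(model, cohort, "demo", McmcSettings(), seed=int(model))
    results.append((model, loo_from_fit(fit)))

table = compare_models(results)
print(table[["rank", "model", "looic", "elpd_diff", "se_diff"]].round(1).to_string(index=False))
print("\nModel 3 (separate rates + fictitious updating) should rank first,"
      "\nmatching how the data were generated; the margin over the nested"
      "\nmodels is many times its standard error.")
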