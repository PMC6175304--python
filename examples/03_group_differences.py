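"""Hyperposterior group comparison: which parameter differs between groups?

Generates a control/mutant pair that differs only in the beta (inverse
temperature) hypermean, fits the full model hierarchically per group, and
prints the 95% HDI of the mutant-minus-control hypermean difference for
each parameter.  A credible (beta-only) effect shows as an HDI excluding
zero for beta but not for the learning rates.
"""

import revlearn as rl
from revlearn.inference import McmcSettings, fit_hierarchical, group_difference

cohort = rl.generate_cohort(
    rl.default_group_specs(), rl.TaskConfig(n_sessions=8), master_seed=11
)
print("fitting the full model to each group separately...")
fits = fit_hierarchical(rl.Model.FICT_RP, cohort, McmcSettings(), seed=11)

print(f"\n{'param':8s} {'95% HDI of difference':>24s}  excludes 0?")
for param in ("eta_pos", "eta_neg", "beta"):
    d = group_difference(fits["mutant"], fits["control"], param)
    print(f"{param:8s} ({d.interval.lower:+.3f}, {d.interval.upper:+.3f})"
          f"{'':>8s}  {d.excludes_zero}")
print("\nOnly the beta difference should exclude zero: the mutant deficit was"
      "\ngenerated purely as a lower inverse temperature (more random choice),"
      "\nwith identical learning-rate hyperdistributions.")
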