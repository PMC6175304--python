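"""Simulate a synthetic cohort on the probabilistic reversal-learning task.

Two groups of agents (8 controls, 6 mutants) differing only in the
inverse-temperature hypermean run 15 sessions of 120 trials with an 80/20
reward schedule that reverses after trial 60.  Prints the per-group
accuracy (fraction of choices of the currently-better port) and the trial
counts, then writes the event log to CSV.
"""

import revlearn as rl

cohort = rl.generate_cohort(rl.default_group_specs(), rl.TaskConfig(), master_seed=7)
print(f"simulated {len(cohort.trials)} trials "
      f"({cohort.trials['subject_id'].nunique()} subjects x 1800)")

acc = rl.p_correct_by_session(cohort.trials).merge(
    cohort.trials[["subject_id", "group"]].drop_duplicates()
)
by_group = acc.groupby("group")["p_correct"].mean()
print("\nmean P(correct) by group (chance = 0.5):")
print(by_group.round(3).to_string())
print("\nControls sit higher because their choices follow learned values more"
      "\nclosely (higher inverse temperature); both groups are well above chance.")

rl.write_event_log(cohort, "cohort_demo.csv")
print("\nevent log written to cohort_demo.csv")
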