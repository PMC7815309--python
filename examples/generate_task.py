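"""Generate a task set and inspect its structure.

Builds the default bandit environment — 100 unique three-bandit trials
(25 per combination of bandit types), each duplicated and played in a
1-draw and a 6-draw horizon — and writes it to CSV.
"""

from banditexplore import TaskConfig, build_taskset, task_to_csv

config = TaskConfig(seed=7)
taskset = build_taskset(config)

n_unique = sum(t.duplicate_of is None for t in taskset.trials) // 2  # per horizon
print(f"total trials:          {len(taskset)}")
print(f"unique trials:         {n_unique}")
print(f"short-horizon trials:  {len(taskset.trials_for_horizon(1))}")
print(f"long-horizon trials:   {len(taskset.trials_for_horizon(6))}")
print(f"duplicate pairs/hor.:  {len(taskset.duplicate_pairs(horizon=1))}")

trial = taskset.trials[0]
print(f"\nexample trial {trial.trial_id} (combination {trial.combination_id}, "
      f"horizon {trial.horizon}):")
for b in trial.bandits:
    print(f"  {b.position:6s} {b.bandit_type:16s} mean={b.generative_mean:5.2f} "
          f"initial samples={list(b.initial_samples)}")

task_to_csv(taskset, "task.csv")
print("\nwrote task.csv (one row per trial-slot)")
# The counts above are the environment's defining structure: every unique
# trial appears four times (2 horizons x 2 duplicates), so choice
# consistency can be measured on identical options.
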