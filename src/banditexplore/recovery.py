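"""Parameter-recovery and model-validation pipelines.

Parameter recovery: simulate one agent per grid point of generative
parameter values, refit each agent, and correlate recovered with generative
values (Pearson) per free parameter — parameters are interpretable to the
extent that these correlations are high and the recovered spread per
generative level is narrow.

Model validation: re-simulate behaviour from (fitted) parameters and compute
the model-free behavioural metrics, for comparison against the data the
parameters were fitted to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .data import ChoiceDataset
from .fit import FitConfig, FitResult, fit_subject
from .metrics import compute_metrics, metrics_to_tidy
from .models import ModelSpec, ParameterSet, free_parameters, vector_from_parameter_set
from .simulate import WINNING_MODEL, simulate_dataset
from .task import TaskConfig, TaskSet, build_taskset

__all__ = ["RecoveryReport", "run_parameter_recovery", "run_model_validation"]


@dataclass
class RecoveryReport:
    model_spec: ModelSpec
    table: pd.DataFrame  # one row per agent: generative__X / recovered__X
    correlations: dict[str, float]  # free-parameter label -> Pearson r
    n_failed: int = 0

    def spread(self, label: str) -> pd.DataFrame:
        """Dispersion of recovered values per generative level of one
        parameter."""
        g = self.table.groupby(f"generative__{label}")[f"recovered__{label}"]
        return g.agg(["mean", "std", "count"])


def _task_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def run_parameter_recovery(
    grid: Sequence[ParameterSet],
    model_spec: ModelSpec = WINNING_MODEL,
    task_config: Optional[TaskConfig] = None,
    fit_config: Optional[FitConfig] = None,
    seed: int = 0,
    task_mode: str = "fresh",
    n_trials_override: Optional[int] = None,
) -> RecoveryReport:
    """Simulate -> refit -> correlate over a grid of generative parameters.

    ``task_mode='fresh'`` gives every agent its own newly generated task set
    (default); ``'shared'`` reuses a single task set for all agents.
    ``n_trials_override`` rescales trials_per_combination to reach a target
    total trial count (used in asymptotic checks).  Fit failures are
    recorded, not fatal.
    """
    if task_mode not in ("fresh", "shared"):
        raise ValueError("task_mode must be 'fresh' or 'shared'")
    base_cfg = task_config or TaskConfig()
    if n_trials_override is not None:
        per_combo = max(1, round(n_trials_override / 16))
        base_cfg = dc_replace(base_cfg, trials_per_combination=per_combo)
    fit_cfg = fit_config or FitConfig(method="map")

    horizons = base_cfg.horizons
    layout = free_parameters(model_spec, horizons=horizons,
                             bounds=fit_cfg.merged_bounds())
    labels = [fp.label for fp in layout]

    shared_task: Optional[TaskSet] = None
    if task_mode == "shared":
        shared_task = build_taskset(
            dc_replace(base_cfg, seed=_task_seed(np.random.SeedSequence(seed)))
        )

    rows = []
    n_failed = 0
    for a, gen_params in enumerate(grid):
        ss = np.random.SeedSequence(seed, spawn_key=(a,))
        task_ss, sim_ss, fit_ss = ss.spawn(3)
        task = shared_task or build_taskset(
            dc_replace(base_cfg, seed=_task_seed(task_ss))
        )
        ds = simulate_dataset(model_spec, gen_params, task, seed=sim_ss,
                              subject_id=f"grid{a}")
        row = {"agent": a}
        gen_x = vector_from_parameter_set(gen_params, layout)
        for lab, v in zip(labels, gen_x):
            row[f"generative__{lab}"] = float(v)
        try:
            res = fit_subject(
                model_spec, ds,
                dc_replace(fit_cfg, seed=_task_seed(fit_ss)),
            )
            for lab, v in zip(labels, res.x):
                row[f"recovered__{lab}"] = float(v)
        except RuntimeError:
            n_failed += 1
            for lab in labels:
                row[f"recovered__{lab}"] = float("nan")
        rows.append(row)

    table = pd.DataFrame(rows)
    correlations = {}
    for lab in labels:
        g = table[f"generative__{lab}"]
        r = table[f"recovered__{lab}"]
        ok = r.notna()
        if ok.sum() >= 3 and g[ok].nunique() > 1:
            correlations[lab] = float(pearsonr(g[ok], r[ok])[0])
        else:
            correlations[lab] = float("nan")
    return RecoveryReport(model_spec=model_spec, table=table,
                          correlations=correlations, n_failed=n_failed)


def _concat_tasksets(tasksets: Sequence[TaskSet]) -> TaskSet:
    """Merge task sets into one, re-identifying trials to stay unique."""
    trials = []
    offset = 0
    for ts in tasksets:
        for t in ts.trials:
            trials.append(
                dc_replace(
                    t,
                    trial_id=t.trial_id + offset,
                    duplicate_of=None if t.duplicate_of is None
                    else t.duplicate_of + offset,
                )
            )
        offset += max(t.trial_id for t in ts.trials) + 1
    return TaskSet(config=tasksets[0].config, trials=trials)


def run_model_validation(
    fitted_params_per_subject: Mapping[str, Union[ParameterSet, FitResult]],
    n_sims: int = 4000,
    task_config: Optional[TaskConfig] = None,
    seed: int = 0,
    model_spec: ModelSpec = WINNING_MODEL,
    observed: Optional[Mapping[str, ChoiceDataset]] = None,
) -> pd.DataFrame:
    """Simulate ``n_sims`` trials per subject from fitted parameters.

    Returns a tidy metric table (subject_id, horizon, metric, value) with a
    ``source`` column; when ``observed`` datasets are given, their metrics
    are appended with ``source='observed'`` for side-by-side comparison.
    """
    base_cfg = task_config or TaskConfig()
    per_taskset = 16 * base_cfg.trials_per_combination
    n_tasksets = max(1, math.ceil(n_sims / per_taskset))

    reports = []
    for s, (sid, params) in enumerate(sorted(fitted_params_per_subject.items())):
        if isinstance(params, FitResult):
            params = params.params
        ss = np.random.SeedSequence(seed, spawn_key=(s,))
        task_sss = ss.spawn(n_tasksets + 1)
        tasks = [
            build_taskset(dc_replace(base_cfg, seed=_task_seed(t_ss)))
            for t_ss in task_sss[:-1]
        ]
        task = _concat_tasksets(tasks)
        if len(task.trials) > n_sims:
            keep = task.trials[:n_sims]
            keep_ids = {t.trial_id for t in keep}
            task = TaskSet(task.config, [
                dc_replace(t, duplicate_of=t.duplicate_of
                           if t.duplicate_of in keep_ids else None)
                for t in keep
            ])
        ds = simulate_dataset(model_spec, params, task, seed=task_sss[-1],
                              subject_id=sid)
        reports.append(compute_metrics(ds))
    sim = metrics_to_tidy(reports)
    sim["source"] = "simulated"
    if observed:
        obs = metrics_to_tidy([compute_metrics(d) for d in observed.values()])
        obs["source"] = "observed"
        sim = pd.concat([sim, obs], ignore_index=True)
    return sim
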