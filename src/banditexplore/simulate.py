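"""Simulation of artificial agents on the bandit task.

Agents choose according to a model's choice probabilities.  In ``first_only``
mode only the first draw of every trial is simulated (what model fitting
uses); in ``full`` mode long-horizon trials play out all six draws, with each
obtained reward updating the agent's beliefs before the next choice.

Also provides the signature experiments that validate the behavioural
markers of the two exploration heuristics — low/high epsilon-greedy agents
differ in low-value-bandit frequency and choice consistency, low/high
novelty-bonus agents differ in novel-bandit frequency — and the Cartesian
parameter grid used for parameter recovery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .beliefs import Priors, beliefs_after_initial_samples, update_belief
from .data import ChoiceDataset, ChoiceRecord
from .metrics import choice_consistency, selection_frequencies
from .models import (
    ModelSpec,
    ParameterSet,
    choice_prob_matrix,
    free_parameters,
    parameter_set_from_vector,
    probs_from_beliefs,
    trial_arrays,
)
from .task import TaskConfig, TaskSet, build_taskset, draw_reward, draw_rewards

__all__ = [
    "simulate_dataset",
    "SignatureResult",
    "simulate_signature_experiment",
    "RECOVERY_RANGES",
    "generate_recovery_grid",
]

#: mean fitted parameters used as the fixed values in the signature runs
SIGNATURE_FIXED = {"sigma0": 1.312, "eta": 2.625, "Q0": 3.2, "epsilon": 0.1}

WINNING_MODEL = ModelSpec(base="thompson", c_vf=1, c_n=1)


def _sample_rows(P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per row of a probability matrix."""
    u = rng.random(P.shape[0])
    return (u[:, None] > np.cumsum(P, axis=1)).sum(axis=1)


def simulate_dataset(
    model_spec: ModelSpec,
    params: ParameterSet,
    taskset: TaskSet,
    seed: int | np.random.SeedSequence = 0,
    draws: str = "first_only",
    subject_id: str = "agent",
    keep_probabilities: bool = False,
) -> ChoiceDataset:
    """Simulate one agent on every trial of a task set.

    ``draws='first_only'`` records only the first draw per trial;
    ``draws='full'`` plays every draw of long-horizon trials, updating
    beliefs with each obtained reward.  Same seed, same dataset.
    """
    if draws not in ("first_only", "full"):
        raise ValueError("draws must be 'first_only' or 'full'")
    rng = np.random.default_rng(seed)
    cfg = taskset.config
    tau_samp = cfg.sampling_precision
    trials = taskset.trials
    arr = trial_arrays(trials)
    P = choice_prob_matrix(model_spec, params, arr, sampling_precision=tau_samp)
    chosen = _sample_rows(P, rng)
    means = np.array(
        [trials[t].bandits[chosen[t]].generative_mean for t in range(len(trials))]
    )
    rewards = draw_rewards(means, cfg, rng)

    records: list[ChoiceRecord] = []
    for t, trial in enumerate(trials):
        b = trial.bandits[chosen[t]]
        records.append(
            ChoiceRecord(
                trial_id=trial.trial_id,
                horizon=trial.horizon,
                draw_index=1,
                chosen_type=b.bandit_type,
                chosen_slot=b.position,
                reward=int(rewards[t]),
                probabilities=tuple(P[t]) if keep_probabilities else None,
            )
        )
        if draws == "full" and trial.horizon > 1:
            p = params.at(trial.horizon)
            beliefs = beliefs_after_initial_samples(
                Priors(Q0=p.Q0, sigma0=p.sigma0), trial, tau_samp
            )
            beliefs = update_belief(beliefs, b.bandit_type, rewards[t], tau_samp)
            for d in range(2, trial.horizon + 1):
                probs = probs_from_beliefs(model_spec, p, beliefs, trial)
                i = int(_sample_rows(probs[None, :], rng)[0])
                bd = trial.bandits[i]
                rew = draw_reward(bd.generative_mean, cfg, rng)
                records.append(
                    ChoiceRecord(
                        trial_id=trial.trial_id,
                        horizon=trial.horizon,
                        draw_index=d,
                        chosen_type=bd.bandit_type,
                        chosen_slot=bd.position,
                        reward=rew,
                        probabilities=tuple(probs) if keep_probabilities else None,
                    )
                )
                beliefs = update_belief(beliefs, bd.bandit_type, rew, tau_samp)

    return ChoiceDataset(
        task=taskset,
        records=records,
        subject_id=subject_id,
        provenance={"model": model_spec.name, "draws": draws, "simulated": True},
    )


@dataclass
class SignatureResult:
    experiment: str
    per_agent: pd.DataFrame  # agent, regime, param value, three metrics
    summary: pd.DataFrame  # regime x metric mean/SD across agents


def simulate_signature_experiment(
    which: str,
    n_agents: int = 200,
    n_trials: int = 200,
    low_value: Optional[float] = None,
    high_value: Optional[float] = None,
    fixed_params: Optional[Mapping[str, float]] = None,
    seed: int = 0,
    horizon: Optional[int] = None,
    task_config: Optional[TaskConfig] = None,
) -> SignatureResult:
    """Simulate cohorts of winning-model agents in a low vs high regime.

    ``which='value_free'`` varies the epsilon-greedy parameter (defaults
    0 vs 0.2, novelty bonus fixed at 2.625); ``which='novelty'`` varies the
    novelty bonus (defaults 0 vs 2, epsilon fixed at 0.1).  The remaining
    parameters sit at the mean fitted values (sigma0 = 1.312, Q0 = 3.2).
    Each agent plays ``n_trials`` trials of a single horizon condition
    (default: the long horizon) and is scored on low-value-bandit frequency,
    choice consistency and novel-bandit frequency.
    """
    if which not in ("value_free", "novelty"):
        raise ValueError("which must be 'value_free' or 'novelty'")
    fixed = dict(SIGNATURE_FIXED)
    if fixed_params:
        fixed.update(fixed_params)
    if which == "value_free":
        low = 0.0 if low_value is None else low_value
        high = 0.2 if high_value is None else high_value
        varied = "epsilon"
    else:
        low = 0.0 if low_value is None else low_value
        high = 2.0 if high_value is None else high_value
        varied = "eta"

    base_cfg = task_config or TaskConfig()
    if n_trials % 8:
        raise ValueError("n_trials must be a multiple of 8 (4 combinations x 2 duplicates)")
    cfg_kwargs = dict(
        sampling_variance=base_cfg.sampling_variance,
        reward_bounds=base_cfg.reward_bounds,
        trials_per_combination=n_trials // 8,
        horizons=base_cfg.horizons,
        mean_prior=base_cfg.mean_prior,
    )
    h = base_cfg.long_horizon if horizon is None else horizon

    rows = []
    for agent in range(n_agents):
        ss = np.random.SeedSequence(seed, spawn_key=(agent,))
        task_seed, sim_seed = (int(s) for s in ss.generate_state(2) % (2**31))
        full = build_taskset(TaskConfig(seed=task_seed, **cfg_kwargs))
        ts = TaskSet(full.config, full.trials_for_horizon(h))
        for regime, value in (("low", low), ("high", high)):
            kw = {
                "Q0": fixed["Q0"],
                "sigma0": fixed["sigma0"],
                "epsilon": fixed["epsilon"] if which == "novelty" else 0.0,
                "eta": fixed["eta"] if which == "value_free" else 0.0,
            }
            kw[varied] = value
            params = ParameterSet(**kw)
            ds = simulate_dataset(
                WINNING_MODEL, params, ts,
                seed=np.random.SeedSequence(sim_seed, spawn_key=(0 if regime == "low" else 1,)),
                subject_id=f"agent{agent}",
            )
            freqs = selection_frequencies(ds)[h]
            cons = choice_consistency(ds)[h]
            rows.append(
                {
                    "agent": agent,
                    "regime": regime,
                    varied: value,
                    "low_value_freq": freqs["low"],
                    "consistency": cons,
                    "novel_freq": freqs["novel"],
                }
            )
    per_agent = pd.DataFrame(rows)
    summary = (
        per_agent.groupby("regime")[["low_value_freq", "consistency", "novel_freq"]]
        .agg(["mean", "std"])
        .reindex(["low", "high"])
    )
    return SignatureResult(experiment=which, per_agent=per_agent, summary=summary)


#: recovery grid ranges (narrower than the fitting bounds)
RECOVERY_RANGES = {
    "sigma0": (0.5, 2.5),
    "Q0": (1.0, 6.0),
    "epsilon": (0.0, 0.5),
    "eta": (0.0, 5.0),
    "beta": (0.5, 10.0),
    "gamma": (0.0, 5.0),
    "w": (0.0, 1.0),
}


def generate_recovery_grid(
    ranges: Optional[Mapping[str, tuple[float, float]]] = None,
    n_values_per_param: int = 4,
    model_spec: ModelSpec = WINNING_MODEL,
    horizons: Sequence[int] = (1, 6),
) -> list[ParameterSet]:
    """Full Cartesian grid of equally spread values per free parameter.

    For the winning model (7 free parameters) the default grid has 4^7
    entries; ``n_values_per_param=1`` degenerates to the range minima.
    """
    if n_values_per_param < 1:
        raise ValueError("n_values_per_param must be >= 1")
    r = dict(RECOVERY_RANGES)
    if ranges:
        r.update(ranges)
    layout = free_parameters(model_spec, horizons=horizons)
    axes = []
    for fp in layout:
        lo, hi = r[fp.name]
        if n_values_per_param == 1:
            axes.append(np.array([lo]))
        else:
            axes.append(np.linspace(lo, hi, n_values_per_param))
    return [
        parameter_set_from_vector(np.array(combo), layout, horizons=horizons)
        for combo in itertools.product(*axes)
    ]
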