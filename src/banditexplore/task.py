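"""Synthetic three-armed bandit task generation.

The task presents, on each trial, three bandits drawn from four generative
types that differ in their mean reward and in how much prior information
(initial samples) the subject sees before choosing:

* ``certain_standard`` — 3 initial samples, mean drawn from N(5.5, 1.4).
* ``standard``         — 1 initial sample, mean offset from the
  certain-standard mean by ±1 or ±2 (four equiprobable cases).
* ``novel``            — 0 initial samples, mean offset by ±1/±2 from either
  the certain-standard or the standard mean (eight equiprobable cases).
* ``low``              — 1 initial sample, mean one unit below the minimum of
  the other three means; its shown sample is forced to be the strictly
  smallest on the trial.

Rewards are normal draws (variance 0.8 by default) rounded to the nearest
integer and rejection-truncated to the closed interval [2, 10], giving
exactly nine possible reward values.  Each of the four three-bandit
combinations contributes 25 unique trials; every unique trial is duplicated
(to measure choice consistency) and played in both a short (1 draw) and a
long (6 draws) horizon, for 400 trials in total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BANDIT_TYPES",
    "COMBINATIONS",
    "POSITIONS",
    "TaskConfig",
    "TrialMeans",
    "BanditInstance",
    "TrialSpec",
    "TaskSet",
    "sample_trial_means",
    "draw_reward",
    "draw_rewards",
    "build_trial",
    "build_taskset",
    "identify_high_value",
    "task_to_csv",
    "task_from_csv",
]

BANDIT_TYPES = ("certain_standard", "standard", "novel", "low")

#: combination_id -> the bandit type that is absent on that trial
COMBINATIONS = {i + 1: t for i, t in enumerate(BANDIT_TYPES)}

#: number of initial samples shown for each bandit type
N_INITIAL_SAMPLES = {"certain_standard": 3, "standard": 1, "novel": 0, "low": 1}

POSITIONS = ("left", "middle", "right")

N_COLOUR_SETS = 8


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the task's generative process."""

    sampling_variance: float = 0.8
    reward_bounds: tuple[int, int] = (2, 10)
    trials_per_combination: int = 25
    horizons: tuple[int, int] = (1, 6)
    mean_prior: tuple[float, float] = (5.5, 1.4)  # (mean, SD) of mu_cs
    seed: int = 0
    resample_cap: int = 10_000

    def __post_init__(self) -> None:
        if self.sampling_variance <= 0:
            raise ValueError("sampling_variance must be > 0")
        lo, hi = self.reward_bounds
        if not lo < hi:
            raise ValueError("reward_bounds must satisfy lower < upper")
        if self.trials_per_combination < 1:
            raise ValueError("trials_per_combination must be >= 1")

    @property
    def sampling_precision(self) -> float:
        """Precision 1/S^2 of the reward distribution (default 1.25)."""
        return 1.0 / self.sampling_variance

    @property
    def short_horizon(self) -> int:
        return self.horizons[0]

    @property
    def long_horizon(self) -> int:
        return self.horizons[1]


@dataclass(frozen=True)
class TrialMeans:
    """Generative means of the four bandit types on one trial."""

    mu_cs: float
    mu_s: float
    mu_n: float
    mu_l: float

    def of(self, bandit_type: str) -> float:
        return {
            "certain_standard": self.mu_cs,
            "standard": self.mu_s,
            "novel": self.mu_n,
            "low": self.mu_l,
        }[bandit_type]


@dataclass(frozen=True)
class BanditInstance:
    bandit_type: str
    generative_mean: float
    initial_samples: tuple[int, ...]
    position: str = "left"
    colour_id: int = 0

    @property
    def n_initial_samples(self) -> int:
        return len(self.initial_samples)

    @property
    def initial_sample_mean(self) -> Optional[float]:
        if not self.initial_samples:
            return None
        return float(np.mean(self.initial_samples))


@dataclass(frozen=True)
class TrialSpec:
    trial_id: int
    combination_id: int
    bandits: tuple[BanditInstance, ...]
    horizon: int = 1
    duplicate_of: Optional[int] = None
    block: int = 0

    def __post_init__(self) -> None:
        if len(self.bandits) != 3:
            raise ValueError("a trial shows exactly 3 bandits")
        types = [b.bandit_type for b in self.bandits]
        if len(set(types)) != 3:
            raise ValueError("bandit types on a trial must be distinct")

    @property
    def bandit_types(self) -> tuple[str, ...]:
        return tuple(b.bandit_type for b in self.bandits)

    def bandit(self, bandit_type: str) -> BanditInstance:
        for b in self.bandits:
            if b.bandit_type == bandit_type:
                return b
        raise KeyError(bandit_type)

    def has(self, bandit_type: str) -> bool:
        return bandit_type in self.bandit_types


@dataclass
class TaskSet:
    config: TaskConfig
    trials: list[TrialSpec] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    def by_id(self, trial_id: int) -> TrialSpec:
        return self._index()[trial_id]

    def _index(self) -> dict[int, TrialSpec]:
        if not hasattr(self, "_idx") or len(self._idx) != len(self.trials):
            self._idx = {t.trial_id: t for t in self.trials}
        return self._idx

    def trials_for_horizon(self, horizon: int) -> list[TrialSpec]:
        return [t for t in self.trials if t.horizon == horizon]

    def duplicate_pairs(self, horizon: Optional[int] = None) -> list[tuple[TrialSpec, TrialSpec]]:
        """(original, duplicate) pairs, optionally restricted to one horizon."""
        idx = self._index()
        pairs = []
        for t in self.trials:
            if t.duplicate_of is not None and (horizon is None or t.horizon == horizon):
                pairs.append((idx[t.duplicate_of], t))
        return pairs


# ---------------------------------------------------------------------------
# generative process


def sample_trial_means(config: TaskConfig, rng: np.random.Generator) -> TrialMeans:
    """Draw the four generative means for one trial.

    mu_cs ~ N(5.5, 1.4); mu_s is mu_cs plus one of {-2, -1, +1, +2} with
    equal probability; mu_n is one of the eight analogous offsets from mu_cs
    or mu_s; mu_l is one below the minimum of the other three.
    """
    mean, sd = config.mean_prior
    mu_cs = float(rng.normal(mean, sd))
    offsets = (1.0, -1.0, 2.0, -2.0)
    mu_s = mu_cs + offsets[rng.integers(4)]
    novel_cases = [mu_cs + o for o in offsets] + [mu_s + o for o in offsets]
    mu_n = novel_cases[rng.integers(8)]
    mu_l = min(mu_cs, mu_s, mu_n) - 1.0
    return TrialMeans(mu_cs=mu_cs, mu_s=mu_s, mu_n=mu_n, mu_l=mu_l)


def draw_rewards(
    means: Sequence[float] | np.ndarray,
    config: TaskConfig,
    rng: np.random.Generator,
    variance: Optional[float] = None,
) -> np.ndarray:
    """Vectorised integer reward draws.

    A reward is a Normal(mean, S^2) draw rounded to the nearest integer,
    with values outside ``reward_bounds`` excluded and redrawn.  The
    resulting law is sampled directly: each integer k in the interval gets
    the normal's mass over its rounding cell [k - 1/2, k + 1/2],
    renormalised over the interval.  ``variance`` overrides
    ``config.sampling_variance`` (test hook).
    """
    from scipy.special import ndtr

    means = np.asarray(means, dtype=float)
    var = config.sampling_variance if variance is None else variance
    sd = math.sqrt(var)
    lo, hi = config.reward_bounds
    if means.size == 0:
        return np.empty(means.shape, dtype=np.int64)
    support = np.arange(lo, hi + 1)
    edges = np.concatenate([support - 0.5, [hi + 0.5]])
    flat = means.ravel()
    cdf = ndtr((edges[None, :] - flat[:, None]) / sd)
    weights = np.diff(cdf, axis=1)
    total = weights.sum(axis=1)
    if np.any(total <= 0):
        bad = flat[total <= 0]
        raise RuntimeError(
            f"reward interval {config.reward_bounds} has zero probability for "
            f"mean(s) {bad[:3]}... — degenerate configuration"
        )
    cum = np.cumsum(weights, axis=1)
    u = rng.random(flat.shape) * total
    idx = (u[:, None] > cum).sum(axis=1)
    return (support[idx]).reshape(means.shape)


def draw_reward(
    mean: float,
    config: TaskConfig,
    rng: np.random.Generator,
    variance: Optional[float] = None,
) -> int:
    """One integer reward in ``config.reward_bounds`` from Normal(mean, S^2)."""
    return int(draw_rewards(np.array([mean]), config, rng, variance=variance)[0])


def _displayed_types(combination_id: int) -> tuple[str, ...]:
    absent = COMBINATIONS[combination_id]
    return tuple(t for t in BANDIT_TYPES if t != absent)


def build_trial(
    combination_id: int,
    config: TaskConfig,
    rng: np.random.Generator,
    trial_id: int = 0,
) -> TrialSpec:
    """Build one unique trial (horizon unset, positions in canonical order).

    If the low-value bandit is displayed, all bandits' initial samples are
    redrawn jointly until the low bandit's sample is strictly smaller than
    every other displayed initial sample, so that it is identifiable as the
    low-value option.  In the rare tail where the means are so low that
    every displayed sample sits at the reward floor (making the strict
    inequality unsatisfiable), the trial's means are resampled as well.
    """
    if combination_id not in COMBINATIONS:
        raise ValueError(f"combination_id must be in 1..4, got {combination_id}")
    types = _displayed_types(combination_id)
    means = sample_trial_means(config, rng)
    low_present = "low" in types

    means_block = max(1, config.resample_cap // 10)
    for attempt in range(config.resample_cap):
        if low_present and attempt and attempt % means_block == 0:
            means = sample_trial_means(config, rng)
        samples = {
            t: tuple(
                int(v)
                for v in draw_rewards(
                    [means.of(t)] * N_INITIAL_SAMPLES[t], config, rng
                )
            )
            for t in types
        }
        if not low_present:
            break
        low_sample = samples["low"][0]
        others = [v for t in types if t != "low" for v in samples[t]]
        if all(low_sample < v for v in others):
            break
    else:
        raise RuntimeError(
            "could not satisfy the smallest-sample constraint for the low "
            f"bandit within {config.resample_cap} redraws"
        )

    bandits = tuple(
        BanditInstance(
            bandit_type=t,
            generative_mean=means.of(t),
            initial_samples=samples[t],
            position=POSITIONS[i],
        )
        for i, t in enumerate(types)
    )
    return TrialSpec(trial_id=trial_id, combination_id=combination_id, bandits=bandits)


def _shuffled_copy(
    trial: TrialSpec,
    rng: np.random.Generator,
    trial_id: int,
    horizon: int,
    duplicate_of: Optional[int],
) -> TrialSpec:
    """Same bandits (types, means, realised samples); new positions/colours."""
    order = rng.permutation(3)
    colour_set = int(rng.integers(N_COLOUR_SETS))
    bandits = tuple(
        replace(
            trial.bandits[order[i]],
            position=POSITIONS[i],
            colour_id=colour_set * 3 + i,
        )
        for i in range(3)
    )
    return TrialSpec(
        trial_id=trial_id,
        combination_id=trial.combination_id,
        bandits=bandits,
        horizon=horizon,
        duplicate_of=duplicate_of,
        block=0,
    )


def build_taskset(config: TaskConfig) -> TaskSet:
    """Generate a full task set.

    With defaults: 4 combinations x 25 = 100 unique trials, each duplicated
    and played in both horizons (400 trials).  Per-trial RNG substreams are
    spawned from the task seed, so trial k of a combination does not depend
    on ``trials_per_combination``.
    """
    uniques: list[TrialSpec] = []
    for combo in COMBINATIONS:
        for k in range(config.trials_per_combination):
            ss = np.random.SeedSequence(config.seed, spawn_key=(combo, k))
            rng = np.random.default_rng(ss)
            uniques.append(build_trial(combo, config, rng))

    layout_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(999,))
    )
    trials: list[TrialSpec] = []
    next_id = 0
    for u in uniques:
        for horizon in config.horizons:
            original = _shuffled_copy(u, layout_rng, next_id, horizon, None)
            duplicate = _shuffled_copy(u, layout_rng, next_id + 1, horizon, next_id)
            trials.extend([original, duplicate])
            next_id += 2

    # random assignment to 4 equally sized blocks
    n = len(trials)
    blocks = np.repeat(np.arange(4), math.ceil(n / 4))[:n]
    layout_rng.shuffle(blocks)
    trials = [replace(t, block=int(b)) for t, b in zip(trials, blocks)]
    return TaskSet(config=config, trials=trials)


def identify_high_value(trial: TrialSpec) -> Optional[BanditInstance]:
    """The displayed bandit with the highest initial-sample mean.

    Defined only on trials showing both the certain-standard and the standard
    bandit; returns None otherwise, and None on a tie in sample means.
    """
    if not (trial.has("certain_standard") and trial.has("standard")):
        return None
    with_samples = [b for b in trial.bandits if b.initial_samples]
    means = [b.initial_sample_mean for b in with_samples]
    best = max(means)
    if means.count(best) > 1:
        return None
    return with_samples[int(np.argmax(means))]


# ---------------------------------------------------------------------------
# CSV interface (one row per trial-slot)


def task_to_frame(taskset: TaskSet) -> pd.DataFrame:
    rows = []
    for t in taskset.trials:
        for b in t.bandits:
            rows.append(
                {
                    "trial_id": t.trial_id,
                    "duplicate_of": t.duplicate_of,
                    "horizon": t.horizon,
                    "block": t.block,
                    "combination_id": t.combination_id,
                    "slot": b.position,
                    "bandit_type": b.bandit_type,
                    "generative_mean": b.generative_mean,
                    "colour_id": b.colour_id,
                    "initial_samples": ";".join(str(v) for v in b.initial_samples),
                }
            )
    return pd.DataFrame(rows)


def task_to_csv(taskset: TaskSet, path) -> None:
    # %.17g keeps the generative means bit-exact through the round trip
    task_to_frame(taskset).to_csv(path, index=False, float_format="%.17g")


def task_from_csv(path, config: Optional[TaskConfig] = None) -> TaskSet:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""],
                     float_precision="round_trip")
    trials = []
    for trial_id, grp in df.groupby("trial_id", sort=True):
        bandits = tuple(
            BanditInstance(
                bandit_type=row.bandit_type,
                generative_mean=float(row.generative_mean),
                initial_samples=tuple(
                    int(v) for v in str(row.initial_samples).split(";") if v != ""
                )
                if not pd.isna(row.initial_samples)
                else (),
                position=row.slot,
                colour_id=int(row.colour_id),
            )
            for row in grp.itertuples()
        )
        first = grp.iloc[0]
        dup = first["duplicate_of"]
        trials.append(
            TrialSpec(
                trial_id=int(trial_id),
                combination_id=int(first["combination_id"]),
                bandits=bandits,
                horizon=int(first["horizon"]),
                duplicate_of=None if pd.isna(dup) else int(dup),
                block=int(first["block"]),
            )
        )
    return TaskSet(config=config or TaskConfig(), trials=trials)
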