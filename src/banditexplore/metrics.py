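"""Model-free behavioural measures on first-draw choices.

All measures are computed per horizon from the first draw of every trial:

* selection frequency per bandit type, as a percentage of ALL trials in the
  horizon (each type is absent on a quarter of trials, so a type chosen
  whenever present reaches at most 75%);
* choice consistency: the percentage of duplicated trial pairs (identical
  bandit types, generative means and initial samples; shuffled positions)
  on which the same bandit type was chosen;
* frequency of choosing the high-value option, on the trials where it is
  defined (both certain-standard and standard bandit displayed, no tie);
* expected value of the first choice (mean of the chosen bandit's initial
  samples, excluding trials where the novel bandit — which shows none — was
  chosen) and information seeking (mean number of initial samples of the
  chosen bandit, novel counted as 0);
* mean reward of the first draw and over all draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ChoiceDataset
from .task import BANDIT_TYPES, identify_high_value

__all__ = [
    "MetricsReport",
    "selection_frequencies",
    "choice_consistency",
    "high_value_frequency",
    "first_choice_value_and_information",
    "reward_summary",
    "compute_metrics",
    "metrics_to_tidy",
]


@dataclass
class MetricsReport:
    subject_id: str
    selection_freq: dict[int, dict[str, float]]  # horizon -> type -> %
    consistency: dict[int, float]  # horizon -> %
    high_value_freq: dict[int, float]  # horizon -> %
    mean_expected_value: dict[int, float]
    mean_information: dict[int, float]
    mean_first_reward: dict[int, float]
    mean_all_reward: dict[int, float]

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for h, freqs in self.selection_freq.items():
            for t, v in freqs.items():
                rows.append((self.subject_id, h, f"selection_freq_{t}", v))
        for name in ("consistency", "high_value_freq", "mean_expected_value",
                     "mean_information", "mean_first_reward", "mean_all_reward"):
            for h, v in getattr(self, name).items():
                rows.append((self.subject_id, h, name, v))
        return pd.DataFrame(rows, columns=["subject_id", "horizon", "metric", "value"])


def _first_by_horizon(dataset: ChoiceDataset) -> dict[int, list]:
    out: dict[int, list] = {}
    for r in dataset.first_draws():
        out.setdefault(r.horizon, []).append(r)
    if not out:
        raise ValueError("dataset has no first-draw records")
    return out


def selection_frequencies(dataset: ChoiceDataset) -> dict[int, dict[str, float]]:
    """Per-type choice frequency, in % of all first-draw trials per horizon."""
    out = {}
    for h, recs in _first_by_horizon(dataset).items():
        n = len(recs)
        out[h] = {
            t: 100.0 * sum(r.chosen_type == t for r in recs) / n
            for t in BANDIT_TYPES
        }
    return out


def choice_consistency(dataset: ChoiceDataset) -> dict[int, float]:
    """% of duplicated pairs with the same first-draw bandit-type choice.

    Duplicates are matched by bandit type (positions and colours are
    re-shuffled between a trial and its duplicate, so slots cannot be
    compared).  Each pair counts once.
    """
    first = {r.trial_id: r for r in dataset.first_draws()}
    out: dict[int, float] = {}
    for h in sorted({r.horizon for r in dataset.first_draws()}):
        pairs = dataset.task.duplicate_pairs(horizon=h)
        pairs = [(a, b) for a, b in pairs if a.trial_id in first and b.trial_id in first]
        if not pairs:
            raise ValueError(f"no duplicate pairs with choices in horizon {h}")
        same = sum(
            first[a.trial_id].chosen_type == first[b.trial_id].chosen_type
            for a, b in pairs
        )
        out[h] = 100.0 * same / len(pairs)
    return out


def high_value_frequency(dataset: ChoiceDataset) -> dict[int, float]:
    """% of eligible trials whose first choice is the high-value option."""
    out: dict[int, float] = {}
    for h, recs in _first_by_horizon(dataset).items():
        hits = n = 0
        for r in recs:
            hv = identify_high_value(dataset.task.by_id(r.trial_id))
            if hv is None:
                continue
            n += 1
            hits += r.chosen_type == hv.bandit_type
        out[h] = 100.0 * hits / n if n else float("nan")
    return out


def first_choice_value_and_information(
    dataset: ChoiceDataset,
) -> tuple[dict[int, float], dict[int, float]]:
    """(mean expected value, mean initial-sample count) of the first choice.

    Expected value is the mean of the chosen bandit's shown initial samples;
    trials where the novel bandit was chosen are excluded from it (the novel
    bandit shows no samples).  The information measure counts the chosen
    bandit's initial samples, with novel choices included as 0.
    """
    ev: dict[int, float] = {}
    info: dict[int, float] = {}
    for h, recs in _first_by_horizon(dataset).items():
        values, counts = [], []
        for r in recs:
            b = dataset.task.by_id(r.trial_id).bandit(r.chosen_type)
            counts.append(b.n_initial_samples)
            if b.initial_samples:
                values.append(b.initial_sample_mean)
        if not values:
            raise ValueError(
                f"expected-value metric undefined in horizon {h}: every first "
                "choice was the novel bandit"
            )
        ev[h] = float(np.mean(values))
        info[h] = float(np.mean(counts))
    return ev, info


def reward_summary(dataset: ChoiceDataset) -> tuple[dict[int, float], dict[int, float]]:
    """(mean first-draw reward, mean reward over all draws) per horizon."""
    first: dict[int, list] = {}
    alldraws: dict[int, list] = {}
    for r in dataset.records:
        alldraws.setdefault(r.horizon, []).append(r.reward)
        if r.draw_index == 1:
            first.setdefault(r.horizon, []).append(r.reward)
    return (
        {h: float(np.mean(v)) for h, v in first.items()},
        {h: float(np.mean(v)) for h, v in alldraws.items()},
    )


def compute_metrics(dataset: ChoiceDataset) -> MetricsReport:
    ev, info = first_choice_value_and_information(dataset)
    first_r, all_r = reward_summary(dataset)
    return MetricsReport(
        subject_id=dataset.subject_id,
        selection_freq=selection_frequencies(dataset),
        consistency=choice_consistency(dataset),
        high_value_freq=high_value_frequency(dataset),
        mean_expected_value=ev,
        mean_information=info,
        mean_first_reward=first_r,
        mean_all_reward=all_r,
    )


def metrics_to_tidy(reports: list[MetricsReport]) -> pd.DataFrame:
    """Stack per-subject reports into one tidy table for external stats."""
    return pd.concat([r.to_tidy() for r in reports], ignore_index=True)
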