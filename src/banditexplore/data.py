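"""Choice datasets: simulated or observed draws on a task set."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .task import TaskConfig, TaskSet, task_from_csv

__all__ = ["ChoiceRecord", "ChoiceDataset", "choices_to_csv", "choices_from_csv"]


@dataclass(frozen=True)
class ChoiceRecord:
    """One draw: which bandit was chosen on which trial, and the reward."""

    trial_id: int
    horizon: int
    draw_index: int  # 1-based; <= horizon
    chosen_type: str
    chosen_slot: str
    reward: int
    probabilities: Optional[tuple[float, ...]] = None  # at decision time

    def __post_init__(self) -> None:
        if not 1 <= self.draw_index <= self.horizon:
            raise ValueError("draw_index must lie in 1..horizon")


@dataclass
class ChoiceDataset:
    """All draws of one subject or simulated agent on a task set."""

    task: TaskSet
    records: list[ChoiceRecord] = field(default_factory=list)
    subject_id: str = "agent"
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def first_draws(self) -> list[ChoiceRecord]:
        return [r for r in self.records if r.draw_index == 1]

    def first_draw_frame(self) -> pd.DataFrame:
        return self.to_frame().query("draw_index == 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "trial_id": r.trial_id,
                "horizon": r.horizon,
                "draw_index": r.draw_index,
                "chosen_type": r.chosen_type,
                "chosen_slot": r.chosen_slot,
                "reward": r.reward,
            }
            for r in self.records
        )

    def chosen_indices(self, trials=None) -> np.ndarray:
        """Index (0..2) of the first-draw choice within each trial's bandit
        tuple, aligned with ``trials`` (default: the task's trial order)."""
        trials = self.task.trials if trials is None else trials
        first = {r.trial_id: r for r in self.records if r.draw_index == 1}
        out = np.empty(len(trials), int)
        for t, trial in enumerate(trials):
            rec = first[trial.trial_id]
            out[t] = trial.bandit_types.index(rec.chosen_type)
        return out


def choices_to_csv(dataset: ChoiceDataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def choices_from_csv(path, task: TaskSet | str, config: Optional[TaskConfig] = None) -> list[ChoiceDataset]:
    """Load one dataset per subject from a choices CSV.

    ``task`` may be a TaskSet or a path to a task CSV.
    """
    if not isinstance(task, TaskSet):
        task = task_from_csv(task, config=config)
    df = pd.read_csv(path)
    out = []
    for sid, grp in df.groupby("subject_id", sort=True):
        records = [
            ChoiceRecord(
                trial_id=int(r.trial_id),
                horizon=int(r.horizon),
                draw_index=int(r.draw_index),
                chosen_type=str(r.chosen_type),
                chosen_slot=str(r.chosen_slot),
                reward=int(r.reward),
            )
            for r in grp.itertuples()
        ]
        out.append(ChoiceDataset(task=task, records=records, subject_id=str(sid),
                                 provenance={"source": str(path)}))
    return out
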