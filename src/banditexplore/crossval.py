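"""K-fold cross-validated model comparison.

Each subject's first-draw trials are partitioned into K folds (default 10).
For every fold, the model is fitted by multi-start MLE on the other K-1
folds and scored on the held-out fold by the mean predicted probability of
the observed choices, expressed in percent (chance = 100/3 for three
bandits).  Fold accuracies are averaged per subject; across subjects the
model with the highest mean accuracy wins, and each subject is also
assigned the model that predicts their own held-out choices best.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .data import ChoiceDataset
from .fit import FitConfig, design_from_dataset, fit_subject
from .models import ModelSpec, choice_prob_matrix, free_parameters, parse_model

__all__ = ["CVConfig", "CVResult", "UNIFORM_BASELINE", "make_folds",
           "crossvalidated_accuracy", "compare_models"]

CHANCE_ACCURACY = 100.0 / 3.0

#: model name accepted wherever a ModelSpec is: predicts 1/3 for everything
UNIFORM_BASELINE = "uniform"


@dataclass(frozen=True)
class CVConfig:
    K: int = 10
    seed: int = 0
    stratify_by_horizon: bool = False
    group_duplicates: bool = False
    fit: FitConfig = field(default_factory=lambda: FitConfig(method="mle"))


@dataclass
class CVResult:
    accuracy: pd.DataFrame  # subjects x models, held-out accuracy in %
    best_model: pd.Series  # per subject
    mean: pd.Series  # per model, across subjects
    sd: pd.Series


def _partition(ids: np.ndarray, K: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(ids)
    return [np.sort(fold) for fold in np.array_split(perm, K)]


def make_folds(dataset: ChoiceDataset, cv_config: CVConfig) -> list[np.ndarray]:
    """Disjoint, exhaustive folds of first-draw trial ids.

    Optionally stratified by horizon (each fold near-balanced between
    horizons) and/or grouped so that a duplicated trial shares its fold
    with its source.
    """
    rng = np.random.default_rng(cv_config.seed)
    first_ids = np.array(sorted(r.trial_id for r in dataset.first_draws()))
    if not 2 <= cv_config.K <= len(first_ids):
        raise ValueError(f"K must lie in [2, {len(first_ids)}]")

    if cv_config.group_duplicates:
        dup_of = {t.trial_id: t.duplicate_of for t in dataset.task.trials}
        groups: dict[int, list[int]] = {}
        for tid in first_ids:
            root = dup_of.get(tid) if dup_of.get(tid) is not None else tid
            groups.setdefault(root, []).append(tid)
        keys = np.array(sorted(groups))
        folds_keys = _partition(keys, cv_config.K, rng)
        return [
            np.sort(np.concatenate([groups[k] for k in fk])) for fk in folds_keys
        ]

    if cv_config.stratify_by_horizon:
        horizon_of = {t.trial_id: t.horizon for t in dataset.task.trials}
        folds = [np.array([], dtype=int) for _ in range(cv_config.K)]
        for h in sorted({horizon_of[t] for t in first_ids}):
            ids_h = np.array([t for t in first_ids if horizon_of[t] == h])
            for i, fold in enumerate(_partition(ids_h, cv_config.K, rng)):
                folds[i] = np.sort(np.concatenate([folds[i], fold]))
        return folds

    return _partition(first_ids, cv_config.K, rng)


def _resolve(model: Union[str, ModelSpec]) -> Union[str, ModelSpec]:
    if isinstance(model, str):
        return UNIFORM_BASELINE if model == UNIFORM_BASELINE else parse_model(model)
    return model


def crossvalidated_accuracy(
    model_spec: Union[str, ModelSpec],
    dataset: ChoiceDataset,
    cv_config: CVConfig = CVConfig(),
) -> tuple[float, list[float]]:
    """Mean held-out accuracy (%) and the per-fold values.

    Accuracy of a fold is the mean predicted probability of the observed
    choices under the model fitted to the other folds.  The uniform
    baseline needs no fitting and scores exactly 100/3 on any fold.
    """
    model_spec = _resolve(model_spec)
    folds = make_folds(dataset, cv_config)
    if model_spec == UNIFORM_BASELINE:
        per_fold = [CHANCE_ACCURACY] * len(folds)
        return CHANCE_ACCURACY, per_fold

    all_ids = np.concatenate(folds)
    per_fold = []
    for i, fold in enumerate(folds):
        train_ids = np.setdiff1d(all_ids, fold)
        fit_cfg = replace(cv_config.fit, seed=cv_config.fit.seed + 1000 * i)
        result = fit_subject(model_spec, dataset, fit_cfg, trial_ids=train_ids)
        held = design_from_dataset(dataset, trial_ids=fold)
        P = choice_prob_matrix(
            model_spec, result.params, held,
            sampling_precision=fit_cfg.sampling_precision,
        )
        pc = P[np.arange(len(held)), held.chosen]
        per_fold.append(100.0 * float(pc.mean()))
    return float(np.mean(per_fold)), per_fold


def _n_free(model: Union[str, ModelSpec]) -> int:
    if model == UNIFORM_BASELINE:
        return 0
    return len(free_parameters(model))


def compare_models(
    model_specs: Sequence[Union[str, ModelSpec]],
    datasets: Sequence[ChoiceDataset],
    cv_config: CVConfig = CVConfig(),
) -> CVResult:
    """Cross-validated accuracy table over models and subjects.

    Per-subject best-model ties are broken toward the model with fewer
    free parameters.
    """
    if not datasets:
        raise ValueError("at least one dataset is required")
    specs = [_resolve(m) for m in model_specs]
    names = [m if isinstance(m, str) else m.name for m in specs]
    rows = {}
    for ds in datasets:
        rows[ds.subject_id] = {
            name: crossvalidated_accuracy(spec, ds, cv_config)[0]
            for name, spec in zip(names, specs)
        }
    acc = pd.DataFrame.from_dict(rows, orient="index")[names]

    complexity = {name: _n_free(spec) for name, spec in zip(names, specs)}

    def pick_best(row: pd.Series) -> str:
        top = row[row == row.max()].index
        return min(top, key=lambda name: (complexity[name], row.index.get_loc(name)))

    best = acc.apply(pick_best, axis=1)
    return CVResult(accuracy=acc, best_model=best, mean=acc.mean(axis=0),
                    sd=acc.std(axis=0))
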