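"""Choice rules: UCB, Thompson (probability of maximum utility), hybrid,
and the value-free (epsilon-greedy) and novelty-bonus extensions.

The model family crosses three base rules with two binary extensions,
giving 12 models named ``<base>[+vf][+nov]`` (e.g. ``thompson+vf+nov``):

* ``ucb``      — value V_i = Q_i + gamma * sigma_i (+ eta for the novel
  bandit when the novelty extension is on), passed through a softmax with
  inverse temperature beta.
* ``thompson`` — a sample x_i ~ N(V_i, sigma_i^2) is notionally taken from
  each bandit's belief and the bandit with the largest sample is chosen;
  the resulting choice probability is the positive-orthant probability of
  the bivariate normal of pairwise sample differences.
* ``hybrid``   — w * P_ucb + (1 - w) * P_thompson, both computed without the
  value-free mixture.

The value-free extension mixes any base probability vector with the uniform
distribution: P' = P * (1 - eps) + eps / 3, so every displayed bandit keeps
probability at least eps / 3 regardless of its value.

All parameters except the prior mean Q0 and the hybrid weight w may differ
between the short and the long horizon.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from ._bvn import orthant_upper
from .beliefs import BeliefState, Priors, beliefs_after_initial_samples
from .task import TrialSpec

__all__ = [
    "ModelSpec",
    "ParameterSet",
    "FreeParameter",
    "MODEL_NAMES",
    "parse_model",
    "free_parameters",
    "DEFAULT_BOUNDS",
    "bandit_values",
    "softmax_probs",
    "ucb_probs",
    "thompson_probs",
    "hybrid_probs",
    "apply_value_free_mixture",
    "model_choice_probs",
    "TrialArrays",
    "trial_arrays",
    "choice_prob_matrix",
]

HORIZONS = (1, 6)

_HORIZON_SPECIFIC = ("sigma0", "epsilon", "eta", "beta", "gamma")

#: default fitting bounds per parameter
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "sigma0": (0.01, 6.0),
    "Q0": (1.0, 10.0),
    "epsilon": (0.0, 0.5),
    "eta": (0.0, 5.0),
    "beta": (1e-3, 50.0),
    "gamma": (-5.0, 20.0),
    "w": (0.0, 1.0),
}


@dataclass(frozen=True)
class ModelSpec:
    """One of the 12 models: base rule plus binary extensions."""

    base: str = "thompson"
    c_vf: int = 0
    c_n: int = 0

    def __post_init__(self) -> None:
        if self.base not in ("ucb", "thompson", "hybrid"):
            raise ValueError(f"unknown base model {self.base!r}")
        if self.c_vf not in (0, 1) or self.c_n not in (0, 1):
            raise ValueError("c_vf and c_n are binary indicators")

    @property
    def name(self) -> str:
        return self.base + ("+vf" if self.c_vf else "") + ("+nov" if self.c_n else "")

    def __str__(self) -> str:
        return self.name


MODEL_NAMES: tuple[str, ...] = tuple(
    ModelSpec(base, vf, nov).name
    for base, (vf, nov) in itertools.product(
        ("ucb", "thompson", "hybrid"), ((0, 0), (1, 0), (0, 1), (1, 1))
    )
)


def parse_model(name: str) -> ModelSpec:
    parts = name.split("+")
    base, exts = parts[0], parts[1:]
    for e in exts:
        if e not in ("vf", "nov"):
            raise ValueError(f"unknown model extension {e!r} in {name!r}")
    return ModelSpec(base=base, c_vf=int("vf" in exts), c_n=int("nov" in exts))


ScalarOrByHorizon = Union[float, Mapping[int, float]]


def _by_horizon(value: ScalarOrByHorizon, horizons: Sequence[int]) -> dict[int, float]:
    if isinstance(value, Mapping):
        d = {int(h): float(v) for h, v in value.items()}
        missing = [h for h in horizons if h not in d]
        if missing:
            raise ValueError(f"missing horizon(s) {missing} in parameter mapping")
        return d
    return {int(h): float(value) for h in horizons}


@dataclass
class ParameterSet:
    """Free parameters of a model.

    ``Q0`` and ``w`` are shared across horizons; the five remaining
    parameters accept either a scalar (applied to both horizons) or a
    mapping keyed by horizon draw count.
    """

    Q0: float = 5.0
    w: float = 0.5
    sigma0: ScalarOrByHorizon = 1.0
    epsilon: ScalarOrByHorizon = 0.0
    eta: ScalarOrByHorizon = 0.0
    beta: ScalarOrByHorizon = 1.0
    gamma: ScalarOrByHorizon = 0.0
    horizons: tuple[int, ...] = HORIZONS

    def __post_init__(self) -> None:
        for name in _HORIZON_SPECIFIC:
            setattr(self, name, _by_horizon(getattr(self, name), self.horizons))
        for h, v in self.sigma0.items():
            if v <= 0:
                raise ValueError(f"sigma0 must be > 0 (horizon {h})")

    def at(self, horizon: int) -> "TrialParameters":
        """Scalar view of the parameters for one horizon."""
        return TrialParameters(
            Q0=self.Q0,
            w=self.w,
            sigma0=self.sigma0[horizon],
            epsilon=self.epsilon[horizon],
            eta=self.eta[horizon],
            beta=self.beta[horizon],
            gamma=self.gamma[horizon],
        )

    def priors(self, horizon: int) -> Priors:
        return Priors(Q0=self.Q0, sigma0=self.sigma0[horizon])


@dataclass(frozen=True)
class TrialParameters:
    Q0: float
    w: float
    sigma0: float
    epsilon: float
    eta: float
    beta: float
    gamma: float


@dataclass(frozen=True)
class FreeParameter:
    """One fitted scalar: parameter name, horizon (None if shared), bounds."""

    name: str
    horizon: Optional[int]
    bounds: tuple[float, float]

    @property
    def label(self) -> str:
        return self.name if self.horizon is None else f"{self.name}[{self.horizon}]"


def free_parameters(
    spec: ModelSpec,
    horizons: Sequence[int] = HORIZONS,
    bounds: Optional[Mapping[str, tuple[float, float]]] = None,
) -> list[FreeParameter]:
    """Ordered free-parameter layout for a model.

    The winning model ``thompson+vf+nov`` has 7: Q0 plus horizon-specific
    sigma0, epsilon and eta.
    """
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    names: list[str] = ["sigma0"]
    if spec.base in ("ucb", "hybrid"):
        names += ["beta", "gamma"]
    if spec.c_vf:
        names.append("epsilon")
    if spec.c_n:
        names.append("eta")
    out = [FreeParameter("Q0", None, tuple(b["Q0"]))]
    if spec.base == "hybrid":
        out.append(FreeParameter("w", None, tuple(b["w"])))
    for name in names:
        for h in horizons:
            out.append(FreeParameter(name, int(h), tuple(b[name])))
    return out


def parameter_set_from_vector(
    x: Sequence[float],
    layout: Sequence[FreeParameter],
    horizons: Sequence[int] = HORIZONS,
) -> ParameterSet:
    """Assemble a ParameterSet from an optimiser vector (inverse of layout)."""
    fields: dict = {n: {int(h): DEFAULT_NEUTRAL[n] for h in horizons}
                    for n in _HORIZON_SPECIFIC}
    shared = {"Q0": 5.0, "w": 0.5}
    for value, fp in zip(x, layout):
        if fp.horizon is None:
            shared[fp.name] = float(value)
        else:
            fields[fp.name][fp.horizon] = float(value)
    return ParameterSet(Q0=shared["Q0"], w=shared["w"], horizons=tuple(horizons),
                        **fields)


#: values used for parameters a model does not include
DEFAULT_NEUTRAL = {"sigma0": 1.0, "epsilon": 0.0, "eta": 0.0, "beta": 1.0,
                   "gamma": 0.0}


def vector_from_parameter_set(
    params: ParameterSet, layout: Sequence[FreeParameter]
) -> np.ndarray:
    out = []
    for fp in layout:
        if fp.horizon is None:
            out.append(getattr(params, fp.name))
        else:
            out.append(getattr(params, fp.name)[fp.horizon])
    return np.asarray(out, float)


# ---------------------------------------------------------------------------
# single-trial choice rules


def _novel_indicator(beliefs: BeliefState, trial: TrialSpec) -> np.ndarray:
    """1 for the novel-type bandit while it still has no observed samples."""
    return np.array(
        [
            1.0 if (t == "novel" and beliefs.n_observations[i] == 0) else 0.0
            for i, t in enumerate(beliefs.bandit_types)
        ]
    )


def bandit_values(
    beliefs: BeliefState,
    params: TrialParameters,
    trial: TrialSpec,
    include_uncertainty_bonus: bool,
    c_n: int = 0,
) -> np.ndarray:
    """V = Q (+ gamma * sigma on the UCB path) (+ eta for the novel bandit)."""
    V = beliefs.Q.copy()
    if include_uncertainty_bonus:
        V = V + params.gamma * beliefs.sigma
    if c_n:
        V = V + params.eta * _novel_indicator(beliefs, trial)
    return V


def softmax_probs(values: np.ndarray, beta) -> np.ndarray:
    """Max-shifted softmax; beta = 0 gives the uniform distribution.

    ``beta`` may be a scalar or an array broadcastable against the leading
    axes of ``values`` (one temperature per row).
    """
    beta = np.asarray(beta, float)
    if np.any(beta < 0):
        raise ValueError("beta must be >= 0")
    z = beta[..., None] * np.asarray(values, float) if beta.ndim else beta * np.asarray(values, float)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _thompson_from_values(V: np.ndarray, var: np.ndarray) -> np.ndarray:
    """Probability-of-maximum-utility over (..., 3) values/variances.

    The three per-bandit orthant probabilities of every row are evaluated in
    a single vectorised bivariate-normal CDF call; arbitrary leading axes
    are supported (trials, or optimiser batch x trials).
    """
    V = np.atleast_2d(np.asarray(V, float))
    var = np.atleast_2d(np.asarray(var, float))
    shape = V.shape
    m1 = np.empty(shape)
    m2 = np.empty(shape)
    v1 = np.empty(shape)
    v2 = np.empty(shape)
    for i in range(3):
        j, k = [c for c in range(3) if c != i]
        m1[..., i] = V[..., i] - V[..., j]
        m2[..., i] = V[..., i] - V[..., k]
        v1[..., i] = var[..., i] + var[..., j]
        v2[..., i] = var[..., i] + var[..., k]
    P = orthant_upper(
        m1.ravel(), m2.ravel(), v1.ravel(), v2.ravel(), var.ravel()
    ).reshape(shape)
    P = np.clip(P, 0.0, None)
    return P / P.sum(axis=-1, keepdims=True)


def ucb_probs(
    beliefs: BeliefState, params: TrialParameters, trial: TrialSpec, c_n: int = 0
) -> np.ndarray:
    V = bandit_values(beliefs, params, trial, include_uncertainty_bonus=True, c_n=c_n)
    return softmax_probs(V, params.beta)


def thompson_probs(
    beliefs: BeliefState, params: TrialParameters, trial: TrialSpec, c_n: int = 0
) -> np.ndarray:
    """P(c = i) = P(x_i > x_j for all j), x_i ~ N(V_i, sigma_i^2)."""
    V = bandit_values(beliefs, params, trial, include_uncertainty_bonus=False, c_n=c_n)
    var = 1.0 / beliefs.tau
    return _thompson_from_values(V, var)[0]


def hybrid_probs(
    beliefs: BeliefState, params: TrialParameters, trial: TrialSpec, c_n: int = 0
) -> np.ndarray:
    """w * P_ucb + (1 - w) * P_thompson, both without the value-free mixture."""
    if not 0.0 <= params.w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    return params.w * ucb_probs(beliefs, params, trial, c_n) + (
        1.0 - params.w
    ) * thompson_probs(beliefs, params, trial, c_n)


def apply_value_free_mixture(probs, epsilon: float, c_vf: int) -> np.ndarray:
    """P' = P * (1 - c_vf * eps) + c_vf * eps / 3 along the last axis."""
    probs = np.asarray(probs, float)
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    if not c_vf:
        return probs.copy()
    k = probs.shape[-1]
    return probs * (1.0 - epsilon) + epsilon / k


def probs_from_beliefs(
    spec: ModelSpec, params: TrialParameters, beliefs: BeliefState, trial: TrialSpec
) -> np.ndarray:
    """Base rule + value-free mixture, from an arbitrary belief state."""
    if spec.base == "ucb":
        base = ucb_probs(beliefs, params, trial, spec.c_n)
    elif spec.base == "thompson":
        base = thompson_probs(beliefs, params, trial, spec.c_n)
    else:
        base = hybrid_probs(beliefs, params, trial, spec.c_n)
    return apply_value_free_mixture(base, params.epsilon, spec.c_vf)


def model_choice_probs(
    model_spec: ModelSpec,
    params: ParameterSet,
    trial: TrialSpec,
    horizon: Optional[int] = None,
    sampling_precision: float = 1.25,
) -> np.ndarray:
    """First-draw choice probabilities for one trial.

    Beliefs are initialised at the prior and conditioned on the shown
    initial samples before the base rule and the value-free mixture apply.
    Deterministic given its inputs.
    """
    h = trial.horizon if horizon is None else horizon
    p = params.at(h)
    beliefs = beliefs_after_initial_samples(
        Priors(Q0=p.Q0, sigma0=p.sigma0), trial, sampling_precision
    )
    return probs_from_beliefs(model_spec, p, beliefs, trial)


# ---------------------------------------------------------------------------
# batch evaluation (used by fitting and simulation)


@dataclass
class TrialArrays:
    """Per-trial sufficient statistics for vectorised likelihoods.

    Row t describes one trial's three displayed bandits (in the trial's
    bandit order): number of initial samples, their sum, and whether the
    bandit is novel.  ``chosen`` holds the index of the first-draw choice
    when the arrays were built from a dataset.
    """

    n_samples: np.ndarray  # (T, 3) int
    sample_sum: np.ndarray  # (T, 3) float
    is_novel: np.ndarray  # (T, 3) float 0/1
    horizon: np.ndarray  # (T,) int
    trial_ids: np.ndarray  # (T,) int
    chosen: Optional[np.ndarray] = None  # (T,) int or None

    def __len__(self) -> int:
        return len(self.horizon)

    def horizon_groups(self) -> list[tuple[int, np.ndarray]]:
        """(horizon, row mask) pairs, cached — this sits inside the
        optimiser's inner loop."""
        if not hasattr(self, "_hgroups"):
            self._hgroups = [
                (int(h), self.horizon == h) for h in np.unique(self.horizon)
            ]
        return self._hgroups

    def subset(self, idx) -> "TrialArrays":
        idx = np.asarray(idx)
        return TrialArrays(
            self.n_samples[idx],
            self.sample_sum[idx],
            self.is_novel[idx],
            self.horizon[idx],
            self.trial_ids[idx],
            None if self.chosen is None else self.chosen[idx],
        )


def trial_arrays(
    trials: Sequence[TrialSpec], chosen: Optional[Sequence[int]] = None
) -> TrialArrays:
    T = len(trials)
    n = np.zeros((T, 3), int)
    s = np.zeros((T, 3), float)
    nov = np.zeros((T, 3), float)
    hor = np.zeros(T, int)
    ids = np.zeros(T, int)
    for t, trial in enumerate(trials):
        hor[t] = trial.horizon
        ids[t] = trial.trial_id
        for i, b in enumerate(trial.bandits):
            n[t, i] = len(b.initial_samples)
            s[t, i] = sum(b.initial_samples)
            nov[t, i] = 1.0 if b.bandit_type == "novel" else 0.0
    return TrialArrays(
        n, s, nov, hor, ids,
        None if chosen is None else np.asarray(chosen, int),
    )


def choice_prob_matrix(
    spec: ModelSpec,
    params: ParameterSet,
    arrays: TrialArrays,
    sampling_precision: float = 1.25,
) -> np.ndarray:
    """(T, 3) first-draw choice probabilities for every trial in ``arrays``.

    Equivalent to calling :func:`model_choice_probs` per trial, but the
    posterior statistics and the choice rule are evaluated with array
    arithmetic, grouped by horizon.
    """
    per_h = {h: params.at(h) for h, _ in arrays.horizon_groups()}
    return _prob_matrix_core(spec, per_h, params.w, arrays, sampling_precision)


def _prob_matrix_core(
    spec: ModelSpec,
    per_h: Mapping[int, TrialParameters],
    w: float,
    arrays: TrialArrays,
    sampling_precision: float,
) -> np.ndarray:
    T = len(arrays)
    Q = np.empty((T, 3))
    var = np.empty((T, 3))
    eps = np.empty(T)
    eta = np.empty(T)
    beta = np.empty(T)
    gamma = np.empty(T)
    for h, m in arrays.horizon_groups():
        p = per_h[h]
        tau0 = 1.0 / p.sigma0**2
        tau = tau0 + arrays.n_samples[m] * sampling_precision
        Q[m] = (tau0 * p.Q0 + sampling_precision * arrays.sample_sum[m]) / tau
        var[m] = 1.0 / tau
        eps[m], eta[m], beta[m], gamma[m] = p.epsilon, p.eta, p.beta, p.gamma

    bonus = eta[:, None] * arrays.is_novel if spec.c_n else 0.0
    if spec.base in ("ucb", "hybrid"):
        P_ucb = softmax_probs(Q + gamma[:, None] * np.sqrt(var) + bonus, beta)
    if spec.base in ("thompson", "hybrid"):
        P_th = _thompson_from_values(Q + bonus, var)

    if spec.base == "ucb":
        base = P_ucb
    elif spec.base == "thompson":
        base = P_th
    else:
        base = w * P_ucb + (1.0 - w) * P_th
    if not spec.c_vf:
        return base
    return base * (1.0 - eps[:, None]) + eps[:, None] / 3.0
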