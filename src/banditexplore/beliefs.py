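"""Gaussian belief tracking over bandit means (stationary Kalman filter).

Each displayed bandit carries a Gaussian belief N(Q, 1/tau) over its mean
reward.  Observing a sample m with sampling precision tau_samp = 1/S^2
updates the belief conjugately:

    Q'   = (tau * Q + tau_samp * m) / (tau + tau_samp)
    tau' = tau + tau_samp

These are the stationary-bandit Kalman filter equations: the posterior mean
is a precision-weighted average of the prior mean and the sample, and
precision accumulates additively, so after n samples
tau = 1/sigma0^2 + n * tau_samp exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .task import TrialSpec

__all__ = ["Priors", "BeliefState", "init_beliefs", "update_belief",
           "beliefs_after_initial_samples"]


@dataclass(frozen=True)
class Priors:
    """Prior belief N(Q0, sigma0^2) shared by all bandits."""

    Q0: float = 5.0
    sigma0: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be > 0")


@dataclass
class BeliefState:
    """Posterior mean Q and precision tau per displayed bandit.

    Arrays are aligned with ``bandit_types``; ``sigma`` exposes the posterior
    SD (1/sqrt(tau)) used by the UCB information bonus and Thompson sampling.
    """

    bandit_types: tuple[str, ...]
    Q: np.ndarray
    tau: np.ndarray
    n_observations: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.n_observations is None:
            self.n_observations = np.zeros(len(self.bandit_types), dtype=int)
        if np.any(self.tau <= 0):
            raise ValueError("belief precisions must be positive")

    @property
    def sigma(self) -> np.ndarray:
        return 1.0 / np.sqrt(self.tau)

    def index_of(self, bandit_type: str) -> int:
        try:
            return self.bandit_types.index(bandit_type)
        except ValueError:
            raise KeyError(f"bandit {bandit_type!r} is not displayed") from None

    def copy(self) -> "BeliefState":
        return BeliefState(self.bandit_types, self.Q.copy(), self.tau.copy(),
                           self.n_observations.copy())


def init_beliefs(priors: Priors, trial: TrialSpec) -> BeliefState:
    """Assign the prior N(Q0, sigma0^2) to every displayed bandit."""
    types = trial.bandit_types
    k = len(types)
    tau0 = 1.0 / priors.sigma0**2
    return BeliefState(types, np.full(k, priors.Q0), np.full(k, tau0))


def update_belief(
    state: BeliefState,
    bandit_type: str,
    sample_value: float,
    sampling_precision: float,
) -> BeliefState:
    """Conjugate update of one bandit's belief with an observed sample.

    Returns a new state; other bandits are untouched.
    """
    if sampling_precision <= 0:
        raise ValueError("sampling_precision must be > 0")
    i = state.index_of(bandit_type)
    new = state.copy()
    tau = state.tau[i]
    new.Q[i] = (tau * state.Q[i] + sampling_precision * sample_value) / (
        tau + sampling_precision
    )
    new.tau[i] = tau + sampling_precision
    new.n_observations[i] += 1
    return new


def beliefs_after_initial_samples(
    priors: Priors, trial: TrialSpec, sampling_precision: float = 1.25
) -> BeliefState:
    """Beliefs after conditioning on every shown initial sample.

    The novel bandit shows no samples and so retains exactly the prior.
    """
    state = init_beliefs(priors, trial)
    for b in trial.bandits:
        for m in b.initial_samples:
            state = update_belief(state, b.bandit_type, m, sampling_precision)
    return state
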