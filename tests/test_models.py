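"""Choice rules: simplex outputs, oracle equivalences, extension effects."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal

from banditexplore import (
    BanditInstance,
    ParameterSet,
    Priors,
    TrialSpec,
    apply_value_free_mixture,
    beliefs_after_initial_samples,
    hybrid_probs,
    model_choice_probs,
    parse_model,
    softmax_probs,
    thompson_probs,
    ucb_probs,
)
from banditexplore._bvn import bvn_cdf
from banditexplore.beliefs import BeliefState
from banditexplore.models import (
    MODEL_NAMES,
    TrialParameters,
    _thompson_from_values,
    bandit_values,
    choice_prob_matrix,
    free_parameters,
    trial_arrays,
)


def make_trial(samples_by_type):
    bandits = tuple(
        BanditInstance(bandit_type=t, generative_mean=5.0, initial_samples=tuple(s))
        for t, s in samples_by_type.items()
    )
    return TrialSpec(trial_id=0, combination_id=1, bandits=bandits)


TRIAL = make_trial({"certain_standard": (5, 6, 7), "standard": (4,), "novel": ()})


def tp(**kw):
    base = dict(Q0=5.0, w=0.5, sigma0=1.0, epsilon=0.0, eta=0.0, beta=1.0, gamma=0.0)
    base.update(kw)
    return TrialParameters(**base)


def manual_state(types, Q, sigma):
    return BeliefState(tuple(types), np.asarray(Q, float),
                       1.0 / np.asarray(sigma, float) ** 2)


class TestBvn:
    def test_against_scipy_mvn(self, rng):
        for _ in range(40):
            h, k = rng.normal(scale=1.5, size=2)
            r = rng.uniform(-0.999, 0.999)
            exact = multivariate_normal(mean=[0, 0], cov=[[1, r], [r, 1]]).cdf([h, k])
            assert bvn_cdf(h, k, r) == pytest.approx(exact, abs=1e-8)

    def test_edge_cases(self):
        assert bvn_cdf(0.0, 0.0, 0.0) == pytest.approx(0.25, abs=1e-10)
        # Phi2(0,0,rho) = 1/4 + asin(rho)/(2 pi)
        assert bvn_cdf(0.0, 0.0, 0.5) == pytest.approx(
            0.25 + np.arcsin(0.5) / (2 * np.pi), abs=1e-8
        )
        assert bvn_cdf(1.0, 2.0, 1.0) == pytest.approx(
            multivariate_normal(mean=[0], cov=[[1]]).cdf([1.0])[()], abs=1e-9
        )


class TestSoftmax:
    def test_zero_temperature_is_uniform(self):
        assert np.allclose(softmax_probs(np.array([9.0, 1.0, 4.0]), 0.0), 1 / 3)

    def test_equal_values_uniform(self):
        assert np.allclose(softmax_probs(np.array([2.0, 2.0, 2.0]), 7.3), 1 / 3)

    def test_worked_example(self):
        # e^6, e^5, e^4 normalised
        e = np.exp([6.0, 5.0, 4.0])
        expected = e / e.sum()
        got = softmax_probs(np.array([6.0, 5.0, 4.0]), 1.0)
        assert np.allclose(got, expected)
        assert got == pytest.approx([0.66524096, 0.24472847, 0.09003057], abs=1e-6)

    def test_large_beta_stable(self):
        p = softmax_probs(np.array([1000.0, 999.0, 0.0]), 50.0)
        assert np.isfinite(p).all() and p.sum() == pytest.approx(1.0)


class TestBanditValues:
    def test_ucb_uncertainty_bonus(self):
        state = manual_state(["standard", "novel", "low"], [5.0, 5.0, 5.0], [2.0, 1.0, 1.0])
        V = bandit_values(state, tp(gamma=0.5), TRIAL, include_uncertainty_bonus=True)
        assert V[0] == pytest.approx(6.0)

    def test_novelty_bonus_applies_to_novel_only(self):
        state = manual_state(["standard", "novel", "low"], [3.2, 3.2, 3.2], [1.0, 1.0, 1.0])
        V = bandit_values(state, tp(eta=2.625), TRIAL,
                          include_uncertainty_bonus=False, c_n=1)
        assert V.tolist() == pytest.approx([3.2, 5.825, 3.2])

    def test_without_novelty_extension(self):
        state = manual_state(["standard", "novel", "low"], [3.2, 3.2, 3.2], [1.0, 1.0, 1.0])
        V = bandit_values(state, tp(eta=2.625), TRIAL,
                          include_uncertainty_bonus=False, c_n=0)
        assert np.allclose(V, 3.2)


class TestThompson:
    def test_exchangeable_is_uniform(self):
        state = manual_state(["standard", "novel", "low"], [5.0] * 3, [1.3] * 3)
        p = thompson_probs(state, tp(), TRIAL)
        assert np.allclose(p, 1 / 3, atol=1e-9)

    def test_dominated_bandit(self):
        state = manual_state(
            ["standard", "novel", "low"], [5.0, 5.0, 5.0 - 100.0], [1.0, 1.0, 1.0]
        )
        p = thompson_probs(state, tp(), TRIAL)
        assert p[:2] == pytest.approx([0.5, 0.5], abs=1e-6)
        assert p[2] < 1e-9

    def test_matches_sampling_oracle(self, rng):
        """Orthant probabilities equal Monte-Carlo argmax frequencies of
        independent Gaussian value samples (3 SE at n = 200,000)."""
        n = 200_000
        for _ in range(8):
            V = rng.uniform(2, 8, size=3)
            sig = rng.uniform(0.3, 2.5, size=3)
            p = _thompson_from_values(V, sig**2)[0]
            draws = rng.normal(V, sig, size=(n, 3))
            freq = np.bincount(np.argmax(draws, axis=1), minlength=3) / n
            se = np.sqrt(freq * (1 - freq) / n)
            assert np.all(np.abs(p - freq) < 3 * se + 1e-4)


class TestValueFreeMixture:
    def test_off_is_identity(self):
        p = np.array([0.7, 0.2, 0.1])
        assert np.allclose(apply_value_free_mixture(p, 0.4, c_vf=0), p)

    def test_full_epsilon_is_uniform(self):
        p = apply_value_free_mixture(np.array([0.9, 0.1, 0.0]), 1.0, c_vf=1)
        assert np.allclose(p, 1 / 3)

    def test_worked_example(self):
        p = apply_value_free_mixture(np.array([0.9, 0.1, 0.0]), 0.3, c_vf=1)
        assert p == pytest.approx([0.73, 0.17, 0.10])

    def test_preserves_simplex_and_floor(self):
        p = apply_value_free_mixture(np.array([1.0, 0.0, 0.0]), 0.3, c_vf=1)
        assert p.sum() == pytest.approx(1.0)
        assert (p >= 0.3 / 3 - 1e-12).all()


class TestHybrid:
    def setup_method(self):
        self.state = manual_state(
            ["standard", "novel", "low"], [5.0, 4.0, 3.0], [1.0, 2.0, 0.5]
        )

    def test_endpoints(self):
        pu = ucb_probs(self.state, tp(beta=2.0, gamma=0.3), TRIAL)
        pt = thompson_probs(self.state, tp(), TRIAL)
        h1 = hybrid_probs(self.state, tp(w=1.0, beta=2.0, gamma=0.3), TRIAL)
        h0 = hybrid_probs(self.state, tp(w=0.0, beta=2.0, gamma=0.3), TRIAL)
        assert np.allclose(h1, pu)
        assert np.allclose(h0, pt)

    def test_midpoint_and_monotonicity(self):
        pu = ucb_probs(self.state, tp(beta=2.0, gamma=0.3), TRIAL)
        pt = thompson_probs(self.state, tp(), TRIAL)
        h = hybrid_probs(self.state, tp(w=0.5, beta=2.0, gamma=0.3), TRIAL)
        assert np.allclose(h, 0.5 * (pu + pt))
        assert h.sum() == pytest.approx(1.0)
        ws = np.linspace(0, 1, 7)
        p0 = np.array([
            hybrid_probs(self.state, tp(w=w, beta=2.0, gamma=0.3), TRIAL)[0]
            for w in ws
        ])
        assert np.all(np.diff(p0) > 0) or np.all(np.diff(p0) < 0)


class TestModelChoiceProbs:
    def test_no_extension_equals_base(self):
        params = ParameterSet(Q0=4.0, sigma0=1.5)
        spec = parse_model("thompson")
        p = model_choice_probs(spec, params, TRIAL, horizon=1)
        beliefs = beliefs_after_initial_samples(Priors(4.0, 1.5), TRIAL, 1.25)
        expected = thompson_probs(beliefs, params.at(1), TRIAL)
        assert np.allclose(p, expected)

    def test_epsilon_floor(self):
        params = ParameterSet(Q0=4.0, sigma0=1.5, epsilon=0.3)
        p = model_choice_probs(parse_model("ucb+vf"), params, TRIAL, horizon=1)
        assert (p >= 0.1 - 1e-12).all() and (p < 1).all()

    def test_greedy_limit(self):
        params = ParameterSet(Q0=5.0, sigma0=1.0, beta=50.0, gamma=0.0)
        p = model_choice_probs(parse_model("ucb"), params, TRIAL, horizon=1)
        beliefs = beliefs_after_initial_samples(Priors(5.0, 1.0), TRIAL, 1.25)
        assert p[np.argmax(beliefs.Q)] > 0.99

    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_simplex_and_batch_equivalence(self, name, small_taskset):
        """Every model yields simplex probabilities, and the vectorised
        batch path agrees with the per-trial path."""
        spec = parse_model(name)
        params = ParameterSet(
            Q0=3.5, w=0.4, sigma0={1: 0.8, 6: 1.6}, epsilon={1: 0.2, 6: 0.05},
            eta={1: 0.5, 6: 2.0}, beta={1: 2.0, 6: 4.0}, gamma={1: 0.3, 6: 1.0},
        )
        trials = small_taskset.trials[:40]
        P = choice_prob_matrix(spec, params, trial_arrays(trials))
        assert np.all(P >= 0) and np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
        for t in (0, 7, 23):
            p1 = model_choice_probs(spec, params, trials[t])
            assert np.allclose(p1, P[t], atol=1e-10)

    @pytest.mark.parametrize("base", ["ucb", "thompson", "hybrid"])
    def test_novelty_bonus_monotone(self, base):
        """Raising eta strictly increases the novel bandit's probability."""
        spec = parse_model(base + "+nov")
        i_novel = TRIAL.bandit_types.index("novel")
        probs = []
        for eta in (0.0, 1.0, 2.5, 5.0):
            params = ParameterSet(Q0=4.0, w=0.4, sigma0=1.2, eta=eta,
                                  beta=2.0, gamma=0.3)
            probs.append(model_choice_probs(spec, params, TRIAL, horizon=1)[i_novel])
        assert np.all(np.diff(probs) > 0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        q0=st.floats(1.0, 10.0),
        sigma0=st.floats(0.05, 6.0),
        eps=st.floats(0.0, 0.5),
        eta=st.floats(0.0, 5.0),
        name=st.sampled_from(MODEL_NAMES),
    )
    def test_simplex_property(self, q0, sigma0, eps, eta, name):
        params = ParameterSet(Q0=q0, sigma0=sigma0, epsilon=eps, eta=eta,
                              beta=3.0, gamma=0.5, w=0.3)
        p = model_choice_probs(parse_model(name), params, TRIAL, horizon=1)
        assert np.all(p >= -1e-12)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        if "vf" in name:
            assert np.all(p >= eps / 3 - 1e-9)
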