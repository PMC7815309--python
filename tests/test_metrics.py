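"""Behavioural metrics: frequencies, consistency, value/information of the
first choice, reward summaries."""

import numpy as np
import pytest

from banditexplore import (
    ChoiceDataset,
    ChoiceRecord,
    ParameterSet,
    TaskConfig,
    build_taskset,
    choice_consistency,
    compute_metrics,
    first_choice_value_and_information,
    parse_model,
    reward_summary,
    selection_frequencies,
    simulate_dataset,
)
from banditexplore.models import choice_prob_matrix, trial_arrays


def dataset_choosing(taskset, pick, horizon=None):
    """Dataset whose first draw on each trial is pick(trial) -> bandit."""
    records = []
    for t in taskset.trials:
        if horizon is not None and t.horizon != horizon:
            continue
        b = pick(t)
        records.append(
            ChoiceRecord(trial_id=t.trial_id, horizon=t.horizon, draw_index=1,
                         chosen_type=b.bandit_type, chosen_slot=b.position,
                         reward=5)
        )
    return ChoiceDataset(task=taskset, records=records)


class TestSelectionFrequencies:
    def test_always_chosen_when_present_is_75(self, small_taskset):
        def pick(t):
            try:
                return t.bandit("standard")
            except KeyError:
                return t.bandits[0]

        ds = dataset_choosing(small_taskset, pick)
        freqs = selection_frequencies(ds)
        for h in (1, 6):
            assert freqs[h]["standard"] == pytest.approx(75.0)

    def test_never_chosen_is_zero(self, small_taskset):
        def pick(t):
            others = [b for b in t.bandits if b.bandit_type != "novel"]
            return others[0]

        ds = dataset_choosing(small_taskset, pick)
        freqs = selection_frequencies(ds)
        assert freqs[1]["novel"] == 0.0

    def test_frequencies_sum_to_100(self, simulated_dataset):
        freqs = selection_frequencies(simulated_dataset)
        for h, per_type in freqs.items():
            assert sum(per_type.values()) == pytest.approx(100.0)

    def test_uniform_chooser_near_25(self):
        ts = build_taskset(TaskConfig(seed=31, trials_per_combination=25))
        params = ParameterSet(Q0=5.0, sigma0=1.0, epsilon=1.0)
        rates = {t: [] for t in ("certain_standard", "standard", "novel", "low")}
        for s in range(10):
            ds = simulate_dataset(parse_model("thompson+vf"), params, ts, seed=s)
            freqs = selection_frequencies(ds)
            for t in rates:
                rates[t].append((freqs[1][t] + freqs[6][t]) / 2)
        n = 10 * 400
        se = 100 * np.sqrt(0.25 * 0.75 / n)
        for t, r in rates.items():
            assert abs(np.mean(r) - 25.0) < 3 * se


class TestConsistency:
    def test_perfectly_consistent(self, small_taskset):
        ds = dataset_choosing(small_taskset, lambda t: t.bandits[0])
        # slot 0 differs between duplicates, but type-matching is what counts
        cons = choice_consistency(
            dataset_choosing(
                small_taskset,
                lambda t: min(t.bandits, key=lambda b: b.bandit_type),
            )
        )
        for h in (1, 6):
            assert cons[h] == 100.0

    def test_uniform_chooser_near_one_third(self):
        ts = build_taskset(TaskConfig(seed=13, trials_per_combination=10))
        params = ParameterSet(Q0=5.0, sigma0=1.0, epsilon=1.0)
        vals = []
        for s in range(30):
            ds = simulate_dataset(parse_model("thompson+vf"), params, ts, seed=s)
            cons = choice_consistency(ds)
            vals.extend([cons[1], cons[6]])
        n_pairs = 30 * 2 * 40
        se = 100 * np.sqrt((1 / 3) * (2 / 3) / n_pairs)
        assert abs(np.mean(vals) - 100 / 3) < 3 * se

    def test_deterministic_maximiser_fully_consistent(self, small_taskset):
        """Identical options imply an identical argmax, hence 100%."""

        def pick(t):
            with_samples = [b for b in t.bandits if b.initial_samples]
            return max(with_samples, key=lambda b: (b.initial_sample_mean,
                                                    b.bandit_type))

        cons = choice_consistency(dataset_choosing(small_taskset, pick))
        assert cons[1] == 100.0 and cons[6] == 100.0

    def test_matches_policy_squared_probability_oracle(self, winning_model):
        """For a memoryless stochastic policy the expected consistency is
        the average over duplicate pairs of sum_i p_i^2."""
        ts = build_taskset(TaskConfig(seed=17, trials_per_combination=5))
        params = ParameterSet(Q0=3.2, sigma0=1.312, epsilon=0.2, eta=2.625)
        # analytic expectation from the policy probabilities
        pair_probs = []
        for orig, dup in ts.duplicate_pairs():
            P = choice_prob_matrix(winning_model, params, trial_arrays([orig]))[0]
            Pd = choice_prob_matrix(winning_model, params, trial_arrays([dup]))[0]
            o_types = orig.bandit_types
            d_types = dup.bandit_types
            pair_probs.append(
                sum(P[o_types.index(t)] * Pd[d_types.index(t)] for t in o_types)
            )
        expected = 100 * np.mean(pair_probs)
        sims = []
        for s in range(150):
            ds = simulate_dataset(winning_model, params, ts, seed=s)
            cons = choice_consistency(ds)
            sims.append(np.mean([cons[1], cons[6]]))
        n_pairs = 150 * 40
        p = expected / 100
        se = 100 * np.sqrt(p * (1 - p) / n_pairs)
        assert abs(np.mean(sims) - expected) < 3 * se


class TestValueAndInformation:
    def test_always_certain_standard_info_3(self, small_taskset):
        def pick(t):
            try:
                return t.bandit("certain_standard")
            except KeyError:
                return [b for b in t.bandits if b.initial_samples][0]

        ds = dataset_choosing(small_taskset, pick)
        _, info = first_choice_value_and_information(ds)
        assert 1.0 < info[1] <= 3.0

    def test_worked_example(self, small_taskset):
        h1 = [t for t in small_taskset.trials if t.horizon == 1]
        # choose a 1-sample bandit on one trial and a 3-sample bandit on another
        t1 = next(t for t in h1 if any(len(b.initial_samples) == 1 for b in t.bandits))
        t2 = next(t for t in h1 if t is not t1 and t.has("certain_standard"))
        b1 = next(b for b in t1.bandits if len(b.initial_samples) == 1)
        b2 = next(b for b in t2.bandits if len(b.initial_samples) == 3)
        records = [
            ChoiceRecord(trial_id=t1.trial_id, horizon=1, draw_index=1,
                         chosen_type=b1.bandit_type, chosen_slot=b1.position,
                         reward=5),
            ChoiceRecord(trial_id=t2.trial_id, horizon=1, draw_index=1,
                         chosen_type=b2.bandit_type, chosen_slot=b2.position,
                         reward=5),
        ]
        ds = ChoiceDataset(task=small_taskset, records=records)
        ev, info = first_choice_value_and_information(ds)
        expected = np.mean([b1.initial_sample_mean, b2.initial_sample_mean])
        assert ev[1] == pytest.approx(expected)
        assert info[1] == pytest.approx(2.0)

    def test_all_novel_choices_error(self, small_taskset):
        trials = [t for t in small_taskset.trials if t.has("novel")]
        records = [
            ChoiceRecord(trial_id=t.trial_id, horizon=t.horizon, draw_index=1,
                         chosen_type="novel",
                         chosen_slot=t.bandit("novel").position, reward=5)
            for t in trials
        ]
        ds = ChoiceDataset(task=small_taskset, records=records)
        with pytest.raises(ValueError):
            first_choice_value_and_information(ds)


class TestRewardSummary:
    def test_single_long_trial_mean(self, small_taskset):
        t = next(t for t in small_taskset.trials if t.horizon == 6)
        b = t.bandits[0]
        rewards = [4, 5, 6, 6, 7, 8]
        records = [
            ChoiceRecord(trial_id=t.trial_id, horizon=6, draw_index=i + 1,
                         chosen_type=b.bandit_type, chosen_slot=b.position,
                         reward=r)
            for i, r in enumerate(rewards)
        ]
        ds = ChoiceDataset(task=small_taskset, records=records)
        first, alld = reward_summary(ds)
        assert alld[6] == pytest.approx(6.0)
        assert first[6] == pytest.approx(4.0)

    def test_short_horizon_first_equals_all(self, simulated_dataset):
        first, alld = reward_summary(simulated_dataset)
        assert first[1] == pytest.approx(alld[1])

    def test_greedy_beats_noisy_on_first_draw_reward(self, winning_model):
        ts = build_taskset(TaskConfig(seed=41, trials_per_combination=25))
        greedy = ParameterSet(Q0=3.2, sigma0=1.312, epsilon=0.0, eta=0.0)
        noisy = ParameterSet(Q0=3.2, sigma0=1.312, epsilon=0.3, eta=0.0)
        g_rewards, n_rewards = [], []
        for s in range(10):
            g = simulate_dataset(winning_model, greedy, ts, seed=s)
            n = simulate_dataset(winning_model, noisy, ts, seed=1000 + s)
            fg, _ = reward_summary(g)
            fn, _ = reward_summary(n)
            g_rewards.append(np.mean(list(fg.values())))
            n_rewards.append(np.mean(list(fn.values())))
        assert np.mean(g_rewards) > np.mean(n_rewards)


class TestFullReport:
    def test_report_structure(self, simulated_dataset):
        rep = compute_metrics(simulated_dataset)
        tidy = rep.to_tidy()
        assert set(tidy["horizon"]) == {1, 6}
        assert tidy["value"].notna().all()
        assert 0 <= rep.consistency[1] <= 100
        assert 0 <= rep.high_value_freq[6] <= 100

    def test_exploration_parameters_drive_their_markers(self, winning_model):
        """Across agents, epsilon correlates with low-value frequency and
        eta with novel-bandit frequency."""
        ts = build_taskset(TaskConfig(seed=51, trials_per_combination=10))
        eps_grid = np.linspace(0.0, 0.5, 6)
        eta_grid = np.linspace(0.0, 5.0, 6)
        low_freqs, nov_freqs = [], []
        for i, (eps, eta) in enumerate(zip(eps_grid, eta_grid)):
            p = ParameterSet(Q0=3.2, sigma0=1.312, epsilon=eps, eta=0.5)
            ds = simulate_dataset(winning_model, p, ts, seed=i)
            low_freqs.append(np.mean([selection_frequencies(ds)[h]["low"]
                                      for h in (1, 6)]))
            p2 = ParameterSet(Q0=3.2, sigma0=1.312, epsilon=0.1, eta=eta)
            ds2 = simulate_dataset(winning_model, p2, ts, seed=100 + i)
            nov_freqs.append(np.mean([selection_frequencies(ds2)[h]["novel"]
                                      for h in (1, 6)]))
        assert np.corrcoef(eps_grid, low_freqs)[0, 1] > 0.5
        assert np.corrcoef(eta_grid, nov_freqs)[0, 1] > 0.5
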