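"""Unit tests for the Monte Carlo estimators and stopping rules."""

import math

import numpy as np
import pytest
from scipy import stats

from moranfix import (
    Game,
    ModelParams,
    ParameterError,
    StoppingConfig,
    estimate_fixation_probability,
    estimate_fixation_time,
    estimate_stationary_distribution,
    kl_divergence,
    multi_step,
    multi_step_mutation,
    naive_step,
    required_realisations,
    sample_fixation_event,
    stationary_distribution,
    stationary_stopping,
)
from moranfix.core import transition_probabilities, transition_probabilities_with_mutation
from moranfix.simulation import (
    SimState,
    SimulationBudgetError,
    smoothed_histogram,
    step_probabilities,
)


class TestStepProbabilities:
    def test_neutral_pair_population(self):
        p = step_probabilities(1, ModelParams(N=2), Game(1, 2, 3, 4))
        assert p.m_b == pytest.approx(0.5)
        assert p.m_d == pytest.approx(0.5)
        assert p.stay_prob == pytest.approx(0.5)
        assert p.jump_prob == pytest.approx(0.5)

    def test_jump_probability_matches_kernel(self, rng):
        # 1 - stay = T^+ + T^- of the mutation-free kernel
        params = ModelParams(N=14, beta=0.8)
        game = Game(0.5, 1.5, -0.2, 0.7)
        for n_A in range(1, 14):
            p = step_probabilities(n_A, params, game)
            up, down = transition_probabilities(n_A, params, game)
            assert p.jump_prob == pytest.approx(up + down, rel=1e-12)


class TestNaiveStep:
    def test_absorbing_states_never_move(self, rng):
        params = ModelParams(N=6)
        game = Game(1, 1, 0, 0)
        for n_A in (0, 6):
            state = SimState(n_A=n_A)
            for _ in range(50):
                state = naive_step(state, params, game, rng)
            assert state.n_A == n_A
            assert state.t == 50

    def test_one_step_frequencies_match_transition_probabilities(self, rng):
        # empirical +1/-1 frequencies over seeded draws within 3 binomial SE
        params = ModelParams(N=8, beta=0.6)
        game = Game(1, 0, 0, 1)
        n_draws = 40_000
        start = SimState(n_A=3)
        moves = np.array([naive_step(start, params, game, rng).n_A - 3 for _ in range(n_draws)])
        up, down = transition_probabilities(3, params, game)
        for target, prob in ((1, up), (-1, down)):
            freq = np.mean(moves == target)
            se = math.sqrt(prob * (1 - prob) / n_draws)
            assert abs(freq - prob) <= 3 * se


class TestMultiStep:
    def test_rejects_absorbing_start(self, rng):
        with pytest.raises(ParameterError):
            multi_step(SimState(n_A=0), ModelParams(N=5), Game(1, 1, 0, 0), rng)

    def test_mean_holding_time(self, rng):
        # N=2, n_A=1, beta=0: jump_prob = 1/2, mean holding time 2
        params = ModelParams(N=2)
        game = Game(1, 2, 3, 4)
        times = [multi_step(SimState(n_A=1), params, game, rng).t for _ in range(20_000)]
        mean = np.mean(times)
        se = np.std(times, ddof=1) / math.sqrt(len(times))
        assert abs(mean - 2.0) <= 3 * se

    def test_direction_probability_given_jump(self, rng):
        params = ModelParams(N=10, beta=0.7)
        game = Game(1, 1, 0, 0)
        p = step_probabilities(4, params, game)
        n = 20_000
        ups = sum(multi_step(SimState(n_A=4), params, game, rng).n_A == 5 for _ in range(n))
        prob = p.m_b * (1 - p.m_d) / p.jump_prob
        se = math.sqrt(prob * (1 - prob) / n)
        assert abs(ups / n - prob) <= 3 * se

    def test_distributionally_equivalent_to_iterated_naive(self, rng):
        # (direction, bucketed holding time) contingency not rejected at alpha = 1e-3
        params = ModelParams(N=8, beta=0.5)
        game = Game(0, 1, 1, 0)
        n = 20_000

        def holding_naive():
            state = SimState(n_A=4)
            while state.n_A == 4:
                state = naive_step(state, params, game, rng)
            return state.n_A - 4, state.t

        def holding_multi():
            out = multi_step(SimState(n_A=4), params, game, rng)
            return out.n_A - 4, out.t

        buckets = [1, 2, 3, 5, 8, np.inf]

        def table(sampler):
            counts = np.zeros((2, len(buckets)))
            for _ in range(n):
                d, t = sampler()
                counts[(d + 1) // 2, np.searchsorted(buckets, t)] += 1
            return counts

        obs = np.array([table(holding_naive).ravel(), table(holding_multi).ravel()])
        obs = obs[:, obs.sum(axis=0) > 0]
        _, pvalue, _, _ = stats.chi2_contingency(obs)
        assert pvalue > 1e-3


class TestMultiStepMutation:
    def test_boundary_waits_geometric_then_moves_up(self, rng):
        params = ModelParams(N=6, beta=0.4, mu=0.25)
        game = Game(1, 1, 0, 0)
        outs = [multi_step_mutation(SimState(n_A=0), params, game, rng) for _ in range(5_000)]
        assert all(o.n_A == 1 for o in outs)
        mean_t = np.mean([o.t for o in outs])
        assert mean_t == pytest.approx(1 / 0.25, rel=0.1)

    def test_full_mutation_jump_probability_matches_kernel(self, rng):
        # at mu=1 the per-step change probability is still T^{k+} + T^{k-}
        # of the mutation kernel (picking different types for birth and death
        # with a mutated offspring can reproduce the dead type, so the chain
        # can stay even under certain mutation)
        params = ModelParams(N=6, beta=0.0, mu=1.0)
        game = Game(1, 2, 3, 4)
        up, down = transition_probabilities_with_mutation(2, params, game)
        # beta=0, k=2, N=6: sA = 1/3, so T+ = (2/3)(2/3), T- = (1/3)(1/3)
        assert up + down == pytest.approx(5 / 9, rel=1e-12)
        times = [multi_step_mutation(SimState(n_A=2), params, game, rng).t for _ in range(20_000)]
        mean = np.mean(times)
        se = np.std(times, ddof=1) / math.sqrt(len(times))
        assert abs(mean - 1 / (up + down)) <= 3 * se

    def test_requires_mutation(self, rng):
        with pytest.raises(ParameterError):
            multi_step_mutation(SimState(n_A=2), ModelParams(N=5, mu=0.0), Game(1, 1, 0, 0), rng)


class TestSampleFixationEvent:
    def test_neutral_fixation_frequency(self, rng):
        params = ModelParams(N=10)
        game = Game(2, 0, 1, 1)
        n = 3_000
        hits = sum(sample_fixation_event(params, game, rng)[0] for _ in range(n))
        se = math.sqrt(0.1 * 0.9 / n)
        assert abs(hits / n - 0.1) <= 3 * se

    def test_fixation_needs_at_least_N_minus_1_steps(self, rng):
        params = ModelParams(N=12, beta=1.0)
        game = Game(1, 1, 0, 0)
        for _ in range(200):
            ind, steps = sample_fixation_event(params, game, rng)
            if ind == 1:
                assert steps >= 11

    def test_budget_breach_raises(self, rng):
        params = ModelParams(N=50)
        game = Game(1, 2, 3, 4)
        with pytest.raises(SimulationBudgetError):
            for _ in range(200):
                sample_fixation_event(params, game, rng, max_steps=10)


class TestChebyshevRule:
    def test_worked_example_variance_and_threshold(self):
        config = StoppingConfig(epsilon=0.1, delta=0.01)
        assert 0.2 * (1 - 0.2) == pytest.approx(0.16)
        assert required_realisations(0.2, config) == 1600

    @pytest.mark.parametrize("degenerate", [0.0, 1.0])
    def test_degenerate_estimates_need_nothing(self, degenerate):
        assert required_realisations(degenerate, StoppingConfig()) == 0

    def test_realisation_count_bounded(self, rng):
        # k <= r0 + ceil(0.25 / sigma^2) + batch slack, since R(p) <= R(1/2)
        config = StoppingConfig(epsilon=0.1, delta=0.05, r0=50, batch_size=50)
        est = estimate_fixation_probability(ModelParams(N=8), Game(0, 1, 1, 0), config, rng=rng)
        bound = config.r0 + math.ceil(0.25 / config.sigma2) + config.batch_size
        assert est.n_realisations <= bound
        assert est.converged

    def test_strong_selection_dominance_needs_few_realisations(self, rng):
        # phi ~ 1 so the Bernoulli variance estimate collapses quickly
        config = StoppingConfig(epsilon=0.1, delta=0.05, r0=50, batch_size=50)
        est = estimate_fixation_probability(
            ModelParams(N=10, beta=5.0), Game(2, 2, 0, 0), config, rng=rng
        )
        assert est.mean > 0.9
        assert est.n_realisations <= 150

    def test_bit_reproducible_given_seed(self):
        params = ModelParams(N=10, beta=0.3)
        game = Game(1, 1, 0, 0)
        config = StoppingConfig(epsilon=0.05, delta=0.05, seed=77)
        a = estimate_fixation_probability(params, game, config)
        b = estimate_fixation_probability(params, game, config)
        assert a == b


class TestFixationTimeEstimation:
    def test_neutral_times_near_closed_forms(self):
        params = ModelParams(N=10)
        game = Game(1, 2, 3, 4)
        config = StoppingConfig(epsilon=0.01, r0=300, batch_size=300, seed=11)
        uncond = estimate_fixation_time(params, game, config)
        assert uncond.mean == pytest.approx(10 * sum(1 / l for l in range(1, 10)), rel=0.10)
        cond = estimate_fixation_time(params, game, config, conditional=True)
        assert cond.mean == pytest.approx(90.0, rel=0.10)
        assert cond.n_discarded > 0

    def test_conditional_discards_dominate_for_disfavored_mutant(self):
        # B dominates A, so fixation of A is rare and most runs are discarded
        params = ModelParams(N=8, beta=0.5)
        game = Game(0, 0, 1, 1)
        config = StoppingConfig(epsilon=0.05, r0=20, batch_size=20, seed=3)
        est = estimate_fixation_time(params, game, config, conditional=True)
        assert est.n_discarded > 5 * est.n_realisations

    def test_total_step_cap_guards_rare_fixation(self):
        params = ModelParams(N=14, beta=1.0)
        game = Game(0, 0, 1, 1)  # fixation of A is astronomically rare
        config = StoppingConfig(epsilon=0.05, r0=50, batch_size=50, seed=5, total_step_cap=20_000)
        with pytest.raises(SimulationBudgetError):
            estimate_fixation_time(params, game, config, conditional=True)


class TestKLDivergence:
    def test_identical_distributions(self):
        p = np.array([0.2, 0.3, 0.5])
        assert kl_divergence(p, p) == 0.0

    def test_hand_value(self):
        val = kl_divergence(np.array([0.5, 0.5]), np.array([0.25, 0.75]))
        assert val == pytest.approx(0.5 * math.log(2) + 0.5 * math.log(2 / 3), rel=1e-12)

    def test_nonnegative_on_random_distributions(self, rng):
        for _ in range(50):
            p = rng.dirichlet(np.ones(7))
            q = rng.dirichlet(np.ones(7))
            assert kl_divergence(p, q) >= 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ParameterError):
            kl_divergence(np.array([0.5, 0.5]), np.array([-0.1, 1.1]))
        with pytest.raises(ParameterError):
            kl_divergence(np.array([0.7, 0.7]), np.array([0.5, 0.5]))

    def test_smoothed_histogram_handles_empty_cells(self):
        counts = np.array([0.0, 10.0, 0.0])
        smoothed = smoothed_histogram(counts)
        assert smoothed.sum() == pytest.approx(1.0)
        assert np.all(smoothed > 0)


class TestStationaryEstimation:
    def test_pair_population_long_run(self):
        params = ModelParams(N=2, mu=0.5)
        game = Game(1, 2, 3, 4)
        config = StoppingConfig(epsilon=1e-4, r0=1_000, batch_size=100_000, seed=9)
        est = estimate_stationary_distribution(params, game, config)
        assert est.converged
        np.testing.assert_allclose(est.distribution, [0.25, 0.5, 0.25], atol=0.01)

    def test_occupancy_approaches_direct_distribution(self):
        params = ModelParams(N=6, beta=0.3, mu=0.3)
        game = Game(0, 1, 1, 0)
        config = StoppingConfig(epsilon=1e-5, r0=1_000, batch_size=200_000, seed=21)
        est = estimate_stationary_distribution(params, game, config)
        target = stationary_distribution(params, game)
        assert kl_divergence(smoothed_histogram(est.distribution), smoothed_histogram(target)) < 1e-3

    def test_bistability_strong_selection_flagged_unconverged(self):
        # mass sits at the two edges and transitions are rare: the snapshot
        # criterion cannot be met within a modest budget
        params = ModelParams(N=30, beta=10.0, mu=0.001)
        game = Game(1, 0, 0, 1)
        config = StoppingConfig(epsilon=1e-6, r0=1_000, batch_size=50_000, max_steps=500_000, seed=13)
        est = estimate_stationary_distribution(params, game, config)
        target = stationary_distribution(params, game)
        bad = kl_divergence(smoothed_histogram(est.distribution), smoothed_histogram(target))
        assert (not est.converged) or bad > 0.1

    def test_requires_mutation(self):
        with pytest.raises(ParameterError):
            estimate_stationary_distribution(ModelParams(N=5, mu=0.0), Game(1, 1, 0, 0))

    def test_default_stopping_scales_with_population(self):
        cfg = stationary_stopping(20)
        assert cfg.r0 == 2_000
        assert cfg.batch_size == 2_000_000
        assert cfg.epsilon == 1e-4
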