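"""Swarm engine: initialization, behaviors, importance, distance and the
full search loop."""

import math

import numpy as np
import pytest

from fslr.config import RunConfig
from fslr.logic_tree import Move
from fslr.regression import Dataset, fit_betas, RegressionModel
from fslr.swarm import (
    Behavior,
    agent_distance,
    choose_behavior,
    compute_importance,
    follow_step,
    initialize_swarm,
    kpdist_step,
    random_step,
    run,
    selection_distribution,
    size_density,
)
from fslr.synthetic_data import SimulationConfig, simulate


def small_data(rng, m=300, n=8):
    g = (rng.random((m, n)) < 0.4).astype(np.int8)
    p = np.where(rng.random(m) < 0.85, g[:, 0], 1 - g[:, 0]).astype(np.int8)
    return Dataset(genotypes=g, phenotypes=p)


class TestInitialize:
    def test_deterministic_given_seed(self, rng):
        data = small_data(rng)
        cfg = RunConfig()
        s1 = initialize_swarm(data, cfg, seed=11)
        s2 = initialize_swarm(data, cfg, seed=11)
        for a, b in zip(s1.agents, s2.agents):
            assert a.model.trees == b.model.trees
            assert np.array_equal(a.bootstrap_indices, b.bootstrap_indices)

    def test_oob_fraction_near_e_inverse(self, rng):
        data = small_data(rng, m=1000)
        state = initialize_swarm(data, RunConfig(), seed=3)
        fracs = [len(a.oob_indices) / 1000 for a in state.agents]
        assert 0.33 < float(np.mean(fracs)) < 0.41

    def test_single_agent_rejected(self, rng):
        with pytest.raises(ValueError):
            RunConfig(n_agents=1)

    def test_degenerate_single_snp_space(self, rng):
        g = (rng.random((100, 1)) < 0.5).astype(np.int8)
        data = Dataset(genotypes=g, phenotypes=g[:, 0])
        state = initialize_swarm(data, RunConfig(s_max=1), seed=5)
        for agent in state.agents:
            assert agent.model.distinct_snps() == {0}
            assert agent.model.model_size == 1


class TestSizeDensity:
    def test_closed_form_at_mode(self):
        assert size_density(3, 3, 1.0) == pytest.approx(
            1.0 / math.sqrt(2 * math.pi), abs=1e-12
        )

    def test_symmetric_about_mode(self):
        for d in (0.5, 1, 2, 3):
            assert size_density(5 + d, 5, 2.0) == pytest.approx(
                size_density(5 - d, 5, 2.0), abs=1e-12
            )

    def test_clamped_to_one_for_tiny_variance(self):
        assert size_density(4, 4, 0.01) == 1.0

    def test_requires_positive_variance(self):
        with pytest.raises(ValueError):
            size_density(1, 1, 0.0)


class TestSelectionDistribution:
    def test_equal_importance_gives_uniform(self):
        p = selection_distribution(np.zeros(7))
        assert np.allclose(p, 1 / 7)

    def test_dominant_snp_gets_top_probability(self):
        v = np.array([0.0, 50.0, 1.0, 0.0])
        p = selection_distribution(v)
        assert p.argmax() == 1 and p[1] > p[2] > 0

    def test_normalizes_for_random_vectors(self, rng):
        for _ in range(1000):
            v = rng.normal(size=20) * rng.integers(1, 100)
            p = selection_distribution(v)
            assert p.min() > 0
            assert p.sum() == pytest.approx(1.0, abs=1e-9)


class TestDistance:
    def _state(self, rng):
        data = small_data(rng)
        return initialize_swarm(data, RunConfig(), seed=2), data

    def test_identical_snp_sets_distance_zero(self, rng):
        state, _ = self._state(rng)
        a = state.agents[0]
        assert agent_distance(a, a, state.importance) == 0.0

    def test_metric_properties(self, rng):
        state, data = self._state(rng)
        imp = compute_importance(state, data, RunConfig())
        agents = state.agents
        for i in range(0, 9, 3):
            a, b, c = agents[i % 12], agents[(i + 1) % 12], agents[(i + 2) % 12]
            dab = agent_distance(a, b, imp)
            assert dab == agent_distance(b, a, imp)
            assert dab <= agent_distance(a, c, imp) + agent_distance(c, b, imp) + 1e-12


class TestBehaviorChoice:
    def test_best_agent_always_holds(self, rng):
        data = small_data(rng)
        state = initialize_swarm(data, RunConfig(), seed=9)
        state.announce_best()
        best = state.best_agent
        for _ in range(50):
            assert choose_behavior(best, state, RunConfig()) is Behavior.HOLD

    def test_degenerate_mixture_always_random(self, rng):
        data = small_data(rng)
        cfg = RunConfig(behavior_probs=(1.0, 0.0, 0.0))
        state = initialize_swarm(data, cfg, seed=9)
        state.announce_best()
        non_best = [a for a in state.agents if a is not state.best_agent][0]
        assert all(
            choose_behavior(non_best, state, cfg) is Behavior.RANDOM
            for _ in range(100)
        )

    def test_empirical_frequencies_match_mixture(self, rng):
        data = small_data(rng)
        cfg = RunConfig(behavior_probs=(0.2, 0.5, 0.3))
        state = initialize_swarm(data, cfg, seed=9)
        state.announce_best()
        agent = [a for a in state.agents if a is not state.best_agent][0]
        n = 10_000
        draws = [choose_behavior(agent, state, cfg) for _ in range(n)]
        for behavior, p in [
            (Behavior.RANDOM, 0.2),
            (Behavior.FOLLOW, 0.5),
            (Behavior.KPDIST, 0.3),
        ]:
            freq = sum(d is behavior for d in draws) / n
            assert abs(freq - p) < 3 * math.sqrt(p * (1 - p) / n)


class TestSteps:
    def _agent_state(self, rng, seed=4):
        data = small_data(rng)
        state = initialize_swarm(data, RunConfig(), seed=seed)
        state.announce_best()
        agent = [a for a in state.agents if a is not state.best_agent][0]
        return agent, state, data

    def test_random_step_move_frequencies(self, rng):
        agent, state, data = self._agent_state(rng)
        cfg = RunConfig()
        # force a model where all four moves are feasible
        while not (
            agent.model.model_size >= 2
            and any(t.internal_paths() for t in agent.model.trees)
            and agent.model.model_size < cfg.s_max * cfg.k_max
        ):
            agent, state, data = self._agent_state(rng, seed=int(rng.integers(1000)))
        n = 4000
        deltas = []
        for _ in range(n):
            prop = random_step(agent, data, cfg)
            deltas.append(prop.model_size - agent.model.model_size)
        deltas = np.array(deltas)
        # ADD (+1) and DEL (-1) should each occur ~1/4 of the time
        for want, p in [(1, 0.25), (-1, 0.25), (0, 0.5)]:
            freq = float(np.mean(deltas == want))
            assert abs(freq - p) < 4 * math.sqrt(p * (1 - p) / n)

    def test_random_step_proposal_differs(self, rng):
        agent, state, data = self._agent_state(rng)
        for _ in range(100):
            prop = random_step(agent, data, RunConfig())
            assert prop.trees != agent.model.trees

    def test_random_step_never_empties_model(self, rng):
        agent, state, data = self._agent_state(rng)
        # shrink the agent to a single leaf
        from fslr.logic_tree import leaf_tree

        agent.model = RegressionModel(trees=(leaf_tree(0),))
        for _ in range(200):
            assert random_step(agent, data, RunConfig()).model_size >= 1

    def test_follow_equal_size_always_alt(self, rng):
        agent, state, data = self._agent_state(rng)
        best_size = state.best_agent.model.model_size
        agent.model = state.best_agent.model
        for _ in range(50):
            prop = follow_step(agent, state, data, RunConfig(), sigma2=1.0)
            assert prop.model_size == best_size  # ALT never changes size

    def test_kpdist_equal_size_always_changes_size(self, rng):
        agent, state, data = self._agent_state(rng)
        agent.model = state.best_agent.model
        if agent.model.model_size == 1:
            pytest.skip("degenerate best of size 1")
        best_size = state.best_agent.model.model_size
        for _ in range(50):
            prop = kpdist_step(agent, state, data, RunConfig(), sigma2=1.0)
            assert abs(prop.model_size - best_size) == 1

    def test_follow_contracts_size_gap(self, rng):
        # repeatedly applying FOLLOW proposals shrinks |s_i - s_best| on average
        agent, state, data = self._agent_state(rng)
        cfg = RunConfig()
        best_size = state.best_agent.model.model_size
        start_gap = abs(agent.model.model_size - best_size)
        gaps = []
        for _ in range(200):
            prop = follow_step(agent, state, data, cfg, sigma2=4.0)
            agent.model = prop
            gaps.append(abs(prop.model_size - best_size))
        assert float(np.mean(gaps[-50:])) <= max(start_gap, 1)


class TestImportance:
    def test_absent_snp_has_zero_importance(self, rng):
        data = small_data(rng)
        state = initialize_swarm(data, RunConfig(), seed=6)
        imp = compute_importance(state, data, RunConfig())
        present = set()
        for a in state.agents:
            present |= a.model.distinct_snps()
        for j in range(data.n_snps):
            if j not in present:
                assert imp.values[j] == 0.0

    def test_single_agent_arithmetic(self, rng):
        # with F agents of which only one holds SNP j,
        # V(j) = (N_k - N_k^{-j}) / F exactly
        data = small_data(rng)
        cfg = RunConfig()
        state = initialize_swarm(data, cfg, seed=8)
        from fslr.swarm import _oob_correct, model_without_snp

        imp = compute_importance(state, data, cfg)
        holders = {}
        for a in state.agents:
            for j in a.model.distinct_snps():
                holders.setdefault(j, []).append(a)
        for j, agents in holders.items():
            if len(agents) != 1:
                continue
            a = agents[0]
            oob_g = data.genotypes[a.oob_indices]
            oob_p = data.phenotypes[a.oob_indices]
            n_k = _oob_correct(a.model, a, oob_g, oob_p, cfg.v, refit=False)
            n_kj = _oob_correct(
                model_without_snp(a.model, j), a, oob_g, oob_p, cfg.v
            )
            assert imp.values[j] == pytest.approx(
                (n_k - n_kj) / len(state.agents), abs=1e-12
            )

    def test_planted_causal_snp_attains_max_importance(self):
        hits = 0
        runs = 15
        for seed in range(runs):
            sim = simulate(
                SimulationConfig(
                    n_pool=4000, n_sites=15, n_causal=1, n_cases=200,
                    n_controls=200, expression_shape="or",
                ),
                seed=seed,
            )
            cfg = RunConfig(stable_iterations=30, max_iterations=120)
            rep = run(sim.dataset, cfg, seed=seed + 40)
            if rep.importance.argmax() == sim.causal_indices[0]:
                hits += 1
        assert hits >= runs - 1


class TestRun:
    def test_same_seed_reproduces_report(self, rng):
        data = small_data(rng)
        cfg = RunConfig(stable_iterations=20, max_iterations=80)
        r1 = run(data, cfg, seed=13)
        r2 = run(data, cfg, seed=13)
        assert r1.best_score == r2.best_score
        assert r1.best_model.trees == r2.best_model.trees
        assert r1.iterations == r2.iterations
        assert np.array_equal(r1.importance, r2.importance)
        assert r1.agent_scores == r2.agent_scores
        assert r1.pair_counts == r2.pair_counts

    def test_models_stay_within_bounds(self, rng):
        data = small_data(rng)
        cfg = RunConfig(s_max=3, k_max=2, stable_iterations=20, max_iterations=100)
        rep = run(data, cfg, seed=21)
        for model in rep.agent_models:
            assert 1 <= model.model_size <= cfg.s_max * cfg.k_max
            assert all(t.size <= cfg.s_max for t in model.trees)
            assert model.k <= cfg.k_max

    def test_best_score_beats_every_agent_start(self, rng):
        data = small_data(rng)
        cfg = RunConfig(stable_iterations=20, max_iterations=100)
        state0 = initialize_swarm(data, cfg, seed=33)
        rep = run(data, cfg, seed=33)
        assert rep.best_score >= max(a.score for a in state0.agents)

    def test_pure_random_mixture_still_searches(self, rng):
        # degraded engine (no FOLLOW/KPDIST) is plain stochastic LR search
        data = small_data(rng)
        cfg = RunConfig(
            behavior_probs=(1.0, 0.0, 0.0), stable_iterations=20, max_iterations=100
        )
        rep = run(data, cfg, seed=5)
        assert rep.best_score >= data.n_individuals // 2
        assert rep.converged or rep.iterations == 100

    def test_hard_cap_prevents_nontermination(self, rng):
        data = small_data(rng)
        cfg = RunConfig(stable_iterations=10_000, max_iterations=30)
        rep = run(data, cfg, seed=5)
        assert rep.iterations == 30 and not rep.converged
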