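"""CPT Bellman recursion, best responses and level-k towers."""

import itertools
import logging

import numpy as np
import pytest

from stagcpt.cpt import CPTParams, UtilitySpec, WeightingSpec, cpt_value
from stagcpt.experiments import EUT_PARAMS, MARKOV_CPT_PARAMS
from stagcpt.markov_env import CanyonGame, CanyonSpec
from stagcpt.planning import (
    PlanningConfig,
    PlanningConvergenceError,
    best_response,
    level_k_tower,
    policy_value,
    step_prospect,
    uniform_policy,
)

from _helpers import agent_swap_permutation, classical_value_iteration

CFG = PlanningConfig()


def random_policy(rng, n_states, n_actions=3):
    return rng.dirichlet(np.ones(n_actions), size=n_states)


def opponent_mixture_row(game, agent, s, a_own, policy_other):
    """Brute-force successor distribution over (a_other, s')."""
    row = np.zeros(game.n_states)
    for a_other in range(game.n_actions):
        pair = (a_own, a_other) if agent == 1 else (a_other, a_own)
        row += policy_other[s, a_other] * game.joint.matrices[pair[0], pair[1], s]
    return row


class TestStepProspect:
    def test_zero_value_zero_reward_is_degenerate(self, tiny_game):
        V = np.zeros(tiny_game.n_states)
        uni = uniform_policy(tiny_game.n_states)
        # joint state (1, 0): agent 1 on the stag alone earns nothing
        prospect = step_prospect(tiny_game, 1, (1, 0), 0, uni, V, CFG)
        assert len(prospect) == 1
        assert prospect.outcomes[0] == pytest.approx(0.0)

    def test_support_bounded_by_kernel_row(self, tiny_game):
        V = np.arange(tiny_game.n_states, dtype=float)
        uni = uniform_policy(tiny_game.n_states)
        for s, a in itertools.product(range(tiny_game.n_states), range(3)):
            prospect = step_prospect(tiny_game, 1, s, a, uni, V, CFG)
            row = opponent_mixture_row(tiny_game, 1, s, a, uni)
            assert len(prospect) <= (row > 0).sum()

    def test_matches_enumeration_oracle(self, tiny_game, rng):
        V = rng.normal(size=tiny_game.n_states)
        pol = random_policy(rng, tiny_game.n_states)
        for agent in (1, 2):
            for s in range(tiny_game.n_states):
                for a in range(3):
                    prospect = step_prospect(tiny_game, agent, s, a, pol, V, CFG)
                    row = opponent_mixture_row(tiny_game, agent, s, a, pol)
                    outcomes = tiny_game.rewards[agent][s] + CFG.discount_beta * V
                    expect = {}
                    for t in np.flatnonzero(row):
                        key = round(outcomes[t], 9)
                        expect[key] = expect.get(key, 0.0) + row[t]
                    assert len(prospect) == len(expect)
                    for o, p in zip(prospect.outcomes, prospect.probabilities):
                        assert p == pytest.approx(expect[round(o, 9)], abs=1e-12)


class TestPolicyValue:
    def test_zero_rewards_fixed_point_is_zero(self):
        game = CanyonGame(CanyonSpec(n_positions=4, hare_position=0,
                                     stag_position=3, hare_reward=0.0,
                                     stag_reward=0.0))
        uni = uniform_policy(game.n_states)
        V = policy_value(game, 1, uni, uni, MARKOV_CPT_PARAMS, CFG)
        np.testing.assert_allclose(V, 0.0, atol=1e-7)

    def test_constant_reward_geometric_series(self, tiny_game):
        game = CanyonGame(tiny_game.spec)
        game.rewards[1] = np.full(game.n_states, 2.0)  # constant-field variant
        uni = uniform_policy(game.n_states)
        for params in (EUT_PARAMS, MARKOV_CPT_PARAMS):
            V = policy_value(game, 1, uni, uni, params, CFG)
            np.testing.assert_allclose(V, 2.0 / (1 - CFG.discount_beta), atol=1e-6)

    def test_eut_limit_matches_linear_solve(self, game, rng):
        pol1 = random_policy(rng, game.n_states)
        pol2 = random_policy(rng, game.n_states)
        V = policy_value(game, 1, pol1, pol2, EUT_PARAMS, CFG)
        M = np.einsum("sa,sb,abst->st", pol1, pol2, game.joint.matrices)
        V_exact = np.linalg.solve(
            np.eye(game.n_states) - CFG.discount_beta * M, game.rewards[1]
        )
        assert np.max(np.abs(V - V_exact)) < 1e-6

    def test_kt1992_logs_instability_warning(self, tiny_game, caplog):
        params = CPTParams(
            UtilitySpec.identity(), WeightingSpec("kt1992", gamma_w=0.85), 0.0
        )
        uni = uniform_policy(tiny_game.n_states)
        with caplog.at_level(logging.WARNING, logger="stagcpt.planning"):
            try:
                policy_value(tiny_game, 1, uni, uni, params, CFG)
            except PlanningConvergenceError:
                pass  # instability is exactly what the warning is about
        assert any("kt1992" in r.message for r in caplog.records)

    def test_non_convergence_raises_with_residual_trace(self, tiny_game):
        uni = uniform_policy(tiny_game.n_states)
        cfg = PlanningConfig(tol=1e-14, max_iter=3)
        with pytest.raises(PlanningConvergenceError) as err:
            policy_value(tiny_game, 1, uni, uni, EUT_PARAMS, cfg)
        assert len(err.value.residuals) == 3


class TestBestResponse:
    def test_zero_rewards_gives_uniform_ties(self):
        game = CanyonGame(CanyonSpec(n_positions=4, hare_position=0,
                                     stag_position=3, hare_reward=0.0,
                                     stag_reward=0.0))
        uni = uniform_policy(game.n_states)
        pol, V = best_response(game, 1, uni, EUT_PARAMS, CFG)
        np.testing.assert_allclose(V, 0.0, atol=1e-7)
        np.testing.assert_allclose(pol, uni, atol=1e-12)

    def test_eut_limit_matches_policy_enumeration(self, tiny_game, rng):
        """On the 2-position canyon, greedy CPT iteration in the EUT limit
        must match exhaustive enumeration of all 3^4 deterministic policies
        evaluated by exact linear solves."""
        pol_other = random_policy(rng, tiny_game.n_states)
        _, V = best_response(tiny_game, 1, pol_other, EUT_PARAMS, CFG)
        n, beta = tiny_game.n_states, CFG.discount_beta
        M = np.einsum(
            "sb,abst->ast", pol_other, tiny_game.joint.matrices
        )
        best = np.full(n, -np.inf)
        for assignment in itertools.product(range(3), repeat=n):
            Mpi = np.stack([M[a, s] for s, a in enumerate(assignment)])
            Vpi = np.linalg.solve(np.eye(n) - beta * Mpi, tiny_game.rewards[1])
            best = np.maximum(best, Vpi)
        assert np.max(np.abs(V - best)) < 1e-6

    def test_eut_bellman_optimality_residual(self, tiny_game, rng):
        pol_other = random_policy(rng, tiny_game.n_states)
        pol, V = best_response(tiny_game, 1, pol_other, EUT_PARAMS, CFG)
        for s in range(tiny_game.n_states):
            q = [
                cpt_value(
                    step_prospect(tiny_game, 1, s, a, pol_other, V, CFG),
                    EUT_PARAMS,
                )
                for a in range(3)
            ]
            assert abs(max(q) - V[s]) < 1e-6
            chosen = np.flatnonzero(pol[s] > 0)
            assert all(q[a] >= max(q) - 1e-6 for a in chosen)

    def test_monotone_backup_in_eut_limit(self, tiny_game, rng):
        uni = uniform_policy(tiny_game.n_states)
        V_lo = rng.normal(size=tiny_game.n_states)
        V_hi = V_lo + rng.uniform(0.0, 2.0, size=tiny_game.n_states)

        def backup(V):
            return np.array([
                max(
                    cpt_value(
                        step_prospect(tiny_game, 1, s, a, uni, V, CFG), EUT_PARAMS
                    )
                    for a in range(3)
                )
                for s in range(tiny_game.n_states)
            ])

        assert np.all(backup(V_lo) <= backup(V_hi) + 1e-12)


class TestLevelKTower:
    def test_level_zero_is_uniform(self, tiny_game):
        tower = level_k_tower(tiny_game, 0, MARKOV_CPT_PARAMS, MARKOV_CPT_PARAMS, CFG)
        uni = uniform_policy(tiny_game.n_states)
        np.testing.assert_allclose(tower.policy(1, 0), uni)
        np.testing.assert_allclose(tower.policy(2, 0), uni)

    def test_symmetric_agents_have_mirrored_towers(self, tiny_game):
        tower = level_k_tower(tiny_game, 2, MARKOV_CPT_PARAMS, MARKOV_CPT_PARAMS, CFG)
        perm = agent_swap_permutation(tiny_game.n_positions)
        for k in range(3):
            np.testing.assert_allclose(
                tower.value(2, k), tower.value(1, k)[perm], atol=1e-9
            )
            np.testing.assert_allclose(
                tower.policy(2, k), tower.policy(1, k)[perm], atol=1e-9
            )

    def test_towers_are_deterministic(self, tiny_game):
        towers = [
            level_k_tower(tiny_game, 2, MARKOV_CPT_PARAMS, MARKOV_CPT_PARAMS, CFG)
            for _ in range(2)
        ]
        for k in range(3):
            for agent in (1, 2):
                assert np.array_equal(
                    towers[0].policy(agent, k), towers[1].policy(agent, k)
                )
                assert np.array_equal(
                    towers[0].value(agent, k), towers[1].value(agent, k)
                )

    def test_stag_value_grows_with_sophistication(self, game, towers):
        """With a zero reference point, identity utility and the optimistic
        Prelec weighting, the value of the joint stag state is nondecreasing
        in the sophistication level."""
        tower = towers(MARKOV_CPT_PARAMS, 4)
        ss = game.index(11, 11)
        vals = [tower.value(1, k)[ss] for k in range(1, 5)]
        assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_rejects_negative_k(self, tiny_game):
        with pytest.raises(ValueError):
            level_k_tower(tiny_game, -1, MARKOV_CPT_PARAMS, MARKOV_CPT_PARAMS, CFG)

    def test_eut_tower_matches_classical_value_iteration(self, tiny_game):
        tower = level_k_tower(tiny_game, 1, EUT_PARAMS, EUT_PARAMS, CFG)
        uni = uniform_policy(tiny_game.n_states)
        M = np.einsum("sb,abst->ast", uni, tiny_game.joint.matrices)
        V_oracle = classical_value_iteration(
            tiny_game.rewards[1], M, CFG.discount_beta
        )
        assert np.max(np.abs(tower.value(1, 1) - V_oracle)) < 1e-6
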