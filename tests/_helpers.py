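"""Shared utilities for the test suite."""

from __future__ import annotations

import numpy as np

from stagcpt.markov_env import CanyonGame
from stagcpt.stationary import (
    condition_chain,
    coordination_metrics,
    stationary_distribution,
)


def agent_swap_permutation(n: int) -> np.ndarray:
    """Flat-index permutation exchanging the two agents' positions."""
    perm = np.empty(n * n, dtype=int)
    for s1 in range(n):
        for s2 in range(n):
            perm[s2 * n + s1] = s1 * n + s2
    return perm


def tower_metrics(game: CanyonGame, tower, k1: int, k2: int):
    """Stationary distribution and coordination summaries for a level pair."""
    chain = condition_chain(game.joint, tower.policy(1, k1), tower.policy(2, k2))
    rho = stationary_distribution(chain)
    return rho, coordination_metrics(rho, game.spec)


def classical_value_iteration(
    rewards: np.ndarray, kernels: np.ndarray, beta: float, tol: float = 1e-10
) -> np.ndarray:
    """Textbook expected-utility value iteration (independent oracle)."""
    V = np.zeros(rewards.size)
    for _ in range(200000):
        Q = rewards[:, None] + beta * np.einsum("ast,t->sa", kernels, V)
        V_new = Q.max(axis=1)
        if np.max(np.abs(V_new - V)) < tol:
            return V_new
        V = V_new
    raise AssertionError("oracle value iteration did not converge")
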