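"""CPT value recursion and level-k policy towers over the Markov stag hunt.

The value an agent places on a joint state is defined recursively: one
step ahead, the agent faces the discrete prospect ``r_i(s) + beta * V(s')``
with the successor ``s'`` drawn from the joint kernel mixed over the
opponent's policy (and, for policy evaluation, the agent's own policy —
the own-action mixture sits inside the probability weighting). The backup
applies CPT valuation to that prospect instead of its expectation; with
identity utility/weighting and zero reference point the recursion is the
classical (expected-utility) Bellman equation.

Because the prospect is discrete, the CPT integral over distorted tail
probabilities is a step function and is evaluated exactly by the
rank-dependent sums of :mod:`stagcpt.cpt` — no quadrature is involved in
the solver itself.

Theory of mind enters through the level-k tower: level-0 policies are the
uniform stereotype, and each level-k policy is the greedy CPT best
response to the opponent's level-(k-1) policy. Unlike the discounted
expectation, the CPT backup carries no contraction guarantee; iteration is
damped (optionally) and non-convergence raises a diagnostic error with the
residual trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cpt import CPTParams, DiscreteProspect, cpt_value_rows
from .markov_env import CanyonGame

__all__ = [
    "PlanningConfig",
    "PlanningConvergenceError",
    "LevelKTower",
    "uniform_policy",
    "step_prospect",
    "policy_value",
    "best_response",
    "level_k_tower",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlanningConfig:
    """Solver knobs for the CPT value recursion."""

    discount_beta: float = 0.9
    tol: float = 1e-8
    max_iter: int = 10000
    damping: float = 1.0
    tie_tol: float = 1e-9

    def __post_init__(self) -> None:
        if not 0.0 < self.discount_beta < 1.0:
            raise ValueError("discount_beta must lie in (0, 1)")
        if self.tol <= 0 or self.max_iter <= 0 or self.tie_tol <= 0:
            raise ValueError("tol, max_iter and tie_tol must be positive")
        if not 0.0 < self.damping <= 1.0:
            raise ValueError("damping must lie in (0, 1]")


class PlanningConvergenceError(RuntimeError):
    """Raised when the CPT value recursion fails to reach tolerance."""

    def __init__(self, message: str, residuals: list[float]):
        super().__init__(message)
        self.residuals = residuals


@dataclass(frozen=True, eq=False)
class LevelKTower:
    """Per-agent ladders of (policy, value) pairs for levels 0..k_max.

    ``policies[agent][k]`` is an (n_states, n_actions) array;
    ``values[agent][k]`` an (n_states,) array. Level 0 is the uniform
    stereotype; level k is the recorded best response to the other agent's
    level k-1 policy.
    """

    policies: dict
    values: dict
    k_max: int

    def policy(self, agent: int, k: int) -> np.ndarray:
        return self.policies[agent][k]

    def value(self, agent: int, k: int) -> np.ndarray:
        return self.values[agent][k]


def uniform_policy(n_states: int, n_actions: int = 3) -> np.ndarray:
    """The uniform stereotype policy (level-0 belief about the other agent)."""
    return np.full((n_states, n_actions), 1.0 / n_actions)


def _check_policy(policy: np.ndarray, game: CanyonGame) -> None:
    if policy.shape != (game.n_states, game.n_actions):
        raise ValueError(
            f"policy shape {policy.shape} does not match "
            f"({game.n_states}, {game.n_actions})"
        )
    if np.any(policy < 0) or np.max(np.abs(policy.sum(axis=1) - 1.0)) > 1e-12:
        raise ValueError("policy rows must be distributions summing to 1")


def _warn_weighting(params: CPTParams) -> None:
    if params.weighting.kind == "kt1992":
        logger.warning(
            "kt1992 weighting inside the Markov solver is prone to numerical "
            "instability; the Prelec family is the supported choice"
        )


def _mixture_kernels(
    game: CanyonGame, agent: int, policy_other: np.ndarray
) -> np.ndarray:
    """Per-own-action kernels with the opponent's policy marginalized out.

    Returns M of shape (n_actions, N, N): row ``s`` of ``M[a]`` is the
    successor distribution when the agent plays ``a`` in joint state ``s``
    and the opponent samples from its policy at ``s``.
    """
    P = game.joint.matrices  # (3, 3, N, N) indexed [a1, a2]
    if agent == 1:
        return np.einsum("sb,abst->ast", policy_other, P)
    return np.einsum("sb,bast->ast", policy_other, P)


def step_prospect(
    game: CanyonGame,
    agent: int,
    state: tuple[int, int] | int,
    a_own: int,
    policy_other: np.ndarray,
    V: np.ndarray,
    config: PlanningConfig,
) -> DiscreteProspect:
    """One-step return prospect r_i(s) + beta * V(s') for a fixed own action.

    The successor distribution mixes the joint kernel over the opponent's
    policy at ``s``; outcomes within 1e-12 of each other are merged. The
    reference point is *not* subtracted here — it is applied inside the
    CPT valuation.
    """
    s = game.index(*state) if isinstance(state, tuple) else int(state)
    _check_policy(policy_other, game)
    row = _mixture_kernels(game, agent, policy_other)[a_own, s]
    support = row > 0.0
    outcomes = game.rewards[agent][s] + config.discount_beta * V[support]
    return DiscreteProspect(outcomes, row[support], merge_tol=1e-12)


def _backup_rows(
    rewards: np.ndarray,
    kernel_rows: np.ndarray,
    V: np.ndarray,
    order: np.ndarray,
    params: CPTParams,
    beta: float,
) -> np.ndarray:
    """Vectorized CPT backup of every state under one successor kernel.

    ``order`` pre-sorts the shared continuation values ascending, so every
    row of the outcome matrix is already sorted and a single batched
    rank-dependent evaluation suffices.
    """
    n = V.size
    x = rewards[:, None] + beta * V[order][None, :]
    x = np.broadcast_to(x, (n, n))
    return cpt_value_rows(x, kernel_rows[:, order], params, assume_sorted=True)


def _iterate(
    game: CanyonGame,
    agent: int,
    params: CPTParams,
    config: PlanningConfig,
    backup,
    what: str,
) -> np.ndarray:
    """Damped fixed-point iteration from V = 0 with a residual trace."""
    V = np.zeros(game.n_states)
    residuals: list[float] = []
    for it in range(config.max_iter):
        V_new = backup(V)
        res = float(np.max(np.abs(V_new - V)))
        residuals.append(res)
        V = (1.0 - config.damping) * V + config.damping * V_new
        if res < config.tol:
            logger.debug("%s converged in %d iterations (residual %.3e)", what, it + 1, res)
            return V
    raise PlanningConvergenceError(
        f"{what} did not reach tol={config.tol} within {config.max_iter} "
        f"iterations (last residual {residuals[-1]:.3e})",
        residuals,
    )


def policy_value(
    game: CanyonGame,
    agent: int,
    policy_own: np.ndarray,
    policy_other: np.ndarray,
    params: CPTParams,
    config: PlanningConfig = PlanningConfig(),
) -> np.ndarray:
    """Fixed point of the CPT policy-evaluation backup.

    The one-step prospect pools the agent's own actions (weighted by its
    policy) together with the opponent mixture before the probability
    distortion is applied, so the whole successor lottery is weighted as
    one prospect.
    """
    _check_policy(policy_own, game)
    _check_policy(policy_other, game)
    _warn_weighting(params)
    M = _mixture_kernels(game, agent, policy_other)
    pooled = np.einsum("sa,ast->st", policy_own, M)
    r = game.rewards[agent]

    def backup(V: np.ndarray) -> np.ndarray:
        order = np.argsort(V, kind="stable")
        return _backup_rows(r, pooled, V, order, params, config.discount_beta)

    return _iterate(game, agent, params, config, backup, f"policy_value(agent {agent})")


def _action_values(
    game: CanyonGame,
    agent: int,
    M: np.ndarray,
    V: np.ndarray,
    params: CPTParams,
    beta: float,
) -> np.ndarray:
    order = np.argsort(V, kind="stable")
    r = game.rewards[agent]
    Q = np.empty((game.n_states, game.n_actions))
    for a in range(game.n_actions):
        Q[:, a] = _backup_rows(r, M[a], V, order, params, beta)
    return Q


def best_response(
    game: CanyonGame,
    agent: int,
    policy_other: np.ndarray,
    params: CPTParams,
    config: PlanningConfig = PlanningConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy CPT value iteration against a fixed opponent policy.

    Each sweep sets ``V(s) = max_a`` CPT-value of the one-step prospect
    under own action ``a``. On convergence the returned policy spreads
    uniformly over every action within ``tie_tol`` of the per-state
    maximum, preserving the left/right symmetry of the canyon.
    """
    _check_policy(policy_other, game)
    _warn_weighting(params)
    M = _mixture_kernels(game, agent, policy_other)

    def backup(V: np.ndarray) -> np.ndarray:
        return _action_values(game, agent, M, V, params, config.discount_beta).max(axis=1)

    V = _iterate(game, agent, params, config, backup, f"best_response(agent {agent})")
    Q = _action_values(game, agent, M, V, params, config.discount_beta)
    ties = Q >= Q.max(axis=1, keepdims=True) - config.tie_tol
    policy = ties / ties.sum(axis=1, keepdims=True)
    n_ties = int(np.sum(ties.sum(axis=1) > 1))
    if n_ties:
        logger.debug("best_response(agent %d): %d states with tied actions", agent, n_ties)
    return policy, V


def level_k_tower(
    game: CanyonGame,
    k_max: int,
    params1: CPTParams,
    params2: CPTParams,
    config1: PlanningConfig = PlanningConfig(),
    config2: PlanningConfig | None = None,
) -> LevelKTower:
    """Recursive tower of increasingly sophisticated policies.

    Level 0 is the uniform stereotype for both agents (whose recorded value
    is the evaluation of uniform-vs-uniform play); at level k >= 1, agent
    i best-responds — with its own valuation parameters — to the other
    agent's level k-1 policy. Heterogeneous agents (e.g. one expected-utility
    and one CPT hunter) are supported via distinct parameter sets.
    """
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    config2 = config1 if config2 is None else config2
    params = {1: params1, 2: params2}
    configs = {1: config1, 2: config2}
    uni = uniform_policy(game.n_states, game.n_actions)
    policies: dict[int, list[np.ndarray]] = {1: [uni], 2: [uni]}
    values: dict[int, list[np.ndarray]] = {}
    for agent in (1, 2):
        values[agent] = [
            policy_value(game, agent, uni, uni, params[agent], configs[agent])
        ]
    for k in range(1, k_max + 1):
        for agent, other in ((1, 2), (2, 1)):
            try:
                pol, val = best_response(
                    game, agent, policies[other][k - 1], params[agent], configs[agent]
                )
            except PlanningConvergenceError as exc:
                raise PlanningConvergenceError(
                    f"level-{k} best response of agent {agent} failed: {exc}",
                    exc.residuals,
                ) from exc
            policies[agent].append(pol)
            values[agent].append(val)
    return LevelKTower(policies=policies, values=values, k_max=k_max)
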