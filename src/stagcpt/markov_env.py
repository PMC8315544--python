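"""The Markov stag hunt: a 1-D canyon of hunting positions for two agents.

Each agent occupies one of ``n`` positions at the bottom of a canyon
(default 16) and moves with actions Left / Stay / Right under slip noise:
the intended displacement succeeds with probability 0.6, the agent stays
put with probability 0.2 and slips one step the opposite way with
probability 0.2 (Stay's two slips go one step each way). Probability mass
that would leave the grid is clamped onto staying, which produces the
characteristic 80% corner entries and gives the default kernels exactly
the five entry levels {0, 0.2, 0.4, 0.6, 0.8}.

One position holds hares (a small reward an agent collects alone) and one
holds stags (a large reward paid only when BOTH agents stand on it), so
the high payoff requires coordination.

The joint two-agent kernel follows the simultaneous-move construction

    P^(a1,a2) = (I (x) P^(a1) + P^(a2) (x) I) / 2,

the average over which agent's move resolves first; exactly one agent's
position changes per step. Joint states are flattened internally as
``index = s2 * n + s1`` to match the Kronecker ordering; the public
surface works with (s1, s2) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ACTIONS",
    "DISPLACEMENTS",
    "CanyonSpec",
    "SingleAgentKernel",
    "JointKernel",
    "build_single_kernel",
    "build_joint_kernel",
    "reward",
    "reward_vector",
    "CanyonGame",
]

ACTIONS: tuple[str, ...] = ("left", "stay", "right")
DISPLACEMENTS: tuple[int, ...] = (-1, 0, 1)


@dataclass(frozen=True)
class CanyonSpec:
    """Geometry, rewards and slip noise of the canyon environment."""

    n_positions: int = 16
    hare_position: int = 3
    stag_position: int = 11
    hare_reward: float = 1.0
    stag_reward: float = 5.0
    lone_stag_reward: float = 0.0
    p_intended: float = 0.6
    p_stay_slip: float = 0.2
    p_opposite_slip: float = 0.2

    def __post_init__(self) -> None:
        if self.n_positions < 2:
            raise ValueError("need at least two positions")
        for name in ("hare_position", "stag_position"):
            v = getattr(self, name)
            if not 0 <= v < self.n_positions:
                raise ValueError(f"{name}={v} outside [0, {self.n_positions})")
        if self.hare_position == self.stag_position:
            raise ValueError("hare and stag positions must differ")
        probs = (self.p_intended, self.p_stay_slip, self.p_opposite_slip)
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-12:
            raise ValueError("slip probabilities must be nonnegative and sum to 1")

    @property
    def n_joint_states(self) -> int:
        return self.n_positions**2


@dataclass(frozen=True, eq=False)
class SingleAgentKernel:
    """Row-stochastic n x n transition matrix per action, shape (3, n, n)."""

    matrices: np.ndarray

    @property
    def n(self) -> int:
        return self.matrices.shape[-1]


@dataclass(frozen=True, eq=False)
class JointKernel:
    """Joint transition matrices, shape (3, 3, n^2, n^2) indexed [a1, a2]."""

    matrices: np.ndarray
    n: int

    def index(self, s1: int, s2: int) -> int:
        return s2 * self.n + s1

    def state(self, idx: int) -> tuple[int, int]:
        return idx % self.n, idx // self.n


def build_single_kernel(spec: CanyonSpec) -> SingleAgentKernel:
    """Per-action slip kernels with off-grid mass clamped onto staying.

    For a move action the intended neighbour gets ``p_intended``, the
    current position ``p_stay_slip`` and the opposite neighbour
    ``p_opposite_slip``; Stay keeps ``p_intended`` in place and slips one
    step left/right with ``p_stay_slip`` / ``p_opposite_slip``.
    """
    n = spec.n_positions
    P = np.zeros((len(ACTIONS), n, n))

    def add(a: int, s: int, target: int, prob: float) -> None:
        if not 0 <= target < n:
            target = s  # clamp: mass that would leave the canyon stays
        P[a, s, target] += prob

    for a, d in enumerate(DISPLACEMENTS):
        for s in range(n):
            if d == 0:
                add(a, s, s, spec.p_intended)
                add(a, s, s - 1, spec.p_stay_slip)
                add(a, s, s + 1, spec.p_opposite_slip)
            else:
                add(a, s, s + d, spec.p_intended)
                add(a, s, s, spec.p_stay_slip)
                add(a, s, s - d, spec.p_opposite_slip)
    P.setflags(write=False)
    return SingleAgentKernel(P)


def build_joint_kernel(k1: SingleAgentKernel, k2: SingleAgentKernel) -> JointKernel:
    """Simultaneous-move joint kernel: average of who-acts-first embeddings."""
    if k1.n != k2.n:
        raise ValueError("kernels must share the position count")
    n = k1.n
    eye = np.eye(n)
    P = np.empty((len(ACTIONS), len(ACTIONS), n * n, n * n))
    for a1 in range(len(ACTIONS)):
        move1 = np.kron(eye, k1.matrices[a1])  # agent 1 moves, agent 2 frozen
        for a2 in range(len(ACTIONS)):
            move2 = np.kron(k2.matrices[a2], eye)
            P[a1, a2] = 0.5 * (move1 + move2)
    P.setflags(write=False)
    return JointKernel(P, n)


def reward(spec: CanyonSpec, agent: int, s1: int, s2: int) -> float:
    """Per-step reward of one agent at the joint position (s1, s2).

    The hare reward is unconditional on the partner; the stag reward is
    paid only when both agents stand on the stag position (a lone visitor
    gets ``lone_stag_reward``, 0 by default).
    """
    if agent not in (1, 2):
        raise ValueError("agent must be 1 or 2")
    for s in (s1, s2):
        if not 0 <= s < spec.n_positions:
            raise ValueError(f"state {s} outside [0, {spec.n_positions})")
    own, other = (s1, s2) if agent == 1 else (s2, s1)
    r = 0.0
    if own == spec.hare_position:
        r += spec.hare_reward
    if own == spec.stag_position:
        r += spec.stag_reward if other == spec.stag_position else spec.lone_stag_reward
    return r


def reward_vector(spec: CanyonSpec, agent: int) -> np.ndarray:
    """Rewards over flattened joint states (index = s2 * n + s1)."""
    n = spec.n_positions
    out = np.empty(n * n)
    for s2 in range(n):
        for s1 in range(n):
            out[s2 * n + s1] = reward(spec, agent, s1, s2)
    return out


class CanyonGame:
    """Bundled environment: spec, kernels and per-agent reward vectors."""

    def __init__(self, spec: CanyonSpec) -> None:
        self.spec = spec
        self.single = build_single_kernel(spec)
        self.joint = build_joint_kernel(self.single, self.single)
        self.rewards = {1: reward_vector(spec, 1), 2: reward_vector(spec, 2)}

    @property
    def n_positions(self) -> int:
        return self.spec.n_positions

    @property
    def n_states(self) -> int:
        return self.spec.n_joint_states

    @property
    def n_actions(self) -> int:
        return len(ACTIONS)

    def index(self, s1: int, s2: int) -> int:
        return self.joint.index(s1, s2)

    def state(self, idx: int) -> tuple[int, int]:
        return self.joint.state(idx)
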