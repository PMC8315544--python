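"""Long-run behaviour: policy-conditioned chains and stationary distributions.

Fixing a joint policy turns the Markov game into a Markov chain with

    P(s, s') = sum_{a1, a2} P^(a1,a2)(s, s') pi1(a1|s) pi2(a2|s),

whose stationary distribution ``rho = rho P`` summarizes where the two
hunters spend their time in the long run. The slip noise of the canyon
makes every policy-conditioned chain irreducible and aperiodic in
practice; irreducibility is verified explicitly (strong connectivity of
the positive-entry graph) before solving so that degenerate inputs fail
loudly instead of yielding a spurious eigenvector.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.sparse
from scipy.sparse.csgraph import connected_components

from .cpt import CPTParams
from .markov_env import CanyonSpec, JointKernel
from .planning import PlanningConfig, level_k_tower

__all__ = [
    "StationaryDistribution",
    "CoordinationMetrics",
    "ReducibleChainError",
    "condition_chain",
    "stationary_distribution",
    "coordination_metrics",
    "SweepPoint",
    "run_sweep",
]

_RESIDUAL_TOL = 1e-10


class ReducibleChainError(ValueError):
    """The chain has no unique stationary distribution."""

    def __init__(self, message: str, classes: list[np.ndarray] | None = None):
        super().__init__(message)
        self.classes = classes or []


@dataclass(frozen=True, eq=False)
class StationaryDistribution:
    """Long-run joint-state occupancy rho with its fixed-point residual."""

    probabilities: np.ndarray
    residual: float

    def occupancy(self, n: int) -> np.ndarray:
        """Reshape to an (s1, s2) matrix for an n-position canyon."""
        return self.probabilities.reshape(n, n).T


@dataclass(frozen=True, eq=False)
class CoordinationMetrics:
    """Summary masses of a stationary distribution.

    ``stag_mass``: probability both agents stand on the stag position;
    ``hare_mass``: probability at least one agent stands on the hare
    position; ``marginal1``/``marginal2``: per-position occupancy of each
    agent.
    """

    stag_mass: float
    hare_mass: float
    marginal1: np.ndarray
    marginal2: np.ndarray


def condition_chain(
    joint_kernel: JointKernel, policy1: np.ndarray, policy2: np.ndarray
) -> np.ndarray:
    """Marginalize the joint kernel over both agents' policies."""
    P = joint_kernel.matrices
    n_states = P.shape[-1]
    for pol in (policy1, policy2):
        if pol.shape != (n_states, P.shape[0]):
            raise ValueError("policy shape does not match the joint kernel")
    return np.einsum("sa,sb,abst->st", policy1, policy2, P)


def _communicating_classes(chain: np.ndarray) -> tuple[int, np.ndarray]:
    graph = scipy.sparse.csr_matrix(chain > 0)
    return connected_components(graph, directed=True, connection="strong")


def stationary_distribution(chain: np.ndarray) -> StationaryDistribution:
    """Unique left fixed vector of a row-stochastic irreducible chain.

    Solved by eigen-decomposition of the transpose, then polished by power
    iteration until the sup-norm residual of ``rho P = rho`` is below
    1e-10. A reducible chain (or one with several unit-magnitude
    eigenvalues, i.e. a periodic chain) raises :class:`ReducibleChainError`
    naming the communicating classes found.
    """
    chain = np.asarray(chain, dtype=float)
    if chain.ndim != 2 or chain.shape[0] != chain.shape[1]:
        raise ValueError("chain must be a square matrix")
    if np.any(chain < 0) or np.max(np.abs(chain.sum(axis=1) - 1.0)) > 1e-10:
        raise ValueError("chain must be row-stochastic")
    n_comp, labels = _communicating_classes(chain)
    if n_comp > 1:
        classes = [np.flatnonzero(labels == c) for c in range(n_comp)]
        sizes = sorted((len(c) for c in classes), reverse=True)
        raise ReducibleChainError(
            f"chain is reducible: {n_comp} communicating classes "
            f"(sizes {sizes[:10]}{'...' if n_comp > 10 else ''})",
            classes,
        )
    eigvals, eigvecs = scipy.linalg.eig(chain.T)
    unit = np.abs(np.abs(eigvals) - 1.0) < 1e-8
    if unit.sum() > 1:
        raise ReducibleChainError(
            "chain has multiple unit-magnitude eigenvalues (periodic chain); "
            "no unique limiting behaviour"
        )
    idx = int(np.argmin(np.abs(eigvals - 1.0)))
    rho = np.real(eigvecs[:, idx])
    rho = np.abs(rho)
    rho /= rho.sum()
    residual = float(np.max(np.abs(rho @ chain - rho)))
    # power-iteration polish: each multiplication contracts toward the fixed point
    iters = 0
    while residual > _RESIDUAL_TOL and iters < 100000:
        rho = rho @ chain
        rho /= rho.sum()
        residual = float(np.max(np.abs(rho @ chain - rho)))
        iters += 1
    if residual > _RESIDUAL_TOL:
        raise ReducibleChainError(
            f"stationary residual {residual:.3e} did not reach {_RESIDUAL_TOL}"
        )
    return StationaryDistribution(probabilities=rho, residual=residual)


def coordination_metrics(
    rho: StationaryDistribution, spec: CanyonSpec
) -> CoordinationMetrics:
    """Stag/hare occupancy masses and per-agent marginals of ``rho``."""
    n = spec.n_positions
    occ = rho.occupancy(n)  # occ[s1, s2]
    marginal1 = occ.sum(axis=1)
    marginal2 = occ.sum(axis=0)
    stag_mass = float(occ[spec.stag_position, spec.stag_position])
    h = spec.hare_position
    hare_mass = float(marginal1[h] + marginal2[h] - occ[h, h])
    return CoordinationMetrics(
        stag_mass=stag_mass,
        hare_mass=hare_mass,
        marginal1=marginal1,
        marginal2=marginal2,
    )


@dataclass(frozen=True, eq=False)
class SweepPoint:
    """One sweep setting with its stationary distribution and summaries."""

    setting: dict
    rho: StationaryDistribution
    metrics: CoordinationMetrics


def _tower_rho(game, tower, k1: int, k2: int) -> StationaryDistribution:
    chain = condition_chain(game.joint, tower.policy(1, k1), tower.policy(2, k2))
    return stationary_distribution(chain)


def run_sweep(
    kind: str,
    game,
    base_params: CPTParams,
    config: PlanningConfig = PlanningConfig(),
    *,
    levels: Sequence[int] = (0, 1, 2, 3, 4),
    level_pairs: Sequence[tuple[int, int]] | None = None,
    grid: Sequence[float] | None = None,
    params2: CPTParams | None = None,
) -> list[SweepPoint]:
    """Stationary-distribution sweeps over sophistication and CPT parameters.

    Kinds:
      - ``levels_grid``: all (k1, k2) pairs (or ``level_pairs``) for one
        parameter set (``params2`` for agent 2 if given — this also covers
        the mixed EUT/CPT pairing).
      - ``reference_points``: symmetric levels crossed with a grid of
        reference points ``b``.
      - ``discounts``: symmetric levels crossed with a grid of discount
        factors ``beta``.
      - ``concavity``: symmetric levels crossed with a grid of utility
        exponents ``gamma`` (power utility).

    Every returned distribution satisfies ``rho P = rho`` to 1e-10.
    """
    points: list[SweepPoint] = []
    if kind in ("levels_grid", "agent_mix"):
        p2 = params2 if params2 is not None else base_params
        pairs = (
            list(level_pairs)
            if level_pairs is not None
            else [(k1, k2) for k1 in levels for k2 in levels]
        )
        kmax = max(max(p) for p in pairs)
        tower = level_k_tower(game, kmax, base_params, p2, config)
        for k1, k2 in pairs:
            rho = _tower_rho(game, tower, k1, k2)
            points.append(
                SweepPoint(
                    {"k1": k1, "k2": k2},
                    rho,
                    coordination_metrics(rho, game.spec),
                )
            )
        return points

    if grid is None:
        raise ValueError(f"sweep kind {kind!r} needs a parameter grid")
    kmax = max(levels)
    for v in grid:
        if kind == "reference_points":
            params = replace(base_params, reference_point=float(v))
            cfg = config
            setting_key = "b"
        elif kind == "discounts":
            params = base_params
            cfg = replace(config, discount_beta=float(v))
            setting_key = "beta"
        elif kind == "concavity":
            params = replace(
                base_params, utility=replace(base_params.utility, gamma=float(v))
            )
            setting_key = "gamma"
        else:
            raise ValueError(f"unknown sweep kind {kind!r}")
        tower = level_k_tower(game, kmax, params, params, cfg)
        for k in levels:
            rho = _tower_rho(game, tower, k, k)
            points.append(
                SweepPoint(
                    {setting_key: float(v), "k": k},
                    rho,
                    coordination_metrics(rho, game.spec),
                )
            )
    return points
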