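"""Symmetric 2x2 games under CPT: action values, mixed equilibria, sweeps.

In a symmetric two-action game with payoffs R (both play the first action),
S (first vs second), T (second vs first) and P (both second), an opponent
mixing with probability ``p`` on the first action turns each own action
into a two-outcome prospect. The CPT mixed equilibrium is the probability
``p*`` at which both actions have equal CPT value; with identity utility
and weighting this is the classical mixed Nash equilibrium
``p* = (P - S) / (R - S - T + P)`` when interior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .cpt import CPTParams, DiscreteProspect, cpt_value

__all__ = [
    "SymmetricGame2x2",
    "MixedEquilibrium",
    "action_value",
    "mixed_equilibrium",
    "pure_equilibria",
    "expected_collective_reward",
    "equilibrium_sweep",
    "apply_parameter",
]

logger = logging.getLogger(__name__)

_GRID_POINTS = 2001  # bracketing grid; resolves roots separated by >= 5e-4
_BISECT_WIDTH = 1e-10


@dataclass(frozen=True)
class SymmetricGame2x2:
    """Payoffs of a symmetric two-player, two-action game.

    ``payoff_R``: both play the first action; ``payoff_S``: first against
    second; ``payoff_T``: second against first; ``payoff_P``: both second.
    """

    payoff_R: float
    payoff_S: float
    payoff_T: float
    payoff_P: float
    labels: tuple[str, str] = ("S", "H")

    def __post_init__(self) -> None:
        for v in (self.payoff_R, self.payoff_S, self.payoff_T, self.payoff_P):
            if not np.isfinite(v):
                raise ValueError("payoffs must be finite")

    @classmethod
    def stag_hunt(cls) -> "SymmetricGame2x2":
        """The stag-hunt instance: R=5, S=-1, T=1, P=1 (Stag vs Hare)."""
        return cls(5.0, -1.0, 1.0, 1.0, labels=("S", "H"))


@dataclass(frozen=True)
class MixedEquilibrium:
    """Interior indifference roots plus a boundary flag.

    ``roots`` lists every probability of the first action at which the two
    actions have equal CPT value. When no interior root exists the flag
    records which action dominates; :attr:`first_action_probability` then
    reports 1 (first dominates) or 0.
    """

    roots: tuple[float, ...]
    boundary_flag: str  # "interior", "all_first", "all_second"

    @property
    def first_action_probability(self) -> float:
        if self.roots:
            return self.roots[0]
        return 1.0 if self.boundary_flag == "all_first" else 0.0


def action_value(
    game: SymmetricGame2x2,
    action: int | str,
    p_other_first: float,
    params: CPTParams,
) -> float:
    """CPT value of one action given the opponent plays the first action w.p. p."""
    if not 0.0 <= p_other_first <= 1.0:
        raise ValueError("p_other_first must lie in [0, 1]")
    if isinstance(action, str):
        action = game.labels.index(action)
    if action == 0:
        hi, lo = game.payoff_R, game.payoff_S
    elif action == 1:
        hi, lo = game.payoff_T, game.payoff_P
    else:
        raise ValueError("action must be 0 or 1 (or a game label)")
    prospect = DiscreteProspect([hi, lo], [p_other_first, 1.0 - p_other_first])
    return cpt_value(prospect, params)


def _indifference(game: SymmetricGame2x2, params: CPTParams):
    def f(p: float) -> float:
        return action_value(game, 0, p, params) - action_value(game, 1, p, params)

    return f


def mixed_equilibrium(game: SymmetricGame2x2, params: CPTParams) -> MixedEquilibrium:
    """All mixed-equilibrium roots of the indifference condition.

    The difference ``f(p) = V(first|p) - V(second|p)`` is sampled on a
    2001-point grid; every sign change is refined by bisection until the
    bracket is narrower than 1e-10. If ``f`` never changes sign the
    dominating pure strategy is reported through the boundary flag.
    """
    f = _indifference(game, params)
    grid = np.linspace(0.0, 1.0, _GRID_POINTS)
    fv = np.array([f(p) for p in grid])
    if not np.all(np.isfinite(fv)):
        raise ValueError("indifference condition is non-finite on the grid")
    roots: list[float] = []
    for i in range(grid.size - 1):
        a, b = grid[i], grid[i + 1]
        fa, fb = fv[i], fv[i + 1]
        if fa == 0.0:
            roots.append(float(a))
            continue
        if fa * fb < 0.0:
            while b - a > _BISECT_WIDTH:
                m = 0.5 * (a + b)
                fm = f(m)
                if fm == 0.0:
                    a = b = m
                    break
                if fa * fm < 0.0:
                    b = m
                else:
                    a, fa = m, fm
            roots.append(0.5 * (a + b))
    if fv[-1] == 0.0:
        roots.append(float(grid[-1]))
    roots = sorted({float(round(r, 12)) for r in roots})
    if roots:
        return MixedEquilibrium(tuple(roots), "interior")
    flag = "all_first" if fv[0] > 0 else "all_second"
    return MixedEquilibrium((), flag)


def pure_equilibria(game: SymmetricGame2x2) -> set[tuple[str, str]]:
    """Pure Nash equilibria by best-response enumeration of the 4 profiles."""
    R, S, T, P = game.payoff_R, game.payoff_S, game.payoff_T, game.payoff_P
    a, b = game.labels
    eq: set[tuple[str, str]] = set()
    if R >= T:
        eq.add((a, a))
    if P >= S:
        eq.add((b, b))
    if S >= P and T >= R:
        eq.add((a, b))
        eq.add((b, a))
    return eq


def expected_collective_reward(game: SymmetricGame2x2, p_first: float) -> float:
    """Expected total payoff of both players when each plays first w.p. p."""
    p, q = p_first, 1.0 - p_first
    per_agent = (
        p * p * game.payoff_R
        + p * q * game.payoff_S
        + q * p * game.payoff_T
        + q * q * game.payoff_P
    )
    return 2.0 * per_agent


_PARAM_NAMES = ("reference_point", "b", "alpha", "lambda", "loss_aversion", "gamma")


def apply_parameter(params: CPTParams, name: str, value: float) -> CPTParams:
    """Return a copy of ``params`` with one named scalar parameter replaced."""
    if name in ("reference_point", "b"):
        return replace(params, reference_point=float(value))
    if name == "alpha":
        return replace(params, weighting=replace(params.weighting, alpha=float(value)))
    if name in ("lambda", "loss_aversion"):
        return replace(
            params, utility=replace(params.utility, loss_aversion=float(value))
        )
    if name == "gamma":
        return replace(params, utility=replace(params.utility, gamma=float(value)))
    raise ValueError(f"unknown parameter {name!r}; expected one of {_PARAM_NAMES}")


def equilibrium_sweep(
    game: SymmetricGame2x2,
    axis1: tuple[str, Sequence[float]],
    axis2: tuple[str, Sequence[float]],
    defaults: CPTParams,
) -> np.ndarray:
    """Stag-probability surface over a pair of CPT parameter grids.

    Cell (i, j) holds the equilibrium probability of the first action with
    ``axis1`` parameter set to its i-th grid value and ``axis2`` to its
    j-th, all other parameters at ``defaults``. When several indifference
    roots exist the smallest is reported (and all roots logged); when no
    interior root exists the dominating pure probability (0 or 1) is used.
    Failed cells become NaN.
    """
    name1, grid1 = axis1
    name2, grid2 = axis2
    grid1 = np.asarray(grid1, dtype=float)
    grid2 = np.asarray(grid2, dtype=float)
    out = np.empty((grid1.size, grid2.size))
    for i, v1 in enumerate(grid1):
        for j, v2 in enumerate(grid2):
            params = apply_parameter(
                apply_parameter(defaults, name1, v1), name2, v2
            )
            try:
                eq = mixed_equilibrium(game, params)
            except ValueError as exc:  # pragma: no cover - diagnostic path
                logger.warning(
                    "equilibrium solve failed at %s=%g, %s=%g: %s",
                    name1, v1, name2, v2, exc,
                )
                out[i, j] = np.nan
                continue
            if len(eq.roots) > 1:
                logger.warning(
                    "multiple indifference roots at %s=%g, %s=%g: %s "
                    "(reporting the smallest)",
                    name1, v1, name2, v2, eq.roots,
                )
            out[i, j] = eq.first_action_probability
    return out
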