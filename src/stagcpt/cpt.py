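"""Cumulative prospect theory (CPT) valuation of discrete prospects.

CPT values an uncertain outcome (a discrete random variable) in two steps.
Outcomes are first split into gains and losses relative to a reference
point ``b`` and mapped through a piecewise power utility: ``u+(x) = x**gamma``
for gains and ``u-(x) = -lambda * |x|**gamma`` for losses, where
``lambda >= 1`` expresses loss aversion and ``gamma`` the curvature
(diminishing marginal returns). Second, cumulative probabilities are
distorted by a weighting function ``w``; each outcome receives the
rank-dependent decision weight

    psi+(r) = w(P(R >= r)) - w(P(R > r))   for gains,
    psi-(r) = w(P(R <= r)) - w(P(R < r))   for losses,

and the CPT value is ``sum u(r - b) * psi(r)``. With identity utility,
identity weighting and ``b = 0`` this reduces to the ordinary expectation
(expected utility with linear utility).

Two weighting families are provided: the Prelec function
``w(p) = exp(-alpha * (-log p)**delta)`` and the original 1992 form
``w(p) = p**g / (p**g + (1-p)**g)**(1/g)``, plus the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "UtilitySpec",
    "WeightingSpec",
    "CPTParams",
    "DiscreteProspect",
    "DecisionWeights",
    "utility",
    "weight",
    "decision_weights",
    "cpt_value",
    "cpt_value_rows",
    "certainty_value",
    "gamble_value",
    "decision_surface",
    "rank_integral_oracle",
]

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class UtilitySpec:
    """Piecewise power utility for gains and losses.

    ``kind="identity"`` behaves exactly as ``gamma=1, loss_aversion=1``.
    """

    kind: str = "power"
    gamma: float = 1.0
    loss_aversion: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("power", "identity"):
            raise ValueError(f"unknown utility kind {self.kind!r}")
        if not (np.isfinite(self.gamma) and self.gamma > 0):
            raise ValueError("gamma must be a positive finite real")
        if not (np.isfinite(self.loss_aversion) and self.loss_aversion > 0):
            raise ValueError("loss_aversion must be a positive finite real")

    @classmethod
    def identity(cls) -> "UtilitySpec":
        return cls(kind="identity")


@dataclass(frozen=True)
class WeightingSpec:
    """Probability weighting function specification.

    ``kind="prelec"`` uses ``alpha`` and ``delta``; ``kind="kt1992"`` uses
    ``gamma_w``; ``kind="identity"`` maps p to p.
    """

    kind: str = "prelec"
    alpha: float = 1.0
    delta: float = 0.75
    gamma_w: float = 0.85

    def __post_init__(self) -> None:
        if self.kind not in ("prelec", "kt1992", "identity"):
            raise ValueError(f"unknown weighting kind {self.kind!r}")
        if self.kind == "prelec" and not (self.alpha > 0 and self.delta > 0):
            raise ValueError("prelec weighting needs alpha > 0 and delta > 0")
        if self.kind == "kt1992" and not self.gamma_w > 0:
            raise ValueError("kt1992 weighting needs gamma_w > 0")

    @classmethod
    def identity(cls) -> "WeightingSpec":
        return cls(kind="identity")


@dataclass(frozen=True)
class CPTParams:
    """Full agent valuation model: utility, weighting and reference point."""

    utility: UtilitySpec = UtilitySpec()
    weighting: WeightingSpec = WeightingSpec()
    reference_point: float = 0.0

    @classmethod
    def eut(cls) -> "CPTParams":
        """The expected-utility special case (identity u and w, b = 0)."""
        return cls(UtilitySpec.identity(), WeightingSpec.identity(), 0.0)

    def replace(self, **kw) -> "CPTParams":
        return replace(self, **kw)


def utility(x, spec: UtilitySpec):
    """Evaluate the utility of an offset ``x = r - b`` from the reference point."""
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("utility requires finite inputs")
    if spec.kind == "identity":
        out = arr.copy()
    else:
        mag = np.abs(arr) ** spec.gamma
        out = np.where(arr >= 0, mag, -spec.loss_aversion * mag)
    return float(out) if arr.ndim == 0 else out


def weight(p, spec: WeightingSpec):
    """Apply the probability weighting function to ``p`` in [0, 1].

    The Prelec form is undefined at p = 0; it is extended by its continuity
    limit w(0) = 0.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if spec.kind == "identity":
        out = arr.copy()
    elif spec.kind == "prelec":
        with np.errstate(divide="ignore"):
            out = np.exp(-spec.alpha * (-np.log(arr)) ** spec.delta)
        out = np.where(arr == 0.0, 0.0, out)
    else:  # kt1992
        g = spec.gamma_w
        pg = arr**g
        qg = (1.0 - arr) ** g
        with np.errstate(invalid="ignore"):
            out = pg / (pg + qg) ** (1.0 / g)
        out = np.where(arr == 0.0, 0.0, out)
        out = np.where(arr == 1.0, 1.0, out)
    return float(out) if arr.ndim == 0 else out


class DiscreteProspect:
    """A finite-support random outcome: distinct real values with probabilities.

    Construction sorts outcomes increasingly, drops zero-probability atoms,
    merges (exactly or within ``merge_tol``) duplicate outcomes by summing
    probability, and renormalizes probabilities that deviate from 1 by at
    most 1e-12; a larger deviation is an error.
    """

    __slots__ = ("outcomes", "probabilities")

    def __init__(
        self,
        outcomes: Sequence[float],
        probabilities: Sequence[float],
        merge_tol: float = 0.0,
    ) -> None:
        o = np.atleast_1d(np.asarray(outcomes, dtype=float)).ravel()
        p = np.atleast_1d(np.asarray(probabilities, dtype=float)).ravel()
        if o.size == 0 or o.size != p.size:
            raise ValueError("outcomes and probabilities must be equal-length, non-empty")
        if not np.all(np.isfinite(o)):
            raise ValueError("outcomes must be finite")
        if np.any(p < -_PROB_TOL) or not np.all(np.isfinite(p)):
            raise ValueError("probabilities must be nonnegative and finite")
        total = p.sum()
        if abs(total - 1.0) > _PROB_TOL:
            raise ValueError(f"probabilities sum to {total!r}, not 1 within 1e-12")
        p = np.clip(p, 0.0, None) / total
        keep = p > 0.0
        o, p = o[keep], p[keep]
        order = np.argsort(o, kind="stable")
        o, p = o[order], p[order]
        # merge duplicate (or tol-close) outcomes: group boundaries where gap exceeds tol
        if o.size > 1:
            new_group = np.empty(o.size, dtype=bool)
            new_group[0] = True
            new_group[1:] = np.diff(o) > merge_tol
            starts = np.flatnonzero(new_group)
            pm = np.add.reduceat(p, starts)
            counts = np.diff(np.append(starts, o.size))
            # probability-weighted representative, but never perturb an
            # unmerged outcome by round-off
            om = np.where(
                counts == 1,
                o[starts],
                np.add.reduceat(o * p, starts) / pm,
            )
            o, p = om, pm
        self.outcomes = o
        self.probabilities = p
        self.outcomes.setflags(write=False)
        self.probabilities.setflags(write=False)

    def __len__(self) -> int:
        return self.outcomes.size

    def __repr__(self) -> str:
        pairs = ", ".join(
            f"{o:g}@{p:.4g}" for o, p in zip(self.outcomes, self.probabilities)
        )
        return f"DiscreteProspect({pairs})"

    def expectation(self) -> float:
        return float(self.outcomes @ self.probabilities)

    @classmethod
    def degenerate(cls, r: float) -> "DiscreteProspect":
        return cls([r], [1.0])


@dataclass(frozen=True, eq=False)
class DecisionWeights:
    """Rank-dependent decision weights psi for a prospect's sorted support."""

    outcomes: np.ndarray
    weights: np.ndarray
    is_gain: np.ndarray  # True where outcome >= reference point


def _rank_weights(p_sorted: np.ndarray, gains: np.ndarray, wspec: WeightingSpec):
    """Per-atom decision weights for ascending-sorted rows.

    ``p_sorted`` is (m, n): each row a probability vector aligned with
    ascending outcomes; ``gains`` the matching gain mask. Ties and
    zero-probability atoms are handled positionally — the telescoping sums
    make the result identical to merging duplicates first.
    """
    cum_bot = np.clip(np.cumsum(p_sorted, axis=-1), 0.0, 1.0)
    cum_top = np.clip(
        np.cumsum(p_sorted[..., ::-1], axis=-1)[..., ::-1], 0.0, 1.0
    )
    # rows are probability vectors: pin the full-mass cumulatives to exactly 1
    # (weighting functions with unbounded slope at 1 would otherwise turn
    # 1e-16 summation drift into 1e-12 weight-sum error)
    full_bot = np.abs(cum_bot[..., -1] - 1.0) < 1e-9
    cum_bot[..., -1] = np.where(full_bot, 1.0, cum_bot[..., -1])
    full_top = np.abs(cum_top[..., 0] - 1.0) < 1e-9
    cum_top[..., 0] = np.where(full_top, 1.0, cum_top[..., 0])
    w_top = weight(cum_top, wspec)
    w_bot = weight(cum_bot, wspec)
    w_top_next = np.zeros_like(w_top)
    w_top_next[..., :-1] = w_top[..., 1:]  # w(P(R > r)) positionally
    w_bot_prev = np.zeros_like(w_bot)
    w_bot_prev[..., 1:] = w_bot[..., :-1]  # w(P(R < r)) positionally
    psi_gain = w_top - w_top_next
    psi_loss = w_bot - w_bot_prev
    return np.where(gains, psi_gain, psi_loss)


def cpt_value_rows(
    outcomes: np.ndarray,
    probabilities: np.ndarray,
    params: CPTParams,
    assume_sorted: bool = False,
) -> np.ndarray:
    """CPT value of each row of a batch of prospects.

    ``outcomes`` and ``probabilities`` are (m, n) arrays; rows need not be
    normalized-support prospects — zero-probability and duplicate entries are
    harmless. Set ``assume_sorted`` when each row is already ascending in
    outcome. This is the workhorse behind :func:`cpt_value` and the Markov
    planner's Bellman backup.
    """
    x = np.atleast_2d(np.asarray(outcomes, dtype=float))
    p = np.atleast_2d(np.asarray(probabilities, dtype=float))
    if x.shape != p.shape:
        raise ValueError("outcomes and probabilities must share a shape")
    if not assume_sorted:
        order = np.argsort(x, axis=-1, kind="stable")
        x = np.take_along_axis(x, order, axis=-1)
        p = np.take_along_axis(p, order, axis=-1)
    gains = x >= params.reference_point
    psi = _rank_weights(p, gains, params.weighting)
    u = utility(x - params.reference_point, params.utility)
    return (u * psi).sum(axis=-1)


def decision_weights(
    prospect: DiscreteProspect, b: float, spec: WeightingSpec
) -> DecisionWeights:
    """Rank-dependent weights psi+/psi- of a prospect's outcomes about ``b``."""
    gains = prospect.outcomes >= b
    psi = _rank_weights(prospect.probabilities[None, :], gains[None, :], spec)[0]
    return DecisionWeights(outcomes=prospect.outcomes, weights=psi, is_gain=gains)


def cpt_value(prospect: DiscreteProspect, params: CPTParams) -> float:
    """CPT value of a discrete prospect: sum of u(r - b) psi(r)."""
    return float(
        cpt_value_rows(
            prospect.outcomes[None, :],
            prospect.probabilities[None, :],
            params,
            assume_sorted=True,
        )[0]
    )


def certainty_value(r: float, params: CPTParams) -> float:
    """Value of a sure outcome ``r``: simply u(r - b)."""
    return float(utility(r - params.reference_point, params.utility))


def gamble_value(
    r_plus: float, r_minus: float, p: float, params: CPTParams
) -> float:
    """Value of the two-outcome gamble {r_plus w.p. p, r_minus w.p. 1-p}.

    Implemented through the explicit two-outcome decision-weight branches
    (rather than the generic prospect path), with the weight of each outcome
    depending on which side of the reference point it falls:

        psi(r+) = w(p)       if r+ >= b else 1 - w(1-p)
        psi(r-) = 1 - w(p)   if r- >= b else w(1-p)
    """
    if not r_plus > r_minus:
        raise ValueError("gamble requires r_plus > r_minus")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    b = params.reference_point
    w = params.weighting
    xp, xm = r_plus - b, r_minus - b
    psi_p = weight(p, w) if xp >= 0 else 1.0 - weight(1.0 - p, w)
    psi_m = (1.0 - weight(p, w)) if xm >= 0 else weight(1.0 - p, w)
    return float(
        utility(xp, params.utility) * psi_p + utility(xm, params.utility) * psi_m
    )


def decision_surface(
    r_certain: float,
    r_plus: float,
    r_minus: float,
    p: float,
    b_grid: Sequence[float],
    alpha_grid: Sequence[float],
    utility_spec: UtilitySpec,
    delta: float = 0.75,
    weighting_kind: str = "prelec",
) -> np.ndarray:
    """Certainty-minus-gamble value over a (b, alpha) grid.

    Rows index ``b_grid``, columns ``alpha_grid``. A positive cell means the
    agent prefers the sure outcome. With identity weighting the alpha axis
    is inert and the surface is flat in that direction.
    """
    b_grid = np.asarray(b_grid, dtype=float)
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if b_grid.size == 0 or alpha_grid.size == 0:
        raise ValueError("grids must be non-empty")
    out = np.empty((b_grid.size, alpha_grid.size))
    for i, b in enumerate(b_grid):
        for j, alpha in enumerate(alpha_grid):
            wspec = WeightingSpec(kind=weighting_kind, alpha=float(alpha), delta=delta)
            params = CPTParams(utility_spec, wspec, float(b))
            out[i, j] = certainty_value(r_certain, params) - gamble_value(
                r_plus, r_minus, p, params
            )
    return out


def rank_integral_oracle(prospect: DiscreteProspect, params: CPTParams) -> float:
    """CPT value via the integral of the weighted survival function.

    Independent evaluation route used to cross-check :func:`cpt_value`: for
    the nonnegative step variables U+ = u+((R - b)+) and U- = -u-(-(R - b)-),

        V = integral_0^inf w(P(U+ > eps)) d eps
          - integral_0^inf w(P(U- > eps)) d eps.

    Each integrand is piecewise constant, so the integral is evaluated
    exactly piece by piece with the survival probability taken at piece
    midpoints (never reusing the rank-weight algebra of :func:`cpt_value`).
    """
    b = params.reference_point
    gains = prospect.outcomes >= b

    def survival_integral(levels: np.ndarray, probs: np.ndarray) -> float:
        if levels.size == 0:
            return 0.0
        order = np.argsort(levels)
        levels, probs = levels[order], probs[order]
        edges = np.concatenate(([0.0], levels))
        total = 0.0
        for lo, hi in zip(edges[:-1], edges[1:]):
            if hi <= lo:
                continue
            mid = 0.5 * (lo + hi)
            surv = min(float(probs[levels > mid].sum()), 1.0)
            total += (hi - lo) * weight(surv, params.weighting)
        return total

    gain_levels = np.asarray(
        utility(prospect.outcomes[gains] - b, params.utility), dtype=float
    ).ravel()
    loss_levels = -np.asarray(
        utility(prospect.outcomes[~gains] - b, params.utility), dtype=float
    ).ravel()
    pos = survival_integral(gain_levels, prospect.probabilities[gains])
    neg = survival_integral(loss_levels, prospect.probabilities[~gains])
    return pos - neg
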