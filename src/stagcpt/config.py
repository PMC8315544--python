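"""YAML configuration for agent parameters and canyon environments."""

from __future__ import annotations

from pathlib import Path

import yaml

from .cpt import CPTParams, UtilitySpec, WeightingSpec
from .markov_env import CanyonSpec

__all__ = ["cpt_params_from_dict", "load_cpt_params", "canyon_spec_from_dict", "load_canyon_spec"]


def cpt_params_from_dict(data: dict) -> CPTParams:
    """Build agent parameters from a nested mapping.

    Recognized keys: ``utility.kind``, ``utility.gamma``, ``utility.lambda``,
    ``weighting.kind``, ``weighting.alpha``, ``weighting.delta``,
    ``weighting.gamma`` (the 1992 exponent) and ``reference_point``.
    """
    u = data.get("utility", {}) or {}
    w = data.get("weighting", {}) or {}
    utility = UtilitySpec(
        kind=u.get("kind", "power"),
        gamma=float(u.get("gamma", 1.0)),
        loss_aversion=float(u.get("lambda", u.get("loss_aversion", 1.0))),
    )
    weighting = WeightingSpec(
        kind=w.get("kind", "prelec"),
        alpha=float(w.get("alpha", 1.0)),
        delta=float(w.get("delta", 0.75)),
        gamma_w=float(w.get("gamma", w.get("gamma_w", 0.85))),
    )
    return CPTParams(utility, weighting, float(data.get("reference_point", 0.0)))


def load_cpt_params(path: str | Path) -> CPTParams:
    with open(path) as fh:
        return cpt_params_from_dict(yaml.safe_load(fh) or {})


def canyon_spec_from_dict(data: dict) -> CanyonSpec:
    known = {
        "n_positions", "hare_position", "stag_position", "hare_reward",
        "stag_reward", "lone_stag_reward", "p_intended", "p_stay_slip",
        "p_opposite_slip",
    }
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown canyon keys: {sorted(unknown)}")
    return CanyonSpec(**data)


def load_canyon_spec(path: str | Path) -> CanyonSpec:
    with open(path) as fh:
        return canyon_spec_from_dict(yaml.safe_load(fh) or {})
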