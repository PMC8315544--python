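"""Named, reproducible experiment runs tying the whole pipeline together.

Each registered experiment fixes the exact parameter set of one analysis
(gamble decision surfaces, normal-form equilibrium sweeps, level-k towers,
stationary-distribution sweeps) and writes deterministic tab-separated
tables plus a JSON manifest recording every parameter, tolerance and
residual. Re-running an experiment produces byte-identical tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import normal_form, stationary
from .cpt import CPTParams, UtilitySpec, WeightingSpec, decision_surface
from .markov_env import CanyonGame, CanyonSpec
from .planning import PlanningConfig, level_k_tower

__all__ = [
    "ExperimentSpec",
    "EXPERIMENTS",
    "run_experiment",
    "generate_fixture_env",
    "MARKOV_CPT_PARAMS",
    "EUT_PARAMS",
]

logger = logging.getLogger(__name__)

#: CPT parameter set used throughout the Markov-game analyses:
#: identity utility, Prelec weighting w(x) = exp(-0.5 (-log x)^0.9), b = 0.
MARKOV_CPT_PARAMS = CPTParams(
    UtilitySpec.identity(), WeightingSpec("prelec", alpha=0.5, delta=0.9), 0.0
)

#: Expected-utility agent: identity utility and weighting, b = 0.
EUT_PARAMS = CPTParams.eut()


@dataclass(frozen=True)
class ExperimentSpec:
    """A named experiment with optional parameter overrides."""

    name: str
    overrides: dict = field(default_factory=dict)
    out_dir: str | Path = "results"
    log_level: str = "INFO"


def generate_fixture_env(n_positions: int, hare: int, stag: int) -> CanyonSpec:
    """A reduced canyon with the default slip rule, for tests and demos."""
    return CanyonSpec(n_positions=n_positions, hare_position=hare, stag_position=stag)


def _write_matrix(
    path: Path, matrix: np.ndarray, rows, cols, row_name: str, col_name: str
) -> None:
    df = pd.DataFrame(np.asarray(matrix), index=list(rows), columns=list(cols))
    df.index.name = f"{row_name}\\{col_name}"
    df.to_csv(path, sep="\t", float_format="%.12g")


def _write_manifest(out: Path, name: str, payload: dict) -> Path:
    path = out / "manifest.json"
    payload = {"experiment": name, **payload}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
    return path


def _markov_setup(overrides: dict) -> tuple[CanyonGame, PlanningConfig]:
    spec_kw = {
        k: overrides[k]
        for k in (
            "n_positions", "hare_position", "stag_position", "hare_reward",
            "stag_reward", "lone_stag_reward", "p_intended", "p_stay_slip",
            "p_opposite_slip",
        )
        if k in overrides
    }
    game = CanyonGame(CanyonSpec(**spec_kw))
    config = PlanningConfig(
        discount_beta=float(overrides.get("beta", 0.9)),
        tol=float(overrides.get("tol", 1e-8)),
    )
    return game, config


def _cpt_params(overrides: dict) -> CPTParams:
    params = MARKOV_CPT_PARAMS
    if "b" in overrides:
        params = replace(params, reference_point=float(overrides["b"]))
    if "gamma" in overrides:
        params = replace(
            params, utility=UtilitySpec("power", float(overrides["gamma"]), 1.0)
        )
    return params


def _gamble_panels(overrides: dict):
    """The four certainty-vs-gamble scenarios of the decision-surface study."""
    if overrides.get("identity_limit"):
        uspec = UtilitySpec.identity()
        kind = "identity"
    else:
        uspec = UtilitySpec("power", gamma=0.85, loss_aversion=2.0)
        kind = "prelec"
    delta = float(overrides.get("delta", 0.75))
    res = int(overrides.get("resolution", 61))
    b_grid = np.linspace(-200.0, 200.0, res)
    alpha_grid = np.linspace(0.05, 3.0, res)
    # (certain, gamble high, gamble low, P(high)); EUT gamble values 950/-950/50/-50
    panels = {
        "a": (900.0, 1000.0, 0.0, 0.95),
        "b": (-900.0, 0.0, -1000.0, 0.05),
        "c": (55.0, 1000.0, 0.0, 0.05),
        "d": (-55.0, 0.0, -1000.0, 0.95),
    }
    return uspec, kind, delta, b_grid, alpha_grid, panels


def _run_fig2(out: Path, overrides: dict) -> dict:
    uspec, kind, delta, b_grid, alpha_grid, panels = _gamble_panels(overrides)
    files = {}
    for panel, (rc, rp, rm, p) in panels.items():
        surface = decision_surface(
            rc, rp, rm, p, b_grid, alpha_grid, uspec, delta, weighting_kind=kind
        )
        path = out / f"surface_{panel}.tsv"
        _write_matrix(path, surface, b_grid, alpha_grid, "b", "alpha")
        files[panel] = path.name
    return {
        "panels": {k: dict(zip(("certain", "high", "low", "p_high"), v))
                   for k, v in panels.items()},
        "utility": asdict(uspec),
        "weighting_kind": kind,
        "delta": delta,
        "files": files,
    }


_FIG3_GRIDS = {
    "b": (-3.0, 3.0),
    "alpha": (0.1, 3.0),
    "lambda": (0.25, 4.0),
    "gamma": (0.25, 2.0),
}
_FIG3_PAIRS = [
    ("alpha", "b"), ("alpha", "lambda"), ("alpha", "gamma"),
    ("b", "lambda"), ("b", "gamma"), ("lambda", "gamma"),
]


def _run_fig3(out: Path, overrides: dict) -> dict:
    res = int(overrides.get("resolution", 41))
    delta = float(overrides.get("delta", 0.75))
    defaults = CPTParams(
        UtilitySpec("power", 1.0, 1.0),
        WeightingSpec("prelec", alpha=1.0, delta=delta),
        0.0,
    )
    game = normal_form.SymmetricGame2x2.stag_hunt()
    files = {}
    for name1, name2 in _FIG3_PAIRS:
        g1 = np.linspace(*_FIG3_GRIDS[name1], res)
        g2 = np.linspace(*_FIG3_GRIDS[name2], res)
        mat = normal_form.equilibrium_sweep(game, (name1, g1), (name2, g2), defaults)
        path = out / f"stag_probability_{name1}_{name2}.tsv"
        _write_matrix(path, mat, g1, g2, name1, name2)
        files[f"{name1}_{name2}"] = path.name
    return {
        "defaults": {"b": 0.0, "alpha": 1.0, "lambda": 1.0, "gamma": 1.0,
                     "delta": delta},
        "payoffs": asdict(game),
        "grids": {k: list(v) + [res] for k, v in _FIG3_GRIDS.items()},
        "files": files,
    }


def _write_tower(out: Path, game: CanyonGame, tower, agents=(1, 2)) -> dict:
    files = {}
    states = np.arange(game.n_states)
    for agent in agents:
        for k in range(tower.k_max + 1):
            vpath = out / f"value_agent{agent}_k{k}.tsv"
            _write_matrix(
                vpath, tower.value(agent, k)[:, None], states, ["value"],
                "joint_state", "",
            )
            ppath = out / f"policy_agent{agent}_k{k}.tsv"
            _write_matrix(
                ppath, tower.policy(agent, k), states,
                ["left", "stay", "right"], "joint_state", "action",
            )
            files[f"agent{agent}_k{k}"] = [vpath.name, ppath.name]
    return files


def _run_tower_experiment(
    out: Path, overrides: dict, params1: CPTParams, params2: CPTParams
) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    game, config = _markov_setup(overrides)
    kmax = int(overrides.get("k_max", 4))
    tower = level_k_tower(game, kmax, params1, params2, config)
    files = _write_tower(out, game, tower)
    return {
        "params_agent1": asdict(params1),
        "params_agent2": asdict(params2),
        "planning": asdict(config),
        "canyon": asdict(game.spec),
        "k_max": kmax,
        "files": files,
    }


def _write_sweep_points(out: Path, game: CanyonGame, points) -> dict:
    files = {}
    rows = []
    for pt in points:
        tag = "_".join(f"{k}{v:g}" if isinstance(v, float) else f"{k}{v}"
                       for k, v in pt.setting.items())
        path = out / f"stationary_{tag}.tsv"
        n = game.n_positions
        _write_matrix(
            path, pt.rho.occupancy(n), np.arange(n), np.arange(n), "s1", "s2"
        )
        files[tag] = path.name
        rows.append({**pt.setting, "stag_mass": pt.metrics.stag_mass,
                     "hare_mass": pt.metrics.hare_mass,
                     "residual": pt.rho.residual})
    pd.DataFrame(rows).to_csv(out / "metrics.tsv", sep="\t", index=False,
                              float_format="%.12g")
    files["metrics"] = "metrics.tsv"
    return files


def _run_stationary_experiment(out: Path, overrides: dict, kind: str,
                               params1: CPTParams, params2: CPTParams | None,
                               **sweep_kw) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    game, config = _markov_setup(overrides)
    if "levels" in overrides:
        sweep_kw["levels"] = tuple(overrides["levels"])
    points = stationary.run_sweep(
        kind, game, params1, config, params2=params2, **sweep_kw
    )
    files = _write_sweep_points(out, game, points)
    return {
        "kind": kind,
        "params_agent1": asdict(params1),
        "params_agent2": asdict(params2) if params2 is not None else None,
        "planning": asdict(config),
        "canyon": asdict(game.spec),
        "sweep": {k: list(v) if isinstance(v, (tuple, list)) else v
                  for k, v in sweep_kw.items()},
        "files": files,
    }


def _run_fig6(out: Path, ov: dict) -> dict:
    return _run_tower_experiment(out, ov, _cpt_params(ov), _cpt_params(ov))


def _run_fig7(out: Path, ov: dict) -> dict:
    return _run_stationary_experiment(
        out, ov, "levels_grid", _cpt_params(ov), None,
        levels=tuple(range(int(ov.get("k_max", 4)) + 1)),
    )


def _run_fig8(out: Path, ov: dict) -> dict:
    game, config = _markov_setup(ov)
    grid = [float(b) for b in ov.get("b_grid", (-1.0, 0.0, 1.0, 2.0))]
    levels = tuple(ov.get("levels", (1, 2, 3, 4)))
    points = stationary.run_sweep(
        "reference_points", game, MARKOV_CPT_PARAMS, config,
        levels=levels, grid=grid,
    )
    files = _write_sweep_points(out, game, points)
    return {
        "kind": "reference_points", "b_grid": grid, "levels": list(levels),
        "params": asdict(MARKOV_CPT_PARAMS), "planning": asdict(config),
        "canyon": asdict(game.spec), "files": files,
    }


def _run_s1(out: Path, ov: dict) -> dict:
    meta_cpt = _run_tower_experiment(out / "cpt", ov, _cpt_params(ov), _cpt_params(ov))
    meta_eut = _run_tower_experiment(out / "eut", ov, EUT_PARAMS, EUT_PARAMS)
    return {"cpt": meta_cpt, "eut": meta_eut}


def _run_s2(out: Path, ov: dict) -> dict:
    levels = tuple(ov.get("levels", (1, 2, 3, 4)))
    pairs = [(k, k) for k in levels]
    meta_cpt = _run_stationary_experiment(
        out / "cpt", ov, "levels_grid", _cpt_params(ov), None, level_pairs=pairs
    )
    meta_eut = _run_stationary_experiment(
        out / "eut", ov, "levels_grid", EUT_PARAMS, None, level_pairs=pairs
    )
    return {"cpt": meta_cpt, "eut": meta_eut}


def _run_s3(out: Path, ov: dict) -> dict:
    betas = [float(b) for b in ov.get("beta_grid", (0.85, 0.95))]
    levels = tuple(ov.get("levels", (1, 2, 3, 4)))
    meta = {}
    for label, params in (("eut", EUT_PARAMS), ("cpt", _cpt_params(ov))):
        meta[label] = _run_stationary_experiment(
            out / label, ov, "discounts", params, None, levels=levels, grid=betas
        )
    return meta


def _run_s4(out: Path, ov: dict) -> dict:
    return _run_stationary_experiment(
        out, ov, "levels_grid", EUT_PARAMS, None,
        levels=tuple(range(int(ov.get("k_max", 4)) + 1)),
    )


def _run_s5(out: Path, ov: dict) -> dict:
    # agent 1 expected-utility, agent 2 CPT
    return _run_stationary_experiment(
        out, ov, "levels_grid", EUT_PARAMS, _cpt_params(ov),
        levels=tuple(range(int(ov.get("k_max", 4)) + 1)),
    )


def _concavity_runner(gamma: float):
    def run(out: Path, ov: dict) -> dict:
        params = _cpt_params({**ov, "gamma": ov.get("gamma", gamma)})
        return _run_stationary_experiment(
            out, ov, "levels_grid", params, None,
            levels=tuple(range(int(ov.get("k_max", 4)) + 1)),
        )

    return run


EXPERIMENTS = {
    "fig2": _run_fig2,
    "fig3": _run_fig3,
    "fig6": _run_fig6,
    "fig7": _run_fig7,
    "fig8": _run_fig8,
    "s1": _run_s1,
    "s2": _run_s2,
    "s3": _run_s3,
    "s4": _run_s4,
    "s5": _run_s5,
    "s6": _concavity_runner(0.99),
    "s7": _concavity_runner(0.95),
}


def run_experiment(spec: ExperimentSpec) -> Path:
    """Run a named (or custom) experiment and return its manifest path.

    ``name="custom"`` runs a level-k tower plus stationary sweep on a
    canyon described entirely by the overrides.
    """
    logging.basicConfig(level=spec.log_level)
    out = Path(spec.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if spec.name == "custom":
        meta = _run_stationary_experiment(
            out, spec.overrides, "levels_grid", _cpt_params(spec.overrides), None,
            levels=tuple(range(int(spec.overrides.get("k_max", 2)) + 1)),
        )
    elif spec.name in EXPERIMENTS:
        meta = EXPERIMENTS[spec.name](out, dict(spec.overrides))
    else:
        raise ValueError(
            f"unknown experiment {spec.name!r}; known: {sorted(EXPERIMENTS)} + ['custom']"
        )
    return _write_manifest(out, spec.name, {"overrides": dict(spec.overrides), **meta})
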