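import numpy as np
import pytest

from stagcpt.cpt import CPTParams
from stagcpt.experiments import generate_fixture_env
from stagcpt.markov_env import CanyonGame, CanyonSpec
from stagcpt.planning import PlanningConfig, level_k_tower


@pytest.fixture(scope="session")
def game() -> CanyonGame:
    """The default 16-position canyon (hare at 3, stag at 11)."""
    return CanyonGame(CanyonSpec())


@pytest.fixture(scope="session")
def tiny_game() -> CanyonGame:
    """A 2-position canyon: 4 joint states, enumeration-oracle sized."""
    return CanyonGame(generate_fixture_env(2, 0, 1))


@pytest.fixture(scope="session")
def small_game() -> CanyonGame:
    """A 4-position canyon for brute-force kernel checks."""
    return CanyonGame(generate_fixture_env(4, 0, 3))


@pytest.fixture(scope="session")
def towers(game):
    """Session-wide memoized level-k towers on the default canyon.

    Symmetric-agent towers keyed by (params, config); asking for a higher
    level extends (recomputes) the cached tower.
    """
    cache: dict = {}

    def get(params: CPTParams, k_max: int, config: PlanningConfig = PlanningConfig()):
        key = (params, config)
        existing = cache.get(key)
        if existing is None or existing.k_max < k_max:
            cache[key] = level_k_tower(game, k_max, params, params, config)
        return cache[key]

    return get


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20210715)
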