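import numpy as np
import pytest

from attnspace import SimConfig, simulate_population
from attnspace.config import ATTENTION_TASKS


def unity_gain_kwargs():
    """Config overrides making every attentional gain exactly 1."""
    zero = (0.0, 0.0)
    return {
        "gain_log_mean_sd": {
            area: {task: zero for task in ATTENTION_TASKS}
            for area in ("AIT", "LIP")
        },
        "passive_offset_log_mean_sd": {"AIT": zero, "LIP": zero},
    }


def make_config(**overrides) -> SimConfig:
    base = {"n_cells_per_area": {"AIT": 12, "LIP": 10}, "seed": 11}
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_session():
    """A modest noisy session with default statistical structure."""
    cfg = make_config()
    table, truth = simulate_population(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def noiseless_unity_session():
    """Deterministic rates, all gains 1, no warp: the identity scenario."""
    cfg = make_config(trial_noise=False, seed=5, **unity_gain_kwargs())
    table, truth = simulate_population(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(202409)
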