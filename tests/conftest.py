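import numpy as np
import pytest

from oddballeeg import SimulationConfig, simulate_subject, simulate_study
from oddballeeg.simulate import subject_rng


def tiny_config(**overrides) -> SimulationConfig:
    base = dict(
        n_asd=2,
        n_td=2,
        n_channels=12,
        epochs_per_block=60,
        blocks_per_subject=1,
        seed=7,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def tiny_cfg() -> SimulationConfig:
    return tiny_config()


@pytest.fixture(scope="session")
def tiny_subject(tiny_cfg):
    """One small simulated TD subject with its ground truth."""
    rec, truth = simulate_subject(tiny_cfg, "TD", subject_rng(tiny_cfg.seed, 0))
    return rec, truth


@pytest.fixture(scope="session")
def tiny_study(tiny_cfg):
    return simulate_study(tiny_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
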