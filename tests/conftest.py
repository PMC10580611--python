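import numpy as np
import pytest

from opioidsim.params import ModelParams, RunConfig


@pytest.fixture
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def small_run_cfg(n_runs=1, n_agents=2_000, years=1, seed=11) -> RunConfig:
    return RunConfig(n_runs=n_runs, n_agents=n_agents, years=years,
                     base_seed=seed)
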