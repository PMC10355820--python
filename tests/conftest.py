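import numpy as np
import pytest

from methdrift.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def study(default_config):
    """One full two-dataset study at the default conditions (seed 1)."""
    return simulate_study(default_config)


@pytest.fixture(scope="session")
def trained(study):
    """Full pipeline artifacts on the session study."""
    from methdrift.pipeline import train_composite_pipeline

    truth = study["truth"]
    n_drivers = sum(1 for v in truth.cpg_module.values() if v > 0)
    cons, clocks, selected, model = train_composite_pipeline(
        study["passaging_train"][:2],
        study["tissue"][:2],
        study["passaging_val"][:2],
        study["tissue_val"][:2],
        n_drivers=n_drivers,
        seed=1,
    )
    return {"consensus": cons, "clocks": clocks, "selected": selected,
            "model": model}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
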