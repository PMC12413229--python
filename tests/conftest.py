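import numpy as np
import pytest

from stentca import engine, scenarios

# ten-seed bank used for all stochastic ensemble statistics
SEEDS = tuple(range(1, 11))

PDLLA_BANK_STEPS = 1500
PBAT_BANK_STEPS = 1600


def _bank(name, steps):
    runs = []
    for s in SEEDS:
        cfg = scenarios.make_scenario(name, steps=steps, seed=s)
        runs.append(engine.run(cfg))
    return runs


@pytest.fixture(scope="session")
def pdlla_bank():
    """Ten PDLLA-deformed runs (seeds 1-10), 1500 steps each."""
    return _bank("PDLLA-deformed", PDLLA_BANK_STEPS)


@pytest.fixture(scope="session")
def pbat_bank():
    """Ten PBAT-deformed runs (seeds 1-10), 1600 steps each."""
    return _bank("PBAT-deformed", PBAT_BANK_STEPS)


@pytest.fixture(scope="session")
def small_run():
    """One short PDLLA-deformed run with frequent snapshots, for mechanism checks."""
    cfg = scenarios.make_scenario("PDLLA-deformed", steps=300, seed=7)
    cfg.snapshot_every = 50
    return engine.run(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
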