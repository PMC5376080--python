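import numpy as np
import pytest

from straydose import benchmarks, transport


@pytest.fixture(scope="session")
def mini_scenario():
    return benchmarks.make_mini_phantom_scenario()


@pytest.fixture(scope="session")
def mini_run_analog(mini_scenario):
    """One shared analog run of the mini phantom (target/near/far tallies)."""
    cfg = transport.RunConfig(n_histories=4000, n_batches=10, seed=11,
                              analog=True)
    return transport.run(mini_scenario, cfg)


@pytest.fixture(scope="session")
def water_sphere_run():
    sc = benchmarks.build_water_sphere_scenario()
    cfg = transport.RunConfig(n_histories=8000, n_batches=10, seed=7,
                              analog=True)
    return transport.run(sc, cfg), sc


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
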