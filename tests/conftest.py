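import numpy as np
import pytest

from sweeptime.simulate import SimulationParams, simulate_sweep


def small_params(**overrides) -> SimulationParams:
    base = dict(
        scenario="constant", NA=120, s=0.3, h=0.5, mu=8e-7, R=1e-6,
        ta=20, r=0.0, K=120, L=20_000, n=24, seed=11,
    )
    base.update(overrides)
    return SimulationParams(**base)


@pytest.fixture(scope="session")
def small_result():
    """One completed small sweep replicate shared across tests."""
    res = simulate_sweep(small_params())
    assert res.status == "complete"
    return res


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_window(rng, n=10, S=8, span=1000.0):
    """A random valid GenotypeWindow for fuzz tests."""
    from sweeptime.sumstats import GenotypeWindow

    while True:
        dosages = rng.integers(0, 3, size=(n, S)).astype(np.uint8)
        counts = dosages.sum(axis=0)
        if np.all((counts > 0) & (counts < 2 * n)):
            break
    positions = np.sort(rng.uniform(0, span, size=S))
    return GenotypeWindow(dosages=dosages, positions=positions, center=span / 2)
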