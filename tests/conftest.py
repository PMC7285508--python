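import numpy as np
import pytest

import fermcurve as fc


@pytest.fixture(scope="session")
def schedule():
    return fc.default_schedule()


@pytest.fixture(scope="session")
def small_screen():
    """A 4-candidate noisy screen, shared read-only across tests."""
    spec = fc.default_sim_spec(seed=42, n_candidates=4, noise_sd=0.03)
    return fc.simulate_screen(spec)


def make_series(times, values, candidate="c1", replicate=1, analyte="cfu"):
    return fc.SampleSeries(candidate, replicate, analyte,
                           np.asarray(times, float),
                           np.asarray(values, float))


@pytest.fixture
def series_factory():
    return make_series
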