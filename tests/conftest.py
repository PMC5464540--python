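import numpy as np
import pytest

from viroprod.series import IncubationSeries


def make_series(values, times=None, treatment="dilution", population="virus",
                station="s", zone="anoxic", replicate=1):
    if times is None:
        times = [5.0 * i for i in range(len(values))]
    return IncubationSeries(
        station=station, zone=zone, treatment=treatment, replicate=replicate,
        population=population, times=tuple(times),
        abundances=tuple(float(v) for v in values),
    )


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def sawtooth():
    """Rises {2e5, 3e5}, falls {1e5, 2e5} over 40 h."""
    return make_series(
        [3e5, 5e5, 4e5, 7e5, 5e5], times=[0, 10, 20, 30, 40]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
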