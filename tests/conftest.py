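import numpy as np
import pytest

from chromacast.rems_io import Parameter, SensorSeries


def make_series(
    values,
    parameter=Parameter.TEMPERATURE,
    missing=None,
    regular=True,
    timestamps=None,
):
    """Convenience SensorSeries factory for tests."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if timestamps is None:
        timestamps = np.arange(n, dtype=float)
    if missing is None:
        missing = np.isnan(values)
    else:
        missing = np.asarray(missing, dtype=bool)
        values = values.copy()
        values[missing] = np.nan
    return SensorSeries(
        parameter=parameter,
        timestamps=np.asarray(timestamps, dtype=float),
        values=values,
        missing_mask=missing,
        regular=regular,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid_1501():
    return np.linspace(0.0, 20.0, 1501)


def gaussian_mix(time, peaks):
    """Sum of Gaussians given (mu, sigma, height) triples."""
    out = np.zeros_like(time)
    for mu, sigma, height in peaks:
        out += height * np.exp(-0.5 * ((time - mu) / sigma) ** 2)
    return out
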