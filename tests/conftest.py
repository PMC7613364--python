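import numpy as np
import pytest

from phenofill import Hyperparameters, TimeSeries
from phenofill.core_gpr import PredictiveSeries


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def theta():
    """A mid-range hyperparameter triple (l ~ 38 d, sigma_f ~ 0.62,
    sigma_n ~ 0.17) typical of agricultural LAI series."""
    return Hyperparameters(-3.6430, -0.4817, -1.7442)


@pytest.fixture
def small_series(rng):
    t = np.sort(rng.uniform(0, 365, 25))
    y = 2.0 * np.sin(2 * np.pi * t / 365.0) + rng.normal(0, 0.2, t.size)
    return TimeSeries(t, y)


def random_series(rng, n, span=730.0, noise=0.2):
    t = np.sort(rng.uniform(0, span, n))
    # jittered-sine signal: smooth, nonzero, no accidental ties
    y = rng.uniform(0.5, 3.0) * np.sin(2 * np.pi * t / rng.uniform(200, 500))
    return TimeSeries(t, y + rng.normal(0, noise, n))


def random_theta(rng):
    return Hyperparameters(
        rng.uniform(-5.0, -1.5), rng.uniform(-1.5, 0.8), rng.uniform(-3.0, -0.5)
    )


@pytest.fixture
def triangle_series():
    """Daily-grid triangle: base 0, rise day 50 -> peak (100, 5) -> fall to
    day 150; analytic 20%-threshold metrics: SOS 60, EOS 140, LOS 80,
    DOM 100, amplitude 5, blue = green = 240."""
    t = np.arange(0.0, 201.0)
    v = np.interp(t, [0, 50, 100, 150, 200], [0, 0, 5, 0, 0])
    return PredictiveSeries(t, v, np.zeros_like(t))
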