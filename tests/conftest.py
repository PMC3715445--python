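import numpy as np
import pytest

from tickertape import ConcentrationTrace, LinearCMLF, PolymeraseKinetics, TimeGrid


@pytest.fixture
def phi29():
    """phi29-like kinetics: 20 ms elongation, 300 ms pauses at 5% density."""
    return PolymeraseKinetics(tau_e=20.0, tau_p=300.0, pause_prob=0.05)


@pytest.fixture
def fast_kin():
    """Fast pause-free polymerase (1000 nt/s), the binary-decoding regime."""
    return PolymeraseKinetics(tau_e=1.0, tau_p=100.0, pause_prob=0.0)


@pytest.fixture
def dpo4_link():
    """Dpo4-like link: 0.5% baseline, 3% at high concentration."""
    return LinearCMLF(e0=0.005, m=0.025)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_trace(values, dt_ms):
    values = np.asarray(values, dtype=float)
    return ConcentrationTrace(TimeGrid(dt_ms, dt_ms * values.size), values)


@pytest.fixture
def eight_condition_grid():
    return TimeGrid(150_000.0, 1_200_000.0)
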