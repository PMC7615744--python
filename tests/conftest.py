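import numpy as np
import pytest

from cahandling import (
    MyocyteParams,
    NoiseSpec,
    Protocol,
    full_report,
    render_fluorescence,
    simulate_myocyte,
)


@pytest.fixture(scope="session")
def default_params():
    return MyocyteParams()


@pytest.fixture(scope="session")
def short_protocol():
    """8-beat train + caffeine: fast enough for per-test reuse."""
    return Protocol(n_beats=8, caffeine_onset=11.0, duration=21.0)


@pytest.fixture(scope="session")
def sim_short(default_params, short_protocol):
    return simulate_myocyte(default_params, short_protocol)


@pytest.fixture(scope="session")
def sim_default(default_params):
    return simulate_myocyte(default_params, Protocol())


@pytest.fixture(scope="session")
def trace_clean(sim_default):
    return render_fluorescence(sim_default, noise=NoiseSpec(channel_sd=0.0, seed=0))


@pytest.fixture(scope="session")
def trace_clean_short(sim_short):
    return render_fluorescence(sim_short, noise=NoiseSpec(channel_sd=0.0, seed=0))


@pytest.fixture(scope="session")
def report_clean(trace_clean):
    return full_report(trace_clean)


@pytest.fixture(scope="session")
def exp_decay():
    """Mono-exponential recovery c(t) = 0.1 + 0.9 exp(-5 t) uM at 1 kHz."""
    t = np.arange(0.0, 1.5, 1e-3)
    return t, 0.1 + 0.9 * np.exp(-5.0 * t)
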