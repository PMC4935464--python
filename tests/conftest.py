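import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wormlearn import synth

settings.register_profile(
    "default",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def odor_protocol():
    """The six-concentration pulsed butanone protocol."""
    return synth.make_odor_protocol()


@pytest.fixture(scope="session")
def light_schedule():
    """Ten 20-s light pulses, two minutes apart."""
    return synth.make_light_schedule()


@pytest.fixture(scope="session")
def noiseless_params():
    return synth.AwcModelParams(noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_trace(noiseless_params, odor_protocol):
    return synth.simulate_awc_trace(noiseless_params, odor_protocol, conditioned=False)


def exp_recovery_trace(fs: float, tau: float, depth: float = 0.5, pulse=(30.0, 60.0), t_end: float = 300.0):
    """Synthetic normalized trace: baseline 1, step suppression during the
    pulse, exact exponential recovery afterwards.  Shared helper for the
    half-time oracle tests."""
    from wormlearn.types import FluorTrace

    t = np.arange(0.0, t_end, 1.0 / fs)
    f = np.ones_like(t)
    on, off = pulse
    f[(t >= on) & (t < off)] = 1.0 - depth
    rec = t >= off
    f[rec] = 1.0 - depth * np.exp(-(t[rec] - off) / tau)
    return FluorTrace(t=t, f=f, animal_id="oracle", norm_state="dffmax")
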