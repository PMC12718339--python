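import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import endurance_lab as el

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def clean_params():
    """Dopaminergic 0-glucose parameters with every stochastic term off."""
    return el.condition_presets("da_0gluc").replace(
        noise_sd=0.0,
        bleach_rate=0.0,
        store_jitter_sigma=0.0,
        gp_jitter_sigma=0.0,
        cost_jitter_sigma=0.0,
    )


@pytest.fixture
def quiet_params():
    """Default noise, but no per-neuron parameter jitter."""
    return el.condition_presets("da_0gluc").replace(
        store_jitter_sigma=0.0, gp_jitter_sigma=0.0, cost_jitter_sigma=0.0
    )


@pytest.fixture
def short_endurance_protocol(clean_params):
    return el.default_protocol(clean_params, "endurance", rounds=5)


def simulate_neuron(params, protocol, seed, **ph_kwargs):
    """One synthetic neuron: bioenergetic state + pHluorin trace."""
    ss = np.random.SeedSequence(seed)
    state = el.simulate_terminal_state(params, protocol, np.random.default_rng(ss))
    trace, gt = el.simulate_ph_trace(
        params, protocol, state, np.random.default_rng(ss.spawn(1)[0]), **ph_kwargs
    )
    return state, trace, gt


@pytest.fixture
def neuron_factory():
    return simulate_neuron
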