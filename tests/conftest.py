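import dataclasses

import pytest
from hypothesis import settings

from salibench.synthetic_data import preset

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def noiseless(params):
    """Copy of a generator parameter set with its noise switched off."""
    field = "baseline_noise_sd" if hasattr(params, "baseline_noise_sd") else "noise_cv"
    return dataclasses.replace(params, **{field: 0.0})


@pytest.fixture(scope="session")
def presets():
    return {name: preset(name) for name in ("liquid", "viscous_liquid", "gel", "saliva")}
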