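import numpy as np
import pytest

from patchkit.synthetic import (
    APWaveformSpec,
    PassiveCircuitSpec,
    make_step_protocol_sweeps,
)


@pytest.fixture(scope="session")
def default_ap():
    return APWaveformSpec()


@pytest.fixture(scope="session")
def default_circuit():
    return PassiveCircuitSpec()


@pytest.fixture(scope="session")
def step_protocol(default_ap, default_circuit):
    """Noise-free 16-step protocol with rheobase on the 160-pA step."""
    return make_step_protocol_sweeps(
        default_ap, default_circuit, rheobase_pA=160.0,
        gain_spikes_per_40pA=1.0, seed=42,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
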