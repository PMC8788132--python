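import numpy as np
import pytest

from ramplux import stimulus, synth


@pytest.fixture
def ramp10():
    """Standard 0.4–32 LUX ramp, 10 s legs, six cycles."""
    return stimulus.RampStimulus(min_lux=0.4, max_lux=32.0, ramp_s=10.0, n_cycles=6)


@pytest.fixture
def ramp30():
    return stimulus.RampStimulus(min_lux=0.4, max_lux=32.0, ramp_s=30.0, n_cycles=4)


@pytest.fixture
def noiseless():
    return synth.IndicatorSpec(noise_sd=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
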