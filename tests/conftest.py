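import pytest

from pufftopo import PROFILES, TopographyParams, generate_trace


@pytest.fixture(scope="session")
def mdph_single():
    """One noiseless MDPH puff at 1 kHz."""
    p = PROFILES["mdph"]
    params = TopographyParams(p.duration_s, p.volume_ml, p.max_flow_slpm,
                              p.interpuff_s, n_puffs=1)
    return params, generate_trace(params)


@pytest.fixture(scope="session")
def mdph_train():
    """Three noiseless MDPH puffs at 30-s spacing, 1 kHz."""
    params = PROFILES["mdph"]
    return params, generate_trace(params)


@pytest.fixture(scope="session")
def high_flow_train_short():
    """Three noiseless high-flow puffs at 5-s spacing (compact for playback)."""
    p = PROFILES["high_flow"]
    params = TopographyParams(p.duration_s, p.volume_ml, p.max_flow_slpm,
                              interpuff_s=5.0, n_puffs=3)
    return params, generate_trace(params)
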