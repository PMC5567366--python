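import pytest

from pulsecall import b_call_spec, power_spectrum, synthesize_train


@pytest.fixture(scope="session")
def fig4_spec():
    """Canonical B-call model: 14.73 Hz fundamental, 7 s, 2 kHz."""
    return b_call_spec()


@pytest.fixture(scope="session")
def fig4_waveform(fig4_spec):
    return synthesize_train(fig4_spec)


@pytest.fixture(scope="session")
def fig4_spectrum(fig4_waveform):
    return power_spectrum(fig4_waveform)
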