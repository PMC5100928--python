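import dataclasses

import pytest

from trpa1pore import synthgen


@pytest.fixture(scope="session")
def wt150():
    return synthgen.get_fixture("WT-150")


@pytest.fixture(scope="session")
def quiet_wt150(wt150):
    """WT-150 without leak or noise, for closed-form current checks."""
    return dataclasses.replace(wt150, leak_conductance_pS=0.0, noise_rms_pA=0.0)


@pytest.fixture(scope="session")
def hold_minus60():
    return synthgen.hold_protocol(-60.0, duration_s=0.5)
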