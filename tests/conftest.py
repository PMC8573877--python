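import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from psirsynth import (
    TissueRelaxation,
    TissueReference,
    default_msasha_protocol,
    make_t1mes_phantom,
    simulate_series,
)

# Post-contrast chronic-infarct group means (T1, T2) in ms.
CHRONIC = {
    "mi": TissueRelaxation(441.0, 43.8),
    "remote": TissueRelaxation(668.0, 42.4),
    "blood": TissueRelaxation(466.0, 142.4),
}


@pytest.fixture(scope="session")
def protocol():
    return default_msasha_protocol()


@pytest.fixture(scope="session")
def chronic_tissues():
    return CHRONIC


@pytest.fixture(scope="session")
def chronic_reference():
    return TissueReference.from_tissues(CHRONIC["remote"], CHRONIC["blood"], lgeb=-0.5)


@pytest.fixture(scope="session")
def t1mes_phantom():
    return make_t1mes_phantom()


@pytest.fixture(scope="session")
def noisefree_t1mes_series(t1mes_phantom, protocol):
    return simulate_series(t1mes_phantom, protocol, snr=np.inf)


def forward_signals(tissue, protocol, amplitude=1.0):
    """Independent forward model: evaluate each event's closed form directly."""
    sig = []
    for e in protocol.events:
        delay = e.recovery_beats * protocol.rr + e.ts if e.kind == "anchor" else e.ts
        s = amplitude * (1.0 - np.exp(-delay / tissue.t1))
        if e.te_prep:
            s *= np.exp(-e.te_prep / tissue.t2)
        sig.append(s)
    return np.array(sig)
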