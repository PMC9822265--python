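import numpy as np
import pytest

from ecphys.recordings import ProtocolKind, StimulusProtocol, Sweep
from ecphys.synth import MembraneParams, PSPComponent, SynapseParams


@pytest.fixture
def rc_membrane():
    """Passive membrane: Rin = 200 MOhm, tau = 20 ms."""
    return MembraneParams(C_pF=100.0, g_L_nS=5.0, a_nS=0.0, noise_sd_mV=0.0)


@pytest.fixture
def resonant_membrane():
    """Membrane with a resonance current: steady Rin = 100 MOhm."""
    return MembraneParams(
        C_pF=100.0, g_L_nS=5.0, a_nS=5.0, tau_w_ms=30.0, noise_sd_mV=0.0
    )


@pytest.fixture
def hyperpolarizing_step():
    return StimulusProtocol(
        kind=ProtocolKind.CURRENT_STEP,
        onset_ms=500.0,
        parameters={"amplitude_pA": -80.0, "duration_ms": 3000.0},
    )


@pytest.fixture
def opto_pulse():
    return StimulusProtocol(
        kind=ProtocolKind.OPTO_PULSE, onset_ms=520.0,
        parameters={"pulse_width_ms": 3.0},
    )


@pytest.fixture
def epsp_only():
    return SynapseParams(
        components={
            "epsp_fast": PSPComponent(
                amplitude_mV=5.0, rise_ms=0.6, decay_ms=8.0, latency_ms=2.0
            )
        }
    )


def make_sweep(voltage, time_step=0.05, current=None, protocol=None, **kw):
    voltage = np.asarray(voltage, dtype=float)
    if current is None:
        current = np.zeros_like(voltage)
    return Sweep(
        time_step=time_step,
        voltage=voltage,
        current=current,
        protocol=protocol or StimulusProtocol(),
        **kw,
    )
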