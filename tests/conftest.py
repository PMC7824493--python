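"""Shared fixtures: one supra-threshold and one unstimulated rendered scan.

Scans are rendered once per session from fixed seeds; every test that needs
a realistic M-mode image reuses them.
"""

from __future__ import annotations

import pytest

from mmode_tkeo import (
    StimProtocol,
    VirtualPatient,
    render_scan,
    trace_from_scan,
)


@pytest.fixture(scope="session")
def protocol() -> StimProtocol:
    """Standard stimulation sequence at the motor-threshold amplitude."""
    return StimProtocol(amplitude_mA=24.0)


@pytest.fixture(scope="session")
def patient() -> VirtualPatient:
    return VirtualPatient(mt_true_mA=23.5, st_true_mA=9.0)


@pytest.fixture(scope="session")
def supra_scan(patient, protocol):
    """Scan at an amplitude above the latent motor threshold."""
    return render_scan(patient, protocol, seed=7)


@pytest.fixture(scope="session")
def null_scan(patient, protocol):
    """Scan at a sub-threshold amplitude: speckle noise only."""
    return render_scan(patient, protocol.with_amplitude(8.0), seed=11)


@pytest.fixture(scope="session")
def supra_trace(supra_scan):
    return trace_from_scan(supra_scan)


@pytest.fixture(scope="session")
def null_trace(null_scan):
    return trace_from_scan(null_scan)
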