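"""Shared fixtures: small synthetic sessions and precomputed MODAL traces.

Everything is generated programmatically at test time with fixed seeds;
session-scoped fixtures cache the expensive wavelet/MODAL passes so several
test modules can share one pipeline run.
"""

from __future__ import annotations

import numpy as np
import pytest

from phasecode import detect_bad_epochs
from phasecode import synthetic as syn
from phasecode.modal import detect_oscillations

FS = 2000.0


@pytest.fixture(scope="session")
def theta_session():
    """120 s session: 3 Hz band (always on), one phase-locked unit."""
    spec = syn.SyntheticSpec(
        duration=120.0,
        fs=FS,
        seed=11,
        bands=[syn.BandSpec(f_center=3.0, f_halfwidth=0.5, amplitude=2.0, bout_duty_cycle=1.0)],
        units=[
            syn.UnitSpec(
                unit_id="locked",
                base_rate=5.0,
                kappa=4.0,
                preferred_phase_by_goal={g: np.pi / 2 for g in range(1, 7)},
            ),
            syn.UnitSpec(unit_id="null", base_rate=5.0, kappa=0.0),
        ],
    )
    session, gt = syn.generate_session(spec)
    return session, gt


@pytest.fixture(scope="session")
def theta_traces(theta_session):
    """Full MODAL output (mask + gated traces) for the theta session."""
    session, gt = theta_session
    lfp = session.channels[0]
    mask = detect_bad_epochs(lfp)
    traces = detect_oscillations(lfp, mask, band_range=(1.0, 10.0))
    assert traces, "expected at least one low-frequency band on the theta session"
    return mask, traces


@pytest.fixture(scope="session")
def coding_session():
    """600 s session with goal-dependent preferred phases (phase coding)."""
    mus = {g: (g - 1) * np.pi / 3 for g in range(1, 7)}  # 60 deg spacing
    spec = syn.SyntheticSpec(
        duration=600.0,
        fs=FS,
        seed=29,
        n_deliveries=73,
        bands=[syn.BandSpec(f_center=3.0, f_halfwidth=0.5, amplitude=2.0)],
        units=[
            syn.UnitSpec(unit_id="coder", base_rate=1.2, kappa=4.0, preferred_phase_by_goal=mus),
            syn.UnitSpec(unit_id="null", base_rate=1.2, kappa=0.0),
        ],
    )
    session, gt = syn.generate_session(spec)
    lfp = session.channels[0]
    mask = detect_bad_epochs(lfp)
    traces = detect_oscillations(lfp, mask, band_range=(1.0, 10.0))
    assert traces
    return session, gt, traces[0]
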