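"""Shared fixtures: small synthetic sessions and their calibrations."""

import numpy as np
import pytest

import octstitch as ox
from octstitch.forward_model import FLAT_ENVELOPE


@pytest.fixture(scope="session")
def calib_session():
    """Dual-laser mirror calibration session, default (ASE) conditions."""
    return ox.simulate_calibration_set(seed=11, n_depths=6,
                                       lateral_size=(2, 2))


@pytest.fixture(scope="session")
def system_calibration(calib_session):
    """Full calibration run on the default session."""
    return ox.calibrate_session(
        calib_session.raw,
        calib_session.lasers,
        depths_um=list(calib_session.truth["depths_um"]),
    )


@pytest.fixture(scope="session")
def flat_calib_session():
    """Flat-envelope noiseless calibration session (idealized)."""
    return ox.simulate_calibration_set(
        seed=7, n_depths=6, lateral_size=(1, 1), envelopes=FLAT_ENVELOPE,
        dc_level=0.0,
    )


@pytest.fixture(scope="session")
def flat_system_calibration(flat_calib_session):
    return ox.calibrate_session(
        flat_calib_session.raw,
        flat_calib_session.lasers,
        depths_um=list(flat_calib_session.truth["depths_um"]),
        correct_envelope=False,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
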