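"""Shared fixtures: small synthetic records and numerical-gradient helpers."""

from __future__ import annotations

import numpy as np
import pytest

import mlanet as m


def numeric_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function of an array."""
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    flat = x.ravel()
    gflat = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f(x)
        flat[i] = orig - eps
        fm = f(x)
        flat[i] = orig
        gflat[i] = (fp - fm) / (2 * eps)
    return g


@pytest.fixture(scope="session")
def clean_patient():
    return m.PatientProfile("p0", amplitude_gain=1.0, heart_rate=60.0,
                            noise_sd=0.0, wander_amp=0.0)


@pytest.fixture(scope="session")
def hc_profile():
    return m.class_profile("HC")


@pytest.fixture(scope="session")
def imi_profile():
    return m.class_profile("IMI", st_shift=0.3)


@pytest.fixture(scope="session")
def clean_record(clean_patient, hc_profile):
    """Noiseless 10-beat healthy record at 60 bpm."""
    return m.generate_record(clean_patient, hc_profile, n_beats=10, seed=7)
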