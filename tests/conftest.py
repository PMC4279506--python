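"""Shared fixtures: the default stack and reusable transport runs."""

from __future__ import annotations

import numpy as np
import pytest

from lumiderm import default_skin_stack, default_source, run_spectrum
from lumiderm.mc import RunSettings, run_single_wavelength


@pytest.fixture(scope="session")
def stack():
    return default_skin_stack()


@pytest.fixture(scope="session")
def source():
    return default_source()


@pytest.fixture(scope="session")
def small_run(stack):
    """Quick 850 nm run on a reduced radial grid (depth grid kept at 0.05 mm)."""
    settings = RunSettings(n_photons=20_000, seed=7, nr=220, nz=400)
    return run_single_wavelength(stack, settings, 850.0, incident_energy_J=10.0)


@pytest.fixture(scope="session")
def reference_spectral_run(stack, source):
    """Full five-wavelength spectral run at the standard ensemble size.

    10^5 photons per wavelength, flat 10 mm beam, 10 J incident: the
    configuration under which the headline absorbed-fraction and
    energy-versus-depth figures are quoted.
    """
    settings = RunSettings(n_photons=100_000, seed=1234)
    return run_spectrum(stack, source, settings, incident_energy_J=10.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20_259)
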