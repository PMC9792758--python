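"""Shared fixtures: canonical montage, simulated subjects, lead fields.

Simulation-backed fixtures are session-scoped; everything is generated at
test time from fixed seeds.
"""

from __future__ import annotations

import numpy as np
import pytest

from vepsource.localize import build_lead_field
from vepsource.montage import build_standard_montage
from vepsource.pipeline import preprocess_recording
from vepsource.simulate import NoiseModel, Paradigm, simulate_subject


@pytest.fixture(scope="session")
def montage():
    return build_standard_montage()


@pytest.fixture(scope="session")
def paradigm():
    return Paradigm()


@pytest.fixture(scope="session")
def rg_recording(paradigm):
    """One subject's RG-team continuous recording at default noise."""
    return simulate_subject(paradigm, "RG", seed=11)


@pytest.fixture(scope="session")
def rg_epochs(rg_recording):
    epochs, _ = preprocess_recording(rg_recording)
    return epochs


@pytest.fixture(scope="session")
def clean_rg_epochs(paradigm, montage):
    """Noise-free RG epochs: the pure forward-projected ERP signal."""
    rec = simulate_subject(paradigm, "RG", noise=NoiseModel().silent(),
                           montage=montage, seed=5)
    epochs, _ = preprocess_recording(rec)
    return epochs


@pytest.fixture(scope="session")
def lead_field(montage):
    """Coarse interior lead field (1.2 cm spacing) for inverse tests."""
    return build_lead_field(montage, spacing=0.012)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
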