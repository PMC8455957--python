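"""Shared fixtures: one synthetic genome and one calibrated profile per session."""

from __future__ import annotations

import numpy as np
import pytest

from hsp20pipe.config import SimulationParams
from hsp20pipe.profile_hmm import build_profile, calibrate
from hsp20pipe.simulate import default_seed_alignment, generate_family_genome


@pytest.fixture(scope="session")
def default_params() -> SimulationParams:
    return SimulationParams(seed=11)


@pytest.fixture(scope="session")
def sim(default_params):
    """Default synthetic genome (40 family genes, mutation rate 0.1)."""
    return generate_family_genome(default_params)


@pytest.fixture(scope="session")
def sim_zero_mutation():
    return generate_family_genome(SimulationParams(seed=11, domain_mutation_rate=0.0))


@pytest.fixture(scope="session")
def seed_alignment():
    return default_seed_alignment(length=90)


@pytest.fixture(scope="session")
def calibrated_profile(seed_alignment):
    profile = build_profile(seed_alignment)
    return calibrate(profile, np.random.default_rng(99), n_null=500)


@pytest.fixture(scope="session")
def well_calibrated_profile(seed_alignment):
    """Tighter null fit for the E-value calibration checks: at the tested
    thresholds the Poisson band presumes small fit error, so the fit uses
    2000 null scores."""
    profile = build_profile(seed_alignment)
    return calibrate(profile, np.random.default_rng(99), n_null=2000)
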