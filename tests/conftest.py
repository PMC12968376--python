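"""Shared fixtures: cohort-mean parameter sets and deterministic athletes."""

import numpy as np
import pytest

from sprintfatigue import (
    CrankGeometry,
    LinearFvProfile,
    PasaParams,
    PesaParams,
)
from sprintfatigue.synthetic import AthleteSpec, NoiseSpec, ProtocolSpec


@pytest.fixture(scope="session")
def geometry() -> CrankGeometry:
    return CrankGeometry(crank_length_m=0.17)


@pytest.fixture(scope="session")
def mean_profile() -> LinearFvProfile:
    """Cohort-mean fatigue-free linear F-v profile (Fmax 1207 N, a -4.53 N/rpm)."""
    return LinearFvProfile(slope_a=-4.53, fmax_N=1207.0)


@pytest.fixture(scope="session")
def mean_pasa(mean_profile) -> PasaParams:
    """Cohort-mean time-based decay: C_F 483 N, tau_F 38 s, TD 2.55 s."""
    return PasaParams(base=mean_profile, cf_N=483.0, tau_s=38.0, td_s=2.55)


@pytest.fixture(scope="session")
def mean_pesa() -> PesaParams:
    """Cohort-mean stroke-based decay: P_peak 1299 W, delta 1.45%, ND 5."""
    return PesaParams(peak_power_W=1299.0, delta=0.0145, nd_strokes=5)


@pytest.fixture(scope="session")
def mean_athlete(mean_profile, mean_pasa, mean_pesa, geometry) -> AthleteSpec:
    """Deterministic athlete built from the cohort means (not sampled)."""
    return AthleteSpec(
        fv=mean_profile, pasa=mean_pasa, pesa=mean_pesa, sex="all", geometry=geometry
    )


@pytest.fixture(scope="session")
def protocol() -> ProtocolSpec:
    return ProtocolSpec()


@pytest.fixture
def no_noise() -> NoiseSpec:
    return NoiseSpec(cv=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
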