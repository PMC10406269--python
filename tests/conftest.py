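"""Shared fixtures: phantom cases at several degradation levels.

The expensive artifacts (a full 12-case cohort run) are session-scoped so
every test that interrogates cohort-level behaviour shares one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from cedflow import PhantomSpec, RigidTransform, generate_case, generate_cohort
from cedflow.phantom import case_adc
from cedflow.pipeline import CaseInputs, run_cohort


@pytest.fixture(scope="session")
def ideal_case():
    """Noise-free, blur-free, identity-shift case: exact-recovery oracle."""
    spec = PhantomSpec(noise_sigma=0.0, pv_blur_sigma_vox=0.0, seed=11)
    return generate_case(spec)


@pytest.fixture(scope="session")
def noisefree_blurred_case():
    """Noise-free but with partial-volume blur: tests edge handling."""
    spec = PhantomSpec(noise_sigma=0.0, seed=12)
    return generate_case(spec)


@pytest.fixture(scope="session")
def noisy_shifted_case():
    """Default noise and blur plus a known rigid inter-session shift."""
    spec = PhantomSpec(
        seed=13,
        session_shift=RigidTransform([1.5, -2.0, 1.0], [3.0, -2.0, 1.5]),
    )
    return generate_case(spec)


@pytest.fixture(scope="session")
def phantom_cohort():
    """12 default-noise cases with random shifts, Vi in the infused range."""
    cases, truth_table = generate_cohort(12, seed=7)
    return cases, truth_table


@pytest.fixture(scope="session")
def cohort_run(phantom_cohort):
    """Full end-to-end pipeline over the 12-case cohort (shared, expensive)."""
    cases, _ = phantom_cohort
    inputs = [CaseInputs.from_phantom(c, case_id=i + 1) for i, c in enumerate(cases)]
    return run_cohort(inputs), cases


def adc_of(case, session):
    return case_adc(case, session)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())
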