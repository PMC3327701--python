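"""Shared fixtures: small synthetic cohorts and catalog access."""

import numpy as np
import pytest

from tlemorph import (
    CohortConfig,
    GroupSpec,
    default_catalog,
    generate_cohort,
    normalize_by_icv,
)
from tlemorph.synthetic import default_base_fractions


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def base_fractions(catalog):
    return default_base_fractions(catalog)


def make_two_group_cohort(
    base_fractions,
    n_patients=10,
    n_controls=10,
    effects=None,
    seed=0,
    noise_cv=0.08,
    patient_name="patient_L",
    control_name="control",
    normalized=True,
):
    """Two-group cohort: patients with optional planted effects vs controls."""
    groups = (
        GroupSpec(patient_name, n_patients, 1450.0, 150.0, dict(effects or {})),
        GroupSpec(control_name, n_controls, 1450.0, 150.0, {}),
    )
    cfg = CohortConfig(
        groups=groups, base_fractions=base_fractions, noise_cv=noise_cv, seed=seed
    )
    cohort = generate_cohort(cfg)
    return normalize_by_icv(cohort) if normalized else cohort


@pytest.fixture()
def planted_cohort(base_fractions):
    """Strong single-structure effect: left hippocampus reduced by 30%."""
    return make_two_group_cohort(
        base_fractions, effects={"Hippocampus_L": 0.30}, seed=11
    )


@pytest.fixture()
def null_cohort(base_fractions):
    """No planted effects; group labels are pure noise."""
    return make_two_group_cohort(
        base_fractions, patient_name="g1_L", control_name="g2_R", seed=23
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20121105)
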