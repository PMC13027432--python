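"""Shared fixtures: seeded synthetic cohorts reused across test modules."""

import pytest

from ptmatlas.pipeline import compute_metrics
from ptmatlas.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort200():
    """200-enzyme cohort with default planted structure."""
    return generate_cohort(SyntheticConfig(n_enzymes=200, seed=7))


@pytest.fixture(scope="session")
def metrics200(cohort200):
    return compute_metrics(cohort200)


@pytest.fixture(scope="session")
def full_scale_cohort():
    """Cohort at full catalog scale (771 enzymes, planted multiplier 3)."""
    return generate_cohort(SyntheticConfig(n_enzymes=771, seed=0))


@pytest.fixture(scope="session")
def full_scale_metrics(full_scale_cohort):
    return compute_metrics(full_scale_cohort)


@pytest.fixture
def sites_by_enzyme(cohort200):
    by = {acc: [] for acc in cohort200.enzymes}
    for s in cohort200.sites:
        by[s.accession].append(s)
    return by
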