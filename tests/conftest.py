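"""Shared fixtures: small synthetic cohorts and datasets, built per test."""

from __future__ import annotations

import pytest

from chemosig import synth
from chemosig.clinical import cohort_frame
from chemosig.studies import planted_features as make_planted_features  # noqa: F401


@pytest.fixture(scope="session")
def small_cohort():
    spec = synth.CohortSpec(n_resistant=10, n_sensitive=20, seed=101)
    return synth.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort_frame(small_cohort):
    return cohort_frame(small_cohort)


@pytest.fixture(scope="session")
def small_prm_table(small_cohort):
    spec = synth.PrmSimSpec(
        n_proteins=6,
        peptides_per_protein=2,
        signal_proteins=("PROT01",),
        seed=102,
    )
    return synth.generate_prm_dataset(small_cohort, spec)
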