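"""Shared fixtures: one synthetic cohort and the reference objects built from it.

Heavy objects (the cohort, the score table, the full repeated cross-
validations) are session-scoped so the acceptance tests and the unit tests
share a single computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import fragmrd as fm


@pytest.fixture(scope="session")
def cohort() -> fm.SyntheticCohort:
    """36-patient / 14-recurrence cohort under the default study conditions."""
    return fm.sample_cohort(fm.SyntheticCohortConfig(seed=11))


@pytest.fixture(scope="session")
def pooled_nonmalignant(cohort) -> fm.FragmentPool:
    return fm.pooled_controls(cohort.controls)


@pytest.fixture(scope="session")
def ref_table(cohort, pooled_nonmalignant) -> fm.FragmentScoreTable:
    """Score table from the cohort's tumour-tagged fragments vs pooled controls."""
    tumour = fm.merge_pools(
        [p.tumour_fragments for p in cohort.patients], "cohort.tumour", "tumour_reference"
    )
    return fm.build_score_table(tumour, pooled_nonmalignant, n_boot=200, seed=1)


@pytest.fixture(scope="session")
def recurrence(cohort) -> np.ndarray:
    return np.array([p.recurrence for p in cohort.patients])


@pytest.fixture(scope="session")
def cv_intact(cohort) -> fm.CVResult:
    """Full 20x10 repeated cross-validation on the default cohort."""
    return fm.run_ttfcv(
        cohort.patients, cohort.controls, n_repeats=20, n_folds=10, seed=0, n_boot=100
    )


@pytest.fixture(scope="session")
def cv_shuffled(cohort) -> fm.CVResult:
    """Same cross-validation with patient-level FS assignments permuted."""
    overrides = fm.shuffle_fs_control(cohort.patients, seed=5)
    return fm.run_ttfcv(
        cohort.patients, cohort.controls, n_repeats=20, n_folds=10, seed=0,
        n_boot=100, fs_overrides=overrides,
    )
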