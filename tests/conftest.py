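"""Shared fixtures: small synthetic cohorts and fitted models.

Session-scoped so expensive fits are shared across test modules.
"""

import numpy as np
import pandas as pd
import pytest

from lpai import (
    LongitudinalAgingIndex,
    SimulationConfig,
    SparseFPCA,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """250 subjects x 8 proteins, 3 informative; ARIC-like design."""
    cfg = SimulationConfig(n_subjects=250, n_proteins=8, n_informative=3,
                           seed=101)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def medium_cohort():
    """600 subjects x 4 proteins for FPCA recovery checks."""
    cfg = SimulationConfig(n_subjects=600, n_proteins=4, n_informative=2,
                           seed=202)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def fitted_fpca(medium_cohort):
    """One protein's PACE fit plus its training scores."""
    pid = medium_cohort.dataset.proteins[0]
    frame = medium_cohort.dataset.protein_frame(pid)
    model = SparseFPCA()
    scores = model.fit_transform(frame)
    return pid, model, scores


@pytest.fixture(scope="session")
def fitted_lpai(small_cohort):
    """Index trained on the small cohort (5 CV folds for speed)."""
    model = LongitudinalAgingIndex(cv_folds=5, random_state=7)
    model.fit(small_cohort.dataset, small_cohort.survival)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_survival_frame(subjects, time, event, cause=None):
    """Helper for building SurvivalTable input frames in tests."""
    if cause is None:
        cause = np.where(np.asarray(event) == 1, "cvd", "none")
    return pd.DataFrame(
        {"subject_id": list(subjects), "time": time, "event": event,
         "cause": cause}
    )
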