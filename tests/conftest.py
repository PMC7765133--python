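import warnings

import numpy as np
import pytest

from somnofuse.synth import CohortSpec, iter_subjects


@pytest.fixture(autouse=True)
def _quiet():
    """FastICA convergence chatter and short-segment warnings are expected
    on synthetic fixtures; keep test output readable."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def default_subject():
    """One fully contaminated subject of the default desk-scale cohort."""
    return next(iter_subjects(CohortSpec(seed=3)))


@pytest.fixture(scope="session")
def light_subject():
    """A subject without EEG synthesis (events + BOLD + ground truth)."""
    return next(iter_subjects(CohortSpec(seed=9), with_eeg=False))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
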