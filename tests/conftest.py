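import numpy as np
import pytest

from neuralhypernet.preprocess import AugmentedIncidence
from neuralhypernet.synth import SyntheticConfig, generate_cohort


def make_incidence(matrix, descriptors=None, labels=None):
    """Build an AugmentedIncidence from a plain 0/1 array."""
    matrix = np.asarray(matrix, dtype=bool)
    n, m = matrix.shape
    if descriptors is None:
        descriptors = [f"d{j}" for j in range(m)]
    return AugmentedIncidence(
        patients=[f"p{i}" for i in range(n)],
        descriptors=list(descriptors),
        matrix=matrix,
        labels=np.full(n, np.nan) if labels is None else np.asarray(labels, dtype=float),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 150-patient cohort under the default study conditions."""
    return generate_cohort(SyntheticConfig(n_patients=150, seed=11))


@pytest.fixture(scope="session")
def clean_cohort():
    """A 60-patient cohort with no missing entries."""
    return generate_cohort(SyntheticConfig(n_patients=60, missing_rates={}, seed=5))
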