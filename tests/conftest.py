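import numpy as np
import pytest

from signedfcn import (
    PlantedPartitionSpec,
    generate_cohort,
    mean_fc,
    subject_fc,
)


@pytest.fixture(scope="session")
def default_spec():
    """The default study conditions: 40 subjects x 165 timepoints x 36 ROIs."""
    return PlantedPartitionSpec(seed=1)


@pytest.fixture(scope="session")
def default_cohort(default_spec):
    return generate_cohort(default_spec)


@pytest.fixture(scope="session")
def default_fcs(default_cohort):
    return [subject_fc(ts) for ts in default_cohort]


@pytest.fixture(scope="session")
def default_mean_fc(default_fcs):
    mean, sd = mean_fc(default_fcs)
    return mean


@pytest.fixture(scope="session")
def small_spec():
    """A cheap three-module cohort for pipeline-level tests."""
    return PlantedPartitionSpec(
        n_nodes=12,
        module_sizes=(4, 4, 4),
        anti_pairs=((1, 3),),
        n_timepoints=60,
        n_subjects=6,
        seed=11,
    )


def random_signed_network(rng, n, low=-0.5, high=1.0):
    w = rng.uniform(low, high, size=(n, n))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return w
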