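import numpy as np
import pandas as pd
import pytest

from krassubtype import synthetic


@pytest.fixture(scope="session")
def centroids():
    return synthetic.generate_centroid_set(n_genes=384, n_marker_per_subtype=128,
                                           marker_effect=2.0, seed=42)


@pytest.fixture(scope="session")
def small_centroids():
    """Cheap 60-gene panel for fast classifier tests."""
    return synthetic.generate_centroid_set(n_genes=60, n_marker_per_subtype=20,
                                           marker_effect=2.0, seed=7)


@pytest.fixture(scope="session")
def reference_set(small_centroids):
    return synthetic.generate_reference_labeled_set(
        small_centroids, n_per_subtype=23, noise_sd=0.4, seed=11
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def trial_cohort(centroids):
    spec = synthetic.CohortSpec(seed=3, unclassifiable_fraction=0.2, n_outliers=0)
    return synthetic.simulate_trial(spec, centroids)
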