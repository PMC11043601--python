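import numpy as np
import pytest
from hypothesis import settings

import specres

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_panel():
    """A 12-enzyme, 40-column panel with 4 planted determinant positions."""
    return specres.generate_panel(
        n_enzymes=12,
        n_positions=40,
        n_polymorphic=20,
        n_planted=4,
        n_classes=3,
        noise_sd=1.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_clusters(small_panel):
    panel, _ = small_panel
    scaled = specres.normalize_profiles(panel)
    return specres.cluster_enzymes(scaled, min_cluster_size=3)


@pytest.fixture(scope="session")
def small_pairs(small_panel, small_clusters):
    panel, _ = small_panel
    return specres.build_dataset(panel, small_clusters, control_seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
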