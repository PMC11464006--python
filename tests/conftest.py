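import numpy as np
import pytest

import atacdeconv as ad


@pytest.fixture(scope="session")
def default_truth():
    """Ground truth at default study conditions (5 types x 3 studies x 4 samples)."""
    return ad.simulate_reference_truth(ad.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def sorted_counts(default_truth):
    return ad.simulate_sorted_samples(default_truth)


@pytest.fixture(scope="session")
def discovered_markers(default_truth, sorted_counts):
    """Marker discovery (no module filter / pruning) shared across tests."""
    return ad.run_marker_discovery(
        sorted_counts,
        reference_cell_types=default_truth.cell_types,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
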