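import numpy as np
import pytest

from stratgraph.actions import CompatibilityMatrix
from stratgraph.cohort import CohortSpec, ModalitySpec, generate_cohort


@pytest.fixture(scope="session")
def small_modalities():
    """Down-scaled modality registry for fast unit tests."""
    return (
        ModalitySpec("vitals", 12, "per-step", "zscore"),
        ModalitySpec("labs", 8, "irregular", "minmax"),
        ModalitySpec("imaging", 16, "per-step", "none"),
        ModalitySpec("text", 24, "irregular", "none"),
    )


@pytest.fixture(scope="session")
def small_cohort(small_modalities):
    spec = CohortSpec(n_patients=60, n_steps=8, modalities=small_modalities,
                      n_clusters=4, cluster_signal=2.0, seed=11)
    return generate_cohort(spec, CompatibilityMatrix.fully_compatible())


@pytest.fixture
def rng():
    return np.random.default_rng(42)
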