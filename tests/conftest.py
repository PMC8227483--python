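import numpy as np
import pytest

from perfdose import synthetic_data as sd


@pytest.fixture(scope="session")
def noise_free_spec():
    return sd.SyntheticPhantomSpec(noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def patient_case(noise_free_spec):
    """Noise-free synthetic thorax volume with ground-truth labels."""
    hu, truth = sd.make_patient_volume(noise_free_spec)
    return hu, truth


@pytest.fixture(scope="session")
def reference_phantom():
    labels, tissue_map = sd.make_reference_phantom()
    return labels, tissue_map


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
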