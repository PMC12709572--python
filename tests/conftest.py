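"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

from photoxkit.parafac import EEMCube
from photoxkit.synthio import SynthConfig, gen_component_library, gen_dataset, gen_eem


@pytest.fixture(scope="session")
def library():
    return gen_component_library()


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Default study conditions: 2 series x (bulk + 6 MW fractions), no noise."""
    return gen_dataset(SynthConfig(), seed=1)


@pytest.fixture(scope="session")
def cube20(library):
    """Noiseless 20-sample six-component cube with known scores."""
    rng = np.random.default_rng(7)
    scores = rng.uniform(5.0, 100.0, size=(20, 6))
    eems = {f"S{i:02d}": gen_eem(scores[i], library) for i in range(20)}
    return EEMCube.from_eems(eems), scores
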