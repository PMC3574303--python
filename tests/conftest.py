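import numpy as np
import pytest

from streakmvpa.synthetic_data import EncodingParams, SessionDesign, generate_session


@pytest.fixture(scope="session")
def default_design() -> SessionDesign:
    return SessionDesign()


@pytest.fixture(scope="session")
def small_session():
    """A small, fast synthetic session shared across read-only tests."""
    params = EncodingParams(n_voxels_per_roi=20)
    return generate_session(params, SessionDesign(), participant_seed=11, participant="sub-01")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
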