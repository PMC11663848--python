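import numpy as np
import pytest

from duoscope.optics import OpticsParams, SceneSpec


@pytest.fixture(scope="session")
def optics() -> OpticsParams:
    """Default (paper-scale) ground-truth optics."""
    return OpticsParams()


@pytest.fixture(scope="session")
def flat_optics() -> OpticsParams:
    """Aberration-free configuration: flat field, no distortion/chroma."""
    return OpticsParams().identity()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scene() -> SceneSpec:
    """A light scene for fast unit tests of the session pipeline."""
    return SceneSpec(n_neurons_green=25, n_neurons_red=10, overlap_fraction=0.8)
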