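import numpy as np
import pytest

from dwiclust.normative import build_normative_map
from dwiclust.synthetic import SyntheticConfig, generate_controls, make_analysis_mask
from dwiclust.volume_io import BinaryMask, VolumeGrid


@pytest.fixture
def grid16() -> VolumeGrid:
    return VolumeGrid((16, 16, 16), np.diag([2.0, 2.0, 2.0, 1.0]))


@pytest.fixture
def full_mask16(grid16) -> BinaryMask:
    return BinaryMask(grid16, np.ones(grid16.shape, bool))


@pytest.fixture(scope="session")
def synth_config() -> SyntheticConfig:
    """The generator at its default study conditions (32^3, 30 controls)."""
    return SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def analysis_mask(synth_config) -> BinaryMask:
    return make_analysis_mask(synth_config)


@pytest.fixture(scope="session")
def controls(synth_config):
    return generate_controls(synth_config)


@pytest.fixture(scope="session")
def normative(controls, analysis_mask):
    return build_normative_map(controls, analysis_mask)
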