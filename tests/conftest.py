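import numpy as np
import pytest

from girthkit import synthpig
from girthkit.types import PipelineConfig


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig(seed=7)


@pytest.fixture(scope="session")
def pig() -> synthpig.LabeledCloud:
    """One default synthetic pig, shared across tests."""
    return synthpig.make_pig(synthpig.PigSpec(seed=1))


@pytest.fixture(scope="session")
def scan(pig) -> synthpig.TwoViewScan:
    """Two-view scan of the shared pig at the default noise level."""
    return synthpig.render_two_views(pig, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
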