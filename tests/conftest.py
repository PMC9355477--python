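import numpy as np
import pytest

from swirpupil.config import GeneratorConfig, PipelineConfig
from swirpupil.types import PupilTrace


@pytest.fixture
def pipe_cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def gen_cfg() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def make_trace(values, valid=None, rate=1200.0, eye="right", t0=0.0) -> PupilTrace:
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones(len(values), dtype=bool)
    return PupilTrace(diameter=values, valid=np.asarray(valid, dtype=bool),
                      sample_rate=rate, t0_s=t0, eye=eye)


@pytest.fixture
def small_pipe_cfg() -> PipelineConfig:
    """A shortened session (4 blocks) for trace-level end-to-end tests."""
    return PipelineConfig(n_blocks=4)
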