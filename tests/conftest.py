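import numpy as np
import pytest

from chronolfp.datatypes import RawTrace, RecordingMeta
from chronolfp.synthetic import preset_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def meta():
    return RecordingMeta(animal_id="W1", genotype="wildtype", region="SCN",
                         regimen="LD", fs=500.0)


@pytest.fixture
def tone_trace(meta):
    """10 s of a unit 10-Hz sine at 500 Hz."""
    t = np.arange(int(10 * meta.fs)) / meta.fs
    return RawTrace(meta=meta, samples=np.sin(2 * np.pi * 10.0 * t))


@pytest.fixture
def noise_trace(meta, rng):
    return RawTrace(meta=meta, samples=rng.standard_normal(int(60 * meta.fs)) * 0.1)


@pytest.fixture
def wt_ld_config():
    return preset_config("wildtype", "LD")
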