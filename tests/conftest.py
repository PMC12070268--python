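import numpy as np
import pytest

from eegbind import clusterperm, synthgen


@pytest.fixture(scope="session")
def array32() -> synthgen.SensorArray:
    return synthgen.make_sensor_array(32)


@pytest.fixture(scope="session")
def adjacency32(array32) -> clusterperm.Adjacency:
    return clusterperm.sensor_adjacency(array32)


@pytest.fixture(scope="session")
def source_model10(array32) -> synthgen.SourceModel:
    """Desk-scale toy source model: 10 mm grid."""
    return synthgen.make_source_model(10.0, array32)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
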