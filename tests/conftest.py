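import warnings

import numpy as np
import pytest

from avpconn.config import PipelineConfig, SynthConfig
from avpconn.pipeline import analyze
from avpconn.synth import generate_connectome


@pytest.fixture(scope="session")
def default_connectome():
    """The default synthetic connectome (ten subtypes, fifty neurons each)."""
    return generate_connectome(SynthConfig())


@pytest.fixture(scope="session")
def default_analysis(default_connectome):
    synapses, annotations, hulls, _ = default_connectome
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analyze(synapses, annotations, hulls, PipelineConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
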