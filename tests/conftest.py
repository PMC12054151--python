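import numpy as np
import pandas as pd
import pytest

from oralmpg.coverage import DepthProfile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_summary():
    """Three genomes in two samples with mixed detection."""
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s1", "s1", "s2", "s2", "s2"],
            "genome_id": ["A", "B", "C", "A", "B", "C"],
            "q2q3_mean_depth": [6.0, 2.0, 10.0, 0.0, 0.0, 0.0],
            "breadth": [0.9, 0.8, 0.3, 0.1, 0.0, 0.2],
            "detected": [True, True, False, False, False, False],
        }
    )


@pytest.fixture
def profile_factory():
    def make(depths, genome="g1", sample="s1"):
        return DepthProfile(genome, sample, np.asarray(depths))

    return make
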