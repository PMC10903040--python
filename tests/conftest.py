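import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from hormonet import aaprops, synthgen


@pytest.fixture(scope="session")
def prop_table():
    return aaprops.default_property_table()


@pytest.fixture(scope="session")
def random_sequences():
    """Ten seeded random protein sequences, length 50-200."""
    cfg = synthgen.SynthConfig(seed=42, seq_length=(50, 200))
    return synthgen.gen_sequences(10, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
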