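import numpy as np
import pytest
from hypothesis import settings

from vascde.synthetic import generate_transcriptome

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_ts():
    """12 transcripts of 300-600 bp with two engineered 80-bp shared segments."""
    return generate_transcriptome(
        12, (300, 600), {"n_pairs": 2, "segment_len": 80}, seed=11
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)
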