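import numpy as np
import pytest

import editscan as es


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture(scope="session")
def amplicon():
    """A 200 bp amplicon with the cut site at position 100."""
    return es.gen_amplicon(200, seed=42), 100


@pytest.fixture(scope="session")
def amplicon_ref(amplicon):
    seq, cut = amplicon
    return es.AmpliconRef(seq, cut)
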