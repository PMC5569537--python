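import random

import pytest

from bpalign import ScoringScheme


@pytest.fixture
def scheme():
    """The default scoring scheme (1, -1, -2), W=1."""
    return ScoringScheme(1, -1, -2)


@pytest.fixture
def rng():
    return random.Random(1730)
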