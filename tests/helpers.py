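"""Shared test helpers."""

import warnings

from bpalign import ScoringScheme
from bpalign.scoring import ScoringWarning


def grid_scheme(rng):
    """A random scoring scheme drawn from the parameter-scan grid."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ScoringWarning)
        return ScoringScheme(
            rng.choice([1, 2, 3]),
            rng.choice([-1, -2, -3]),
            rng.choice([-1, -2, -3]),
            sop_weight=rng.choice([1, 2, 3]),
        )
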