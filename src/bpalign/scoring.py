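"""Scoring model for the partially local three-way breakpoint alignment.

The alignment scores columns with a pairwise similarity ``sigma`` over the
nucleotide alphabet plus the gap character, and a three-way score ``gamma``
defined as the sum of the three pairwise scores, divided by the sum-of-pairs
weight ``W`` when all three symbols are letters.  ``W`` tunes the relative
weight of the overlap region (where F, L and R are all aligned) against the
flanking regions where only one query is present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
AMBIGUOUS = "N"
LETTERS = ALPHABET + AMBIGUOUS
GAP = "-"

#: integer codes used by the DP kernels; N is 4
_CODE = {c: i for i, c in enumerate(LETTERS)}

# IUPAC one-letter ambiguity codes that are normalized to N on input
IUPAC_EXTRA = set("RYSWKMBDHVU")


class ScoringWarning(UserWarning):
    """Raised for legal but inadvisable scoring schemes."""


@dataclass(frozen=True)
class NucSeq:
    """A named nucleotide sequence over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq) - set(LETTERS)
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains symbols outside "
                f"{{A,C,G,T,N}}: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def __str__(self) -> str:
        return self.seq


@dataclass(frozen=True)
class ScoringScheme:
    """Pairwise scores (match, mismatch, gap), edge gap score g, and weight W.

    Parameters
    ----------
    match : float
        Score alpha for identical letters; must be positive.
    mismatch : float
        Score beta for differing letters (N mismatches everything, including
        N itself); must be negative.
    gap : float
        Score delta for a letter aligned to a gap; must be negative.
    edge_gap : float, optional
        Uniform gap score g used on the initialization edges of the DP
        tensor.  Defaults to ``gap``.
    sop_weight : float
        Sum-of-pairs weight W >= 1 dividing all-letter three-way columns.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0
    edge_gap: float | None = None
    sop_weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.match > 0:
            raise ValueError(f"match score must be positive, got {self.match}")
        if not self.mismatch < 0:
            raise ValueError(f"mismatch score must be negative, got {self.mismatch}")
        if not self.gap < 0:
            raise ValueError(f"gap score must be negative, got {self.gap}")
        if self.sop_weight < 1:
            raise ValueError(f"sum-of-pairs weight must be >= 1, got {self.sop_weight}")
        if self.edge_gap is None:
            object.__setattr__(self, "edge_gap", self.gap)
        if not self.mismatch > self.gap:
            warnings.warn(
                f"mismatch score ({self.mismatch}) should be larger than the "
                f"gap score ({self.gap}) to avoid spurious indel pairs",
                ScoringWarning,
                stacklevel=2,
            )

    @property
    def g(self) -> float:
        """The uniform edge gap score."""
        return self.edge_gap  # type: ignore[return-value]

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.match, self.mismatch, self.gap)


def _check_symbol(a: str) -> None:
    if a != GAP and a not in _CODE:
        raise ValueError(f"unknown symbol {a!r}; expected one of A,C,G,T,N or '-'")


def sigma(a: str, b: str, scheme: ScoringScheme) -> float:
    """Pairwise score of two symbols (letters or gaps).

    Two gaps score 0, a letter against a gap scores delta, identical letters
    score alpha, and differing letters score beta.  The ambiguity letter N
    scores as a mismatch against every letter and against N.
    """
    _check_symbol(a)
    _check_symbol(b)
    if a == GAP and b == GAP:
        return 0.0
    if a == GAP or b == GAP:
        return scheme.gap
    if a == b and a != AMBIGUOUS:
        return scheme.match
    return scheme.mismatch


def gamma(a: str, b: str, c: str, scheme: ScoringScheme) -> float:
    """Three-way sum-of-pairs column score.

    The sum of the three pairwise sigma values, divided by W when all three
    symbols are letters and by 1 otherwise.  An all-gap column is invalid.
    """
    if a == GAP and b == GAP and c == GAP:
        raise ValueError("a column of three gaps can never occur in an alignment")
    s = sigma(a, b, scheme) + sigma(a, c, scheme) + sigma(b, c, scheme)
    if a != GAP and b != GAP and c != GAP:
        return s / scheme.sop_weight
    return s


def encode(seq: str | NucSeq) -> np.ndarray:
    """Encode a sequence as int8 codes (A=0, C=1, G=2, T=3, N=4)."""
    s = str(seq)
    return np.fromiter((_CODE[c] for c in s), dtype=np.int8, count=len(s))


def pair_score_matrix(scheme: ScoringScheme) -> np.ndarray:
    """5x5 letter-vs-letter sigma matrix for the encoded alphabet."""
    mat = np.full((5, 5), scheme.mismatch, dtype=np.float64)
    for i in range(4):
        mat[i, i] = scheme.match
    # N (code 4) mismatches everything including itself: already beta
    return mat
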