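"""Overlap / gap statistic of a breakpoint alignment.

The overlap is the number of alignment columns from the first to the last
column at which F, L and R are all aligned (intervening columns count even
if one row is gapped).  If no such column exists and the aligned part of R
starts in F more than one position after the aligned part of L ends, the
geometry is a gap whose length is the number of reference nucleotides
between the two that are aligned to neither fragment.  Otherwise L and R
abut flush on F.
"""

from __future__ import annotations

from dataclasses import dataclass

from .engine import TriAlignment
from .scoring import GAP


@dataclass(frozen=True)
class BreakpointGeometry:
    """The measured relation of L and R on the reference F.

    ``signed_value`` is +length for an overlap, -length for a gap and 0 for
    a flush junction.  ``degenerate`` flags alignments in which one of the
    fragments has no aligned column at all, so the geometry is undefined.
    """

    kind: str  # "overlap" | "gap" | "flush"
    length: int
    signed_value: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        assert self.kind in ("overlap", "gap", "flush")
        assert (self.kind == "flush") == (self.length == 0)
        expect = self.length if self.kind == "overlap" else -self.length
        assert self.signed_value == expect


def measure_overlap(aln: TriAlignment) -> BreakpointGeometry:
    """Measure the breakpoint geometry of an alignment."""
    cols = aln.columns
    triple = [
        idx
        for idx, c in enumerate(cols)
        if c.f != GAP and c.l != GAP and c.r != GAP
    ]
    if triple:
        length = triple[-1] - triple[0] + 1
        return BreakpointGeometry("overlap", length, length)
    l_end = aln.l_end_in_F
    r_start = aln.r_start_in_F
    if l_end == 0 or r_start == 0:
        # one fragment never pairs with the reference: undefined geometry
        return BreakpointGeometry("flush", 0, 0, degenerate=True)
    if r_start > l_end + 1:
        length = sum(
            1
            for c in cols
            if c.f != GAP
            and l_end < c.f_pos < r_start
            and c.l == GAP
            and c.r == GAP
        )
        if length > 0:
            return BreakpointGeometry("gap", length, -length)
    return BreakpointGeometry("flush", 0, 0)
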