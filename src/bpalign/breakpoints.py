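"""Breakpoint detection from signed gene orders and (F, L, R) extraction.

A breakpoint is a gene adjacency of the reference order that is absent from
the derived order (in either orientation-consistent reading).  For each
breakpoint, the reference region F is the genomic forward-strand window
spanning the last ``flank`` nucleotides of the left gene, the intergenic
region if any, and the first ``flank`` nucleotides of the right gene.  The
left query L is the end of the left gene plus its following intergenic
region in the derived genome; the right query R is the intergenic region
preceding the right gene plus the start of that gene.  For a gene whose
orientation flipped relative to the reference, the neighbor direction is
mirrored and the extracted query is reverse-complemented before alignment.

Coordinates are 1-based inclusive at every interface; features and
extraction windows may wrap the origin of a circular genome.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .engine import align
from .scoring import GAP, NucSeq, ScoringScheme

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated gene: 1-based inclusive coordinates, strand + or -.

    ``start > end`` denotes a feature wrapping the origin of a circular
    genome.
    """

    gene: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise ValueError(f"coordinates are 1-based; got {self.start}..{self.end}")

    def length(self, genome_length: int) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        return genome_length - self.start + 1 + self.end


@dataclass(frozen=True)
class Breakpoint:
    """A reference gene adjacency broken in the derived order."""

    left_gene: str
    right_gene: str
    left_flipped: bool = False
    right_flipped: bool = False
    rearrangement_hint: str | None = None


@dataclass
class BreakpointRegion:
    """An extracted (F, L, R) triple with provenance and exclusion status."""

    F: NucSeq
    L: NucSeq
    R: NucSeq
    breakpoint: Breakpoint
    provenance: dict = field(default_factory=dict)
    exclusion: str | None = None


# ---------------------------------------------------------------------------
# signed gene orders


def parse_signed(token: str) -> tuple[str, int]:
    """Split a signed gene token into (name, sign)."""
    if token.startswith("-"):
        return token[1:], -1
    if token.startswith("+"):
        return token[1:], 1
    return token, 1


def _signed_list(order: list[str]) -> list[tuple[str, int]]:
    genes = [parse_signed(t) for t in order]
    names = [g for g, _ in genes]
    if len(set(names)) != len(names):
        raise ValueError("gene orders with duplicate gene names are not supported")
    return genes


def _adjacencies(genes: list[tuple[str, int]], circular: bool) -> set:
    pairs = set(zip(genes, genes[1:]))
    if circular and len(genes) > 1:
        pairs.add((genes[-1], genes[0]))
    return pairs


def find_breakpoints(
    ref_order: list[str],
    derived_order: list[str],
    circular: bool = True,
    ignore: tuple[str, ...] = (),
) -> list[Breakpoint]:
    """Reference adjacencies absent from the derived order.

    A signed adjacency (a, b) counts as conserved if the derived order
    contains (a, b) or its mirror (-b, -a) consecutively (wrapping the ends
    when circular).  Flip flags record whether each gene's sign differs
    between the two orders.
    """
    ref = [g for g in _signed_list(ref_order) if g[0] not in ignore]
    der = [g for g in _signed_list(derived_order) if g[0] not in ignore]
    if {g for g, _ in ref} != {g for g, _ in der}:
        raise ValueError("reference and derived orders are over different gene sets")
    der_sign = {g: s for g, s in der}
    der_adj = _adjacencies(der, circular)
    out = []
    ref_adj = list(zip(ref, ref[1:]))
    if circular and len(ref) > 1:
        ref_adj.append((ref[-1], ref[0]))
    for (a, sa), (b, sb) in ref_adj:
        fwd = ((a, sa), (b, sb)) in der_adj
        rev = ((b, -sb), (a, -sa)) in der_adj
        if not (fwd or rev):
            out.append(
                Breakpoint(
                    left_gene=a,
                    right_gene=b,
                    left_flipped=der_sign[a] != sa,
                    right_flipped=der_sign[b] != sb,
                )
            )
    return out


def order_from_annotations(annotations: list[GeneAnnotation]) -> list[str]:
    """Signed gene order read off a genome annotation (sorted by start)."""
    anns = sorted(annotations, key=lambda a: a.start)
    return [("-" if a.strand == "-" else "") + a.gene for a in anns]


# ---------------------------------------------------------------------------
# sequence extraction


def reverse_complement(s: NucSeq | str) -> NucSeq | str:
    """Watson-Crick reverse complement; N maps to N."""
    if isinstance(s, NucSeq):
        return NucSeq(s.id, s.seq.translate(_COMPLEMENT)[::-1])
    return s.translate(_COMPLEMENT)[::-1]


def _window(genome: str, start: int, end: int, circular: bool) -> str:
    """Forward-strand window, 1-based inclusive, possibly wrapping the origin."""
    glen = len(genome)
    start = (start - 1) % glen + 1
    end = (end - 1) % glen + 1
    if start <= end:
        return genome[start - 1 : end]
    if not circular:
        raise ValueError(f"window {start}..{end} wraps the origin of a linear genome")
    return genome[start - 1 :] + genome[:end]


def _find_ann(annotations: list[GeneAnnotation], gene: str) -> GeneAnnotation:
    for a in annotations:
        if a.gene == gene:
            return a
    raise ValueError(f"gene {gene!r} is not annotated")


def _sorted_anns(annotations: list[GeneAnnotation]) -> list[GeneAnnotation]:
    return sorted(annotations, key=lambda a: a.start)


def _neighbors(
    annotations: list[GeneAnnotation], gene: str, circular: bool
) -> tuple[GeneAnnotation | None, GeneAnnotation, GeneAnnotation | None]:
    """(previous, this, next) annotation in genomic order, wrapping if circular."""
    anns = _sorted_anns(annotations)
    idx = next(i for i, a in enumerate(anns) if a.gene == gene)
    prev_a = anns[idx - 1] if (idx > 0 or circular) else None
    next_a = anns[(idx + 1) % len(anns)] if (idx + 1 < len(anns) or circular) else None
    return prev_a, anns[idx], next_a


def extract_reference(
    genome: NucSeq,
    annotations: list[GeneAnnotation],
    bp: Breakpoint,
    flank: int = 60,
    circular: bool = True,
) -> NucSeq:
    """The reference breakpoint region F.

    The forward-strand window from (end of left gene - flank + 1) to
    (start of right gene + flank - 1); flanks are clamped to the gene
    lengths, and the window wraps the origin of a circular genome.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    left = _find_ann(annotations, bp.left_gene)
    right = _find_ann(annotations, bp.right_gene)
    _, _, nxt = _neighbors(annotations, bp.left_gene, circular)
    if nxt is None or nxt.gene != bp.right_gene:
        raise ValueError(
            f"genes {bp.left_gene!r} and {bp.right_gene!r} are not adjacent "
            f"in the reference annotation"
        )
    glen = len(genome)
    fl = min(flank, left.length(glen))
    fr = min(flank, right.length(glen))
    start = left.end - fl + 1
    end = right.start + fr - 1
    seq = _window(genome.seq, start, end, circular)
    return NucSeq(f"F|{bp.left_gene}|{bp.right_gene}", seq)


def _query_window(
    genome: NucSeq,
    annotations: list[GeneAnnotation],
    gene: str,
    flank: int,
    side: str,  # "L" (gene end + following intergenic) or "R" (preceding intergenic + gene start)
    flipped: bool,
    circular: bool,
) -> NucSeq:
    glen = len(genome)
    prev_a, ann, next_a = _neighbors(annotations, gene, circular)
    fl = min(flank, ann.length(glen))
    # an unflipped L (or a flipped R) reads toward the gene's genomic 3' side
    toward_end = (side == "L") != flipped
    if toward_end:
        if next_a is None:
            raise ValueError(f"gene {gene!r} has no following neighbor")
        start = ann.end - fl + 1
        end = next_a.start - 1  # window = gene flank + following intergenic
    else:
        if prev_a is None:
            raise ValueError(f"gene {gene!r} has no preceding neighbor")
        start = prev_a.end + 1
        end = ann.start + fl - 1  # window = preceding intergenic + gene flank
    # the window always contains at least the fl-nt gene flank, so it is
    # never empty even when the intergenic region vanishes
    seq = _window(genome.seq, start, end, circular)
    out = NucSeq(f"{side}|{gene}", seq)
    if flipped:
        out = NucSeq(out.id, reverse_complement(out.seq))
    return out


def extract_queries(
    genome: NucSeq,
    annotations: list[GeneAnnotation],
    bp: Breakpoint,
    flank: int = 60,
    circular: bool = True,
) -> tuple[NucSeq, NucSeq]:
    """The derived-genome queries (L, R) for one breakpoint.

    L is the last ``flank`` nucleotides of the left query gene plus the
    intergenic region toward its new neighbor; R is the intergenic region
    preceding the right query gene plus its first ``flank`` nucleotides.
    Flipped genes mirror the neighbor direction and are
    reverse-complemented.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    L = _query_window(genome, annotations, bp.left_gene, flank, "L", bp.left_flipped, circular)
    R = _query_window(genome, annotations, bp.right_gene, flank, "R", bp.right_flipped, circular)
    return L, R


def extract_region(
    ref_genome: NucSeq,
    ref_annotations: list[GeneAnnotation],
    derived_genome: NucSeq,
    derived_annotations: list[GeneAnnotation],
    bp: Breakpoint,
    flank: int = 60,
    circular: bool = True,
) -> BreakpointRegion:
    """Extract the full (F, L, R) triple for one breakpoint."""
    F = extract_reference(ref_genome, ref_annotations, bp, flank, circular)
    L, R = extract_queries(derived_genome, derived_annotations, bp, flank, circular)
    glen = len(ref_genome)
    left = _find_ann(ref_annotations, bp.left_gene)
    right = _find_ann(ref_annotations, bp.right_gene)
    # nucleotides between the genes; zero when they abut
    intergenic = (right.start - 1 - left.end) % glen
    return BreakpointRegion(
        F=F,
        L=L,
        R=R,
        breakpoint=bp,
        provenance={
            "ref": ref_genome.id,
            "derived": derived_genome.id,
            "flank": flank,
            "ref_intergenic_len": intergenic,
            "left_flipped": bp.left_flipped,
            "right_flipped": bp.right_flipped,
        },
    )


def apply_filters(
    region: BreakpointRegion,
    max_ref_intergenic: int = 40,
    min_query_in_F: int = 10,
    scheme: ScoringScheme | None = None,
    alignment=None,
) -> BreakpointRegion:
    """Exclusion filters for survey statistics.

    A region is excluded (but still reported) when the intergenic stretch in
    F exceeds ``max_ref_intergenic`` nucleotides, or when the aligned span
    of L or R within F covers fewer than ``min_query_in_F`` reference
    positions.  The span test aligns the region if no alignment is given.
    """
    intergenic = region.provenance.get("ref_intergenic_len", 0)
    if intergenic > max_ref_intergenic:
        return dataclasses.replace(
            region, exclusion=f"ref_intergenic_gt_{max_ref_intergenic}"
        )
    if alignment is None:
        if len(region.L) == 0 or len(region.R) == 0:
            return dataclasses.replace(region, exclusion=f"query_lt_{min_query_in_F}_in_F")
        alignment = align(region.F, region.L, region.R, scheme or ScoringScheme())
    span_l = sum(1 for c in alignment.columns if c.f != GAP and c.l != GAP)
    span_r = sum(1 for c in alignment.columns if c.f != GAP and c.r != GAP)
    if span_l < min_query_in_F or span_r < min_query_in_F:
        return dataclasses.replace(region, exclusion=f"query_lt_{min_query_in_F}_in_F")
    return region
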