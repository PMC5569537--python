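"""Tests for gene-order breakpoints, region extraction and filters."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bpalign import (
    Breakpoint,
    GeneAnnotation,
    NucSeq,
    ScoringScheme,
    align,
    apply_filters,
    extract_queries,
    extract_reference,
    extract_region,
    find_breakpoints,
    measure_overlap,
    order_from_annotations,
    reverse_complement,
)
from bpalign.fixtures import toy_genome_pair


class TestFindBreakpoints:
    def test_transposition_breaks_three_adjacencies(self):
        bps = find_breakpoints(list("abcd"), list("acbd"), circular=False)
        assert {(b.left_gene, b.right_gene) for b in bps} == {
            ("a", "b"), ("b", "c"), ("c", "d"),
        }

    def test_identical_orders_have_no_breakpoints(self):
        assert find_breakpoints(list("abcd"), list("abcd"), circular=False) == []
        assert find_breakpoints(list("abcd"), list("abcd"), circular=True) == []

    def test_inversion_conserves_the_inner_adjacency(self):
        bps = find_breakpoints(["a", "b", "c", "d"], ["a", "-c", "-b", "d"],
                               circular=False)
        assert {(b.left_gene, b.right_gene) for b in bps} == {("a", "b"), ("c", "d")}
        by = {(b.left_gene, b.right_gene): b for b in bps}
        assert by[("a", "b")].right_flipped and not by[("a", "b")].left_flipped

    def test_circular_wraparound_adjacency_checked(self):
        # rotating a circular order is not a rearrangement
        assert find_breakpoints(list("abcd"), list("cdab"), circular=True) == []
        # but linear reading sees the cut
        assert find_breakpoints(list("abcd"), list("cdab"), circular=False)

    def test_different_gene_sets_rejected(self):
        with pytest.raises(ValueError):
            find_breakpoints(list("abc"), list("abd"), circular=False)

    def test_ignored_features_dropped_before_comparison(self):
        bps = find_breakpoints(["a", "CR", "b"], ["a", "b", "CR"],
                               circular=True, ignore=("CR",))
        assert bps == []

    @settings(derandomize=True, max_examples=60)
    @given(rot_ref=st.integers(0, 5), rot_der=st.integers(0, 5))
    def test_rotation_invariance_on_circular_orders(self, rot_ref, rot_der):
        ref = ["a", "b", "c", "d", "e", "f"]
        der = ["a", "c", "b", "d", "-f", "-e"]
        base = {(b.left_gene, b.right_gene)
                for b in find_breakpoints(ref, der, circular=True)}
        ref_r = ref[rot_ref:] + ref[:rot_ref]
        der_r = der[rot_der:] + der[:rot_der]
        got = {(b.left_gene, b.right_gene)
               for b in find_breakpoints(ref_r, der_r, circular=True)}
        assert got == base


def _toy_genome(parts):
    """Assemble (name_or_None, seq) parts into (NucSeq, annotations)."""
    seq, anns = "", []
    for name, s in parts:
        if name:
            anns.append(GeneAnnotation(name, len(seq) + 1, len(seq) + len(s), "+"))
        seq += s
    return NucSeq("toy", seq), anns


class TestExtractReference:
    def test_flank_plus_intergenic_plus_flank(self):
        genome, anns = _toy_genome(
            [(None, "T" * 10), ("a", "A" * 30), (None, "G" * 20), ("b", "C" * 30),
             (None, "T" * 10)]
        )
        F = extract_reference(genome, anns, Breakpoint("a", "b"), flank=10,
                              circular=False)
        assert F.seq == genome.seq[30:70]
        assert len(F) == 40

    def test_abutting_genes_have_no_intergenic_part(self):
        genome, anns = _toy_genome([("a", "A" * 30), ("b", "C" * 30)])
        F = extract_reference(genome, anns, Breakpoint("a", "b"), flank=10,
                              circular=False)
        assert F.seq == "A" * 10 + "C" * 10

    def test_flank_clamped_to_short_genes(self):
        genome, anns = _toy_genome([("a", "ACGTA"), ("b", "C" * 30)])
        F = extract_reference(genome, anns, Breakpoint("a", "b"), flank=10,
                              circular=False)
        assert F.seq.startswith("ACGTA") and len(F) == 15

    def test_window_wraps_circular_origin(self):
        # adjacency (b, a) wraps: b at the end, a at the start
        genome, anns = _toy_genome(
            [("a", "A" * 20), (None, "G" * 5), ("b", "C" * 20), (None, "T" * 5)]
        )
        F = extract_reference(genome, anns, Breakpoint("b", "a"), flank=10,
                              circular=True)
        assert F.seq == "C" * 10 + "T" * 5 + "A" * 10

    def test_non_adjacent_genes_rejected(self):
        genome, anns = _toy_genome(
            [("a", "A" * 20), ("b", "C" * 20), ("c", "G" * 20)]
        )
        with pytest.raises(ValueError):
            extract_reference(genome, anns, Breakpoint("a", "c"), circular=False)


class TestExtractQueries:
    def test_unflipped_lengths_include_intergenic(self):
        genome, anns = _toy_genome(
            [("a", "A" * 30), (None, "G" * 15), ("b", "C" * 30), (None, "T" * 4),
             ("c", "A" * 30)]
        )
        L, R = extract_queries(genome, anns, Breakpoint("a", "b"), flank=10,
                               circular=False)
        assert len(L) == 25  # 10-nt flank + 15-nt following intergenic
        assert L.seq == "A" * 10 + "G" * 15
        assert R.seq == "G" * 15 + "C" * 10

    def test_zero_intergenic_gives_bare_flanks(self):
        genome, anns = _toy_genome([("a", "A" * 30), ("b", "C" * 30)])
        L, R = extract_queries(genome, anns, Breakpoint("a", "b"), flank=10,
                               circular=False)
        assert len(L) == len(R) == 10

    def test_flipped_right_query_is_reverse_complemented(self):
        b_gene = "ACGGATTACAGGATCCGTTA"
        i_bc = "GGGTT"
        genome, anns = _toy_genome(
            [("a", "A" * 20), (None, "CCAA"),
             ("b", reverse_complement(b_gene)), (None, i_bc), ("c", "T" * 20)]
        )
        # mark b as minus-strand in the derived annotation
        anns = [
            GeneAnnotation(a.gene, a.start, a.end, "-" if a.gene == "b" else "+")
            for a in anns
        ]
        bp = Breakpoint("a", "b", right_flipped=True)
        _, R = extract_queries(genome, anns, bp, flank=8, circular=False)
        # reading direction of b: its first 8 nt, preceded by the intergenic
        # on its 5' side (which lies toward c on the forward strand)
        assert R.seq == reverse_complement(i_bc) + b_gene[:8]


class TestFilters:
    def _region(self, intergenic_len, scheme):
        genome, anns = _toy_genome(
            [("a", "A" * 80), (None, "G" * intergenic_len), ("b", "C" * 80)]
        )
        bp = Breakpoint("a", "b")
        return extract_region(genome, anns, genome, anns, bp, flank=60,
                              circular=False)

    def test_long_reference_intergenic_excluded(self, scheme):
        region = self._region(45, scheme)
        out = apply_filters(region, scheme=scheme)
        assert out.exclusion == "ref_intergenic_gt_40"

    def test_clean_region_passes(self, scheme):
        region = self._region(0, scheme)
        out = apply_filters(region, scheme=scheme)
        assert out.exclusion is None

    def test_short_aligned_span_excluded(self, scheme):
        region = self._region(0, scheme)
        # an L that can pair with at most 6 reference positions
        region.L = NucSeq("L", "A" * 6)
        out = apply_filters(region, scheme=scheme)
        assert out.exclusion == "query_lt_10_in_F"


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected", [("ACGT", "ACGT"), ("AAAC", "GTTT"), ("ANG", "CNT")]
    )
    def test_values(self, seq, expected):
        assert reverse_complement(seq) == expected

    def test_involution_on_nucseq(self):
        s = NucSeq("x", "ACGGTNACC")
        assert reverse_complement(reverse_complement(s)).seq == s.seq


class TestRoundTrips:
    """End-to-end invariants on the packaged toy genome pairs."""

    def _rows(self, kind, scheme):
        ref, ref_anns, der, der_anns = toy_genome_pair(kind)
        bps = find_breakpoints(
            order_from_annotations(ref_anns),
            order_from_annotations(der_anns),
            circular=True,
        )
        out = {}
        for bp in bps:
            region = extract_region(ref, ref_anns, der, der_anns, bp)
            aln = align(region.F, region.L, region.R, scheme)
            out[(bp.left_gene, bp.right_gene)] = measure_overlap(aln)
        return out

    def test_clean_transposition_junction_is_flush(self, scheme):
        rows = self._rows("transposition", scheme)
        assert rows[("nad1", "trnK")].signed_value == 0

    def test_tandem_duplication_remnant_measured_exactly(self, scheme):
        rows = self._rows("tdrl", scheme)
        g = rows[("cox2", "atp8")]
        assert g.kind == "overlap" and g.length == 12
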