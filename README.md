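# bpalign — partially local three-way alignment of breakpoint regions

When a genome rearrangement (a transposition, inversion, or tandem
duplication followed by random loss, TDRL) breaks a gene adjacency, the
breakpoint region of the ancestral genome `F` is split into two pieces that
end up in different places of the derived genome: a left fragment `L` and a
right fragment `R`. Pinpointing where exactly `L` ends and `R` begins on
`F` — and whether they *overlap* (a duplication remnant) or leave a *gap*
(deleted sequence) — is evidence for the molecular mechanism behind the
rearrangement. Mitochondrial gene orders are the classic application: TDRL
events leave pseudogenized duplication remnants around breakpoints, while
clean cut-and-paste transpositions do not.

`bpalign` implements the specialized alignment this question requires: a
three-way alignment of `F`, `L` and `R` that is **global at the outer
ends** but **local toward the breakpoint** — a suffix of `L` and a prefix
of `R` may stay unaligned at no cost, `L` and `R` may overlap on `F` (the
overlap is scored as a three-way alignment), or an internal interval of
`F` may remain unaligned without gap penalty.

## The model

Columns are scored by pairwise similarities `σ` on `{A,C,G,T,-}` with
match `α > 0`, mismatch `β < 0`, indel `δ < 0`, `σ(-,-) = 0`, and a
sum-of-pairs three-way score

    γ(a,b,c) = (σ(a,b) + σ(a,c) + σ(b,c)) / w(a,b,c)

with `w = W ≥ 1` when all three symbols are letters and `w = 1` otherwise.
`W` down-weights the overlap region relative to the flanks.

The optimum is computed by dynamic programming over a tensor `S[i,j,k]`
(best score for the prefixes `F[1..i]`, `L[1..j]`, `R[1..k]`, with `k = 0`
encoding "R not yet begun") and a matrix `M[i,k]` holding the best score of
an `F`–`R` alignment continuing after the end of `L`'s aligned part; the
case "the three sequences do not overlap" uses a running maximum
`m̃[i] = max_{i'<i} max_j S[i',j,0]` so the whole computation is
`O(m·n·p)` time and space. The traceback starts at `M[m,p]`. The default
scores are `(α, β, δ) = (1, -1, -2)` with `W = 1`.

The **overlap** is the number of alignment columns from the first to the
last column in which `F`, `L` and `R` are all aligned; the **gap** is the
number of reference nucleotides between `L`'s and `R`'s aligned regions
that are aligned to neither.

## Worked example

```sh
$ cat trio.fa
>F
ACGT
>L
ACG
>R
CGT
$ bpalign align trio.fa --stockholm out.sto
score   overlap_or_gap  l_end_in_F      r_start_in_F
8       2       3       2
$ cat out.sto
# STOCKHOLM 1.0
#=GF SC 8
#=GF OV 2
F            ACGT
L            ACG-
R            -CGT
#=GC region  LOOR
//
```

The optimal alignment scores 8: one `F`–`L` column (`L`), two three-way
overlap columns (`O`, scored `γ(C,C,C) = γ(G,G,G) = 3` each), and one
`F`–`R` column (`R`). `L` and `R` overlap on two reference positions
(`overlap_or_gap = 2`, positive = overlap): the fragments share the
duplicated `CG` core. A negative value would report a gap, e.g. aligning
`F=ACGTAC, L=AC, R=AC` yields score 4 with `overlap_or_gap = -2` — the two
reference positions `GT` are deleted in the derived genome.

As a library:

```python
from bpalign import align, measure_overlap, ScoringScheme

aln = align("ACGT", "ACG", "CGT", ScoringScheme(1, -1, -2))
print(aln.score, measure_overlap(aln).signed_value)  # 8.0 2
```

Further subcommands: `bpalign simulate` (scoring-parameter scan on
synthetic instances), `bpalign breakpoints` (signed gene orders → broken
adjacencies), `bpalign extract` (genomes + annotations → `F`,`L`,`R`
FASTA, with 60-nt gene flanks, intergenic regions and
reverse-complementation of inverted queries), and `bpalign pipeline`
(extract → align → measure over a manifest of genome pairs, with the
standard exclusion filters: reference intergenic stretch > 40 nt, query
aligned to < 10 nt of `F`).

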