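# Methods

## The alignment model

`bpalign` aligns a reference breakpoint region `F` (length `m`) against the
two fragments `L` (length `n`) and `R` (length `p`) into which the region
is split in a rearranged genome. The alignment is global at the outer ends
of all three sequences and local toward the breakpoint:

* a terminal suffix of `L` and a terminal prefix of `R` may remain
  unaligned at no cost (in real data these are intergenic sequence toward
  the fragments' new neighbors, with no homology to `F`);
* `L` and `R` may overlap on `F`; overlapping columns are scored as a
  three-way alignment (duplication remnants make both fragments similar to
  the same reference interval);
* alternatively an internal interval of `F` between the end of `L`'s and
  the start of `R`'s aligned regions may stay unaligned without gap
  penalty (deleted sequence).

Scores are additive over columns. Pairwise scores are letter-independent:
match `α > 0`, mismatch `β < 0`, indel `δ < 0`, `σ(-,-) = 0`; the
ambiguity letter `N` scores as a mismatch against everything including
itself. Three-way columns use the sum-of-pairs score
`γ(a,b,c) = (σ(a,b)+σ(a,c)+σ(b,c))/w`, where `w = W ≥ 1` if all three
symbols are letters and `w = 1` otherwise. `β > δ` is recommended (a
warning is raised otherwise) so that mismatches are not replaced by
indel pairs.

### Dynamic program

`S[i,j,k]` is the optimal score of an alignment of the prefixes `F[1..i]`,
`L[1..j]`, `R[1..k]`, where `k = 0` means `R` has not begun (its prefix
may later be deleted free of charge). Interior cells take the maximum of
the seven `γ`-extension cases plus, for `k > 0`, the free-R-prefix case
`S[i,j,0]`. The `k = 0` face is a plain pairwise global alignment of `F`
and `L`; the `j = 0` and `i = 0` faces are pairwise recursions scored with
`γ`, because gaps relative to the not-yet-started `L` (resp. the exhausted
`F`) are penalized there. Edge initializations are `S[i,0,0] = i·g`,
`S[0,j,0] = j·g` and `S[0,0,k] = 2g·k`, with `g` the uniform edge gap
score.

A second matrix `M[i,k]` holds the optimal score of an `F`–`R` alignment
that continues after the aligned part of `L` has ended: pairwise
σ-extensions, the transition case `max_j S[i,j,k]` ("L ends at j"), and
the no-overlap case `max_{i'<i} max_j S[i',j,0]` in which the reference
interval `F[i'+1..i]` carries no gap cost. The running maximum
`m̃[i] = max(m̃[i-1], max_j S[i-1,j,0])` makes the last case O(1) per
cell, so the whole computation is `O(m·n·p)` time and space. The traceback
starts at `M[m,p]` and ends at `S[0,0,0]`.

The recursion kernels are numba-compiled; the traceback is plain Python
(path length `O(m+n+p)`). All score comparisons use an absolute tolerance
of 1e-9; with the default integer scheme and `W = 1` all values are exact
integers, with `W ∈ {2,3}` thirds and halves appear.

### Design choices

* **g = δ by default.** The edge gap score is stored separately from the
  interior indel score but defaults to it, keeping a single gap economy.
* **Tie-breaking.** When several cases reach the maximum, the traceback
  prefers them in the listed order of the interior recursion (three-way
  column first, then `F`-containing doubles, the free R-prefix last); in
  `M` it prefers σ-extensions, then the transition with the largest `j`,
  then the free-interval case with the largest `i'` (then largest `j`).
  Output is therefore deterministic, and scored columns are preferred over
  free deletions, which maximizes explicit homology — the quantity the
  overlap statistic is based on.
* **Free R prefix only from the interior.** The free-prefix case is
  applied only for `i, j ≥ 1`, exactly as the interior recursion defines
  it; the boundary faces do not include it.
* **Strict `i' < i`.** The free-interval case of `M` uses the strict
  inequality, so a flush junction is reached through the transition case,
  not through a zero-length free interval.
* **Asymmetry in degenerate corners.** The model is local in `R`'s prefix
  but only the *suffix* of `L` (after the transition) is free; an `L` that
  never aligns is still gap-penalized through the `j = 0` face. As a
  consequence, mirror symmetry (reverse `F`, swap and reverse `L` and `R`)
  holds whenever both fragments genuinely align — verified on designed
  instances — but can fail by a few score units on degenerate inputs where
  one fragment is best left entirely unaligned. This follows the
  recursions as printed; the engine's brute-force oracle agrees with the
  engine on both orientations of such counterexamples.
* **Empty `R`** degenerates to the pairwise problem through the same code
  path (no special casing); empty `F` or `L` is rejected as outside the
  model.

### The brute-force oracle

`brute_force_score` (inputs up to length 6) enumerates every legal
partially local *structure* directly — a global pairwise `F`–`L` prefix, an
optional `γ`-scored three-way segment or an unpenalized `F` interval, a
global pairwise `F`–`R` suffix, free `L`-suffix and `R`-prefix — scoring
each with small memoized global alignments of the subsequences. It shares
no code with the DP kernels and is the primary correctness gate: engine
and oracle agree exactly on hundreds of random instances and random
scoring schemes from the parameter grid.

## The overlap / gap statistic

The overlap is the number of alignment columns from the first to the last
column in which all three sequences are aligned; intervening columns count
even if one row is gapped. If no such column exists, the gap is the number
of reference nucleotides strictly between the end of `L`'s and the start
of `R`'s aligned regions that are aligned to neither fragment (the gap is
measured in nucleotides of `F`, because the deletion scenario removes
reference sequence). A junction with neither is flush. Signed convention:
overlap positive, gap negative. Alignments in which one fragment never
pairs with the reference are flagged degenerate.

## Synthetic instances and the parameter scan

`make_instance` plants a known geometry: a uniform random reference of 120
nt, breakpoint at the center `b = 60`, designed overlap or gap of `t = 10`
nt split symmetrically (`⌈t/2⌉` left, `⌊t/2⌋` right of `b`). `L` receives
the homologous prefix of `F` and `R` the homologous suffix; a random
prefix is prepended to `L` and a random suffix appended to `R`, both of
the designed length by default, mimicking annotation items that flank the
approximate breakpoint position. The homologous parts of `L` and `R`
(only) are substitution-mutated position-wise at 0, 15 or 30%; mutations
never insert or delete. Per-instance seeds are `base_seed + index`, and
instances are shared across scoring schemes within one (scenario,
mutation) condition, so scheme comparisons are paired and every scan is
bit-reproducible from its base seed.

The outer placement of the random flanks matters and was chosen
deliberately: placing tens of random nucleotides at the *junction* side
instead produces local-alignment excursions of the flank against the
reference (classic local-alignment statistics of random sequence) that
systematically stretch the first-to-last-triple span by ~5–10 nt at
`W = 1` and can flip designed gaps into apparent overlaps. With the
flanks at the outer (globally aligned) ends, the designed geometry is the
unique optimum in the noiseless case: the scan recovers the 10-nt overlap
and gap exactly at `(1,-1,-2)`, `W = 1`. What the passing recovery tests
therefore show is calibration of the scoring scheme on clean planted
geometries; they do not bound the junction-side random-match noise of real
data, which the toy-genome pipeline fixtures (with realistic 12–25 nt
junction intergenics) deliberately exhibit, and which shows up in real
surveys as spurious overlaps of a few nucleotides.

Qualitative behavior reproduced by the scan (50 instances per cell):
raising `W` to 3 shrinks the measured overlap (three-way matches lose
their advantage over pairwise continuation); overconfident schemes
(match 3, gap −1) grossly overestimate overlaps under 30% mutation; weak
relative match scores (1 with mismatch/gap −2 or −3) underestimate them or
turn them into apparent gaps; gaps are recovered almost exactly without
mutation and are slightly underestimated for small gap penalties.

## Breakpoints and extraction

Breakpoints are reference gene adjacencies `(a, b)` absent from the
derived signed gene order; a signed adjacency counts as conserved if it
occurs forward `(a, b)` or mirrored `(-b, -a)`, including the wrap-around
adjacency of circular genomes. Orientation flips are read off the signs.
Named features (e.g. the control region) can be dropped before the
comparison.

For each breakpoint, `F` is the genomic forward-strand window from
(end of left gene − flank + 1) to (start of right gene + flank − 1),
flank 60 nt by default, clamped to short genes (tRNAs), wrapping the
origin of circular genomes. `L` is the last flank of the left query gene
plus the intergenic region toward its new neighbor; `R` is the intergenic
region preceding the right query gene plus that gene's first flank (the
gene flank is included in `R` — without it `R` would share no homology
with `F`'s right half). For a gene whose orientation flipped, the neighbor
direction is mirrored and the extracted query is reverse-complemented.
All interface coordinates are 1-based inclusive.

Exclusion filters for survey statistics: reference intergenic stretch
longer than 40 nt, or a query whose aligned span covers fewer than 10
reference positions ("span" = count of `F` positions in columns pairing
the reference with that query; the filter is applied after alignment, and
excluded regions are still reported, only withheld from statistics).

## Fixtures and their limits

The packaged toy genomes (`bpalign.fixtures`) are ~1 kb circular
six-gene "mitogenomes" with 150-nt genes and 25-nt intergenic regions,
related by one planted clean transposition (expected geometry: flush) or
one planted tandem duplication–random loss leaving a 12-nt pseudogene
remnant (expected: overlap 12). One boundary nucleotide after the planted
remnant is set to mismatch the reference continuation so that chance
matches cannot extend the designed overlap. Breakpoints not involved in
the designed junctions carry 12–25 nt of junction-side intergenic junk
and consequently show small chance overlaps — realistic behavior that the
tests deliberately do not constrain.

These synthetic data share none of the biological structure of real
mitogenomes (codon structure, strand-asymmetric base composition, tRNA
clusters, control-region repeats); passing tests demonstrate the
correctness of the algorithmics and the calibration of the scoring
scheme, not performance on diverged real sequence.

## Problem sizes

Default analyses run at the scale the method is meant for: breakpoint
regions of 100–200 nt, for which one alignment fills ~2–8 M tensor cells
(tens of milliseconds compiled). The acceptance script uses 50 instances
per scenario at 120 nt; the full 3×3×3×3×3 parameter scan at 50
instances per cell is a few thousand alignments.
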