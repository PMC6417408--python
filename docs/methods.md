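# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Coordinates and formats

Internally every interval is 0-based half-open; user-facing TSVs are
1-based inclusive (the GenBank convention) and BED output is 0-based
half-open. GenBank `join()` locations become multi-interval features;
minus-strand CDS are extracted as the reverse complement of the
concatenated intervals in genome order. N bases are legal input but act
as universal mismatches: they break SSR tracts, terminate repeat and IR
matches, and are excluded from both numerator and denominator of GC%.
Ambiguity codes other than N in alignments are mapped to N with a
warning. Plastomes default to circular; `extract_region` wraps across the
origin for circular records only.

## Quadripartite structure

The inverted-repeat pair is required to be an *exact* reverse-complement
match: assembled plastome IR copies are identical by construction, and
exactness keeps boundaries unambiguous. Detection anchors 21-mers of the
sequence against its reverse complement, merges anchors along diagonals,
extends each run to its maximal exact extent, and keeps the longest run
whose two genome intervals are disjoint. For circular records the search
is repeated on a half-rotation so an origin-straddling IR cannot be
missed. Ties among co-maximal candidates raise an error listing the
candidates rather than silently choosing — structural ambiguity should be
user-visible. `min_ir` (default 1,000 bp) excludes dispersed inverted
repeats from consideration.

The partition is canonically rotated so the LSC starts at position 0 and
the genome reads LSC, IRb, SSC, IRa; `rotation_offset` records the
applied rotation and `--no-rotate` reports input coordinates instead.
Region statistics report one IR copy's length and GC but the proportion
of both copies (2·ir/L·100). Junction reports consider genic features
(gene/CDS/tRNA/rRNA) only; distances are signed (negative = straddling),
and a straddling feature's `truncated_fragment_len` is its overlap with
the adjacent IR — the duplicated pseudogene fragment in the opposite IR
has the same length by IR symmetry.

## SSRs

Maximal perfect tandem tracts of primitive 1–6 bp units at thresholds
{1: 10, 2: 6, 3: 4, 4: 3, 5: 3, 6: 3} copies. Non-primitive units (ATAT
as a tetramer) are reported only at the shortest unit; tracts are
reported at their leftmost phase. Two qualifying tracts separated by at
most 100 bp (the conventional upstream default; configurable) merge into
one compound "c" SSR — member tracts are retained with a flag, and
summaries count the compound locus once so categories p1–p6/c are
mutually exclusive. Motifs are reported as encountered (no
strand/rotation canonicalization, since published tetranucleotide lists
keep rotations distinct); a normalized column (lexicographic minimum over
cyclic rotations) is provided for grouping. SSRs are called on the full
genome including both IRs, mirroring published whole-genome runs.

## Dispersed repeats

Four types compare the genome S against a transform T: F (T = S),
P (reverse complement), R (reverse), C (complement). Matching uses exact
15-mer seeds to select diagonals; on each seeded diagonal all *maximal
qualifying windows* are computed: a window must start and end on a match,
reach 30 bp, and keep identity strictly above 0.90, and no qualifying
window may contain it. The farthest qualifying end for each start is
found in O(m log m) via a suffix maximum of g(x) = x − t·p(x) over match
positions p (the qualifying condition is g(end) > g(start) − (1 − t)).
Symmetric duplicates are emitted once (canonical pos1 ≤ pos2), the
trivial self-match of F is excluded, and a pair contained in a longer
same-type pair is suppressed. The IR pair itself surfaces as one giant P
pair (possibly extended past the exact IR while identity stays above
90%); `--mask-second-ir` replaces IRb with Ns to remove it while keeping
dispersed repeats.

Two caveats are deliberate. First, the upstream tool's E-value/Hamming
parameterization is replaced by the stated contract (≥ 30 bp, > 90%),
so exact count parity with that tool is not guaranteed. Second, seeding
at k = 15 can miss a qualifying window whose mismatches are spaced so
that no 15-bp exact run survives (possible from ~31 bp with 3 evenly
spread mismatches); lowering `k` trades speed for that sensitivity.

## Divergence

The window statistic is 100·(NS + ID)/L per window of L alignment
columns. The published formula comes from a pairwise context; for many
rows the simplest generalization is used and recorded in output
metadata: NS counts columns containing ≥ 2 distinct bases from {A,C,G,T}
(gaps and N ignored for distinctness — variable columns, not pairwise
differences), and ID counts *indel events*, i.e. maximal gap runs with
identical column bounds counted once regardless of how many rows share
them, assigned to the window containing their first column.
`--indel-count per-row` switches to counting each row's run separately;
both conventions are tested. Row order and row duplication cannot change
either count.

Windows live in alignment-column space (the method windows the aligned
sequence), advance by 400 columns with an 800-column width by default,
and the terminal short window is kept with its actual L. Identical-site
percentage treats the gap as an ordinary character. Hotspots are maximal
runs of consecutive windows with percent strictly above the threshold;
presets 13 / 3.2 / 7.5% correspond to published genus/Batatas/Quamoclit
analyses. Hotspots are projected onto a chosen reference row by prefix
non-gap counts and named by overlapping genes ("gene intron" when only
an intron is hit) or the flanking-gene spacer "geneA-geneB".

## Codon usage

All in-frame codons of annotated CDS, stops included (stop codons form
their own synonymous family and enter the totals). CDS whose length is
not a codon multiple are skipped with a warning. IR-duplicated CDS (same
gene name, identical sequence) are counted once by default
(`dedupe_ir`); published totals do not state which convention they use,
so both are available and neither is asserted. RSCU uses NCBI translation
table 11; families with zero total report an empty RSCU, and per-family
mean RSCU is 1 whenever the family was observed.

## Synthetic data

`simulate_plastome` emulates exactly the features the analyses measure:
an i.i.d. background at a chosen GC (default 0.375), region sizes
defaulting to published plastome dimensions (87.6 kb / 30.9 kb /
12.04 kb), planted SSR tracts (unit-length mix weighted like published
plastome censuses, mono-heavy), planted repeat pairs cycling F/P/R/C
with 0–3 mismatches, named genes (CDS with proper start/stop, a spliced
CDS, an IR-duplicated CDS), and optionally a CDS straddling the SSC/IRa
junction by a chosen overlap. Exact-recovery guarantees are engineered:
planted elements never overlap (padded placement), tract and repeat
flanks are locally mutated so each planted element is exactly maximal,
chance background tracts that would qualify as SSRs are scrubbed by
point mutation, and the bases adjacent to the IR junctions are broken so
the detected IR equals the planted one. It does *not* emulate real gene
density or order, codon bias, GC skew between regions, tandem repeat
arrays, or IR expansion/contraction.

`simulate_family` evolves n rows from a common ancestor in alignment
space: substitution columns (a random proper subset of rows takes one
alternative base — guaranteeing a variable column) and indel events
(geometric lengths, mean 6; shared by a random proper subset of rows) at
per-column rates, kept mutually disjoint and separated so ledger counts
equal detector counts exactly. `hotspot_spec` multiplies both rates
inside chosen intervals. Defaults (8 taxa, 10 kb, substitution rate
0.03/column, indel rate 0.003/column) produce closely related families
comparable to a within-group plastome alignment; because the truth *is*
the alignment, aligner error is outside what passing tests demonstrate.

## Problem sizes and runtime

The test suite runs desk-scale fixtures (5–30 kb genomes, 10–20 kb
alignments) in well under a minute. The acceptance script simulates one
full-size plastome (161,440 bp) and one family of 8 × 20,000 columns and
completes in a few seconds; these sizes were chosen so every stage runs
at realistic scale while staying instant to rerun.

## Known limitations

* IR detection requires exact IR copies; assemblies with divergent IRs
  (rare, but real) would need a relaxed-identity mode.
* Repeat counts are contract-faithful but not count-identical to
  suffix-tree tools with E-value cutoffs; qualitative structure (F/P
  dominance, length-bin shape) is comparable.
* The multi-row NS/ID generalization is one defensible choice among
  several; sensitivity to the indel convention should be reported when
  comparing against published figures (both modes are built in).
* Junction reports assume the four-region layout; plastomes that have
  lost an IR are rejected by design.
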