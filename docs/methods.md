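# Methods

## Coordinate and sequence conventions

All coordinates are 0-based, half-open, on the plus strand; GenBank's
1-based inclusive positions are converted only at the I/O boundary.
Circularity is taken from the GenBank LOCUS line (absent → linear).
A feature crossing the origin of a circular record is stored with
`wraps_origin=True` and a virtual end beyond the record length,
normalized modulo the length on output. CDS translation follows the
bacterial code (table 11): alternative start codons render as M,
codons containing any non-ACGT base as X, the terminal stop is
stripped, and an internal stop is signalled to the caller — the
GenBank reader demotes such CDS to pseudo and excludes them from all
protein-level operations.

## Local alignment and best-hit scoring

Protein pairs are aligned with Smith–Waterman local alignment under
affine gaps via Biopython's `PairwiseAligner`. Defaults mirror the
de-facto standard protein-search parameterization: BLOSUM62, gap open
11, gap extend 1, with a gap of length *L* costing 11 + *L* (BLAST
convention). The matrix's X row/column is zeroed: an unknown residue
carries no signal either way. Identity is counted over all alignment
columns (gap columns count against it); coverage is the fraction of
query residues inside the alignment. Raw substitution-matrix scores
are summed downstream rather than bit scores — the normalization by
the query's self-score makes the λ/K conversion nearly cancel, and raw
scores are aligner-independent; bit-score output remains available
(`AlignmentParams.bit_scores`, Karlin–Altschul λ = 0.267, K = 0.041
for gapped BLOSUM62 11/1).

A hit is accepted at ≥30% identity and ≥50% query coverage by default;
both thresholds are exposed everywhere (library and CLI). Ties for the
best hit break by higher identity, then lower target start coordinate.

**Prefilter.** Candidate pairs must share at least two exact protein
4-mers (inverted index per target proteome). Because a marginal,
threshold-passing chance hit can share fewer than two 4-mers, any
query left hitless by the filtered pass is re-scanned exhaustively;
the filter therefore never changes the reported hits, only the time
taken to find them. This exactness is asserted against an unfiltered
run on 50 synthetic proteome pairs.

**Plasmid totals: one-to-one credit.** Per-CDS hit reporting
(`best_hits`, and the ring-matrix blanks built from it) is
many-to-one: each query CDS independently gets its best target match,
which is what a per-gene presence/absence ring should show. Plasmid
*totals* (`plasmid_raw_score`, and the relative-similarity percentage
built on them) instead use a greedy one-to-one assignment
(`matched_hits`): pairs are taken in descending score order and each
target gene can back at most one query gene, a displaced query falling
back to its next-best unused target. The distinction matters only for
duplicated genes — a target carrying one copy of a family the query
holds in two copies contributes that family's score once, so it cannot
be credited with content it does not have. For a self-comparison the
assignment is a perfect matching and the total equals the summed
self-scores exactly, which pins rel(Q,Q) at 100.00.

## Relative similarity and ranking

rel(Q,T) = 100 · S(Q,T)/S(Q,Q), reported to two decimals. The
self-total is computed once per query and reused across a panel. Panel
ranking sorts by the percentage, breaking ties by raw total then
target id so output is byte-reproducible. The ring matrix rows follow
rank order; a cell is blank exactly when `best_hits` found no accepted
hit for that (query CDS, target) pair. Diagonal dominance of BLOSUM62
bounds every cross-score by the self-score, keeping the percentage in
[0, 100]; this is asserted property-style rather than assumed.

## Duplication census

Two genes are duplicates when their alignment reaches ≥90% identity
and ≥90% coverage of *both* proteins; families are connected
components of the symmetrized graph (union–find). The 90/90 defaults
are a stated design choice aimed at near-identical paralogs such as
repeated transposases, and are exposed as options. Pseudo genes are
excluded from the census entirely.

## Operon calling

A cluster is a maximal same-strand run in which every intergenic gap
satisfies `start(next) − end(prev) < max_gap` strictly (default 20 bp,
so a 19-bp gap joins and a 20-bp gap splits). Measuring between
half-open intervals makes abutting genes gap 0; overlapping genes
(negative gap) always join regardless of `max_gap`. An
opposite-strand gene always breaks a run, even when it would fit
inside the gap. On circular records the first and last runs merge when
the rule holds across the origin, which makes the partition invariant
under rotation of the coordinate origin (tested over random
rotations). Pseudo genes participate: operon structure is a property
of gene arrangement, not of coding integrity. The shipped keyword
table for functional labels (~10 coarse categories, first match in
table order wins, unmatched → "hypothetical/unknown") is a
convenience, not a curated classification.

## Direct repeats (iterons)

`find_direct_repeats` scans unit lengths from longest to shortest. An
array grows greedily: the next copy must start within `max_spacer`
bases (default 10) of the previous copy's end and lie within
`max_mismatch` (default 1) Hamming distance of the *first* copy.
Arrays must be maximal on both sides, and a genomic span already
reported at a longer unit length is not re-reported at a shorter one.
The scan is quadratic-ish and intended for replicon regions (an origin
neighbourhood), not whole chromosomes. Note that when the bases
flanking every copy happen to agree, the repeat unit genuinely extends
— the reported unit length is then longer than the nominal planted
unit; the synthetic generator therefore accepts explicit spacer
sequences so planted arrays can pin their unit length.

## Inverted-repeat pairs

An IR pair of length *L* satisfies revcomp(right) within
`max_mismatch` Hamming distance of left, and every base pairing of
such a pair lies on one anti-diagonal D = left.start + right.end − 1
of the sequence-vs-reverse-complement dot plot. The search indexes
exact k-mers, nominates diagonals from k-mer/revcomp-k-mer matches,
and scans windows around the seeds for maximal mismatch-bounded runs.
k = ⌊(min_len − max_mismatch)/(max_mismatch + 1)⌋ (clamped to [4, 10]):
by pigeonhole a qualifying pair always contains an exact k-run, so no
valid pair can escape the seeding — the search is exhaustively checked
against an independent per-diagonal brute-force scan on short
sequences. Low-complexity masking (homopolymer runs ≥12, dinucleotide
runs ≥16) precedes seeding; unmasked search floods on AT-rich spacers.
Overlapping reports merge to the longest, then fewest mismatches.
Maximal runs absorb chance-matching flank bases within the mismatch
budget, so a planted IR may be reported 1–2 bp longer than planted;
tests assert containment, not flush boundaries.

## Target-site duplications

A TSD must be exact — a duplication is created by a single insertion
event — and lengths are tested from the top of the range down (default
4–6 bp, so a 5-bp duplication is preferred over a coincidental 4-mer).

## Element delineation

A family descriptor carries one terminal IR sequence, one or more
transposase proteins, and the family's TSD length (shipped synthetic
examples use the published Tn3-family geometries: 39/25/38-bp IRs,
5-bp TSD; their sequences are generated stand-ins, since this package
ships no biological reference sequences). Delineation anchors the
descriptor transposases on the record by best-hit alignment, then
takes the descriptor-IR match (≤2 mismatches, numpy sliding Hamming
scan) nearest the anchor on each side within a window (default 100 kb,
sized to the largest composite elements seen in megaplasmids; ties go
to fewer mismatches). Both IRs found → complete call with TSD check.
One IR → truncated on the other side. The span convention for a
right-truncated element: it ends at the interrupting nested element's
right TSD copy when one follows within a short gap (insertional
truncation — the child's right TSD copy is part of the parent), else
at the anchoring transposase CDS; left-truncation mirrors this. Parent
assignment is by smallest containing span; with the TSD-copy
convention a nested child is strictly inside its parent. Cargo lists
CDS strictly inside the span minus the element's own machinery and any
nested element's genes.

## Synteny chaining

One homologue per query gene (its best hit) enters the chaining — this
avoids the quadratic pair explosion of multi-hit chaining and suits
count-based synteny statements. The chain is the longest strictly
monotone subsequence of hit target coordinates (O(n²) DP; clusters are
tens of genes), computed for both orientations with ties going to
"same". Chain length, not an alignment score, is the reported
statistic; no gap penalties are involved. The DP is checked against
exhaustive subsequence enumeration on instances of ≤12 pairs.

## In-silico PCR

Primer binding allows substitutions up to `max_mismatch` (default 2)
but demands an exact 3-base 3' clamp, no indels — a standard PCR
specificity heuristic. Product length runs from the 5' end of the
forward site to the 5' end of the reverse site on the opposite strand,
both primers included. Circular templates are searched on a doubled
sequence so sites and products may span the origin, and products over
20 kb are suppressed as unamplifiable. Both primer orientations are
tried, and predictions are invariant under rotation of a circular
record.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume,
and its defaults are the package's study conditions: 50 genes per
query plasmid, proteins of 80–200 residues, strand runs averaging 3
genes with intra-run gaps drawn from [0, 19] bp and inter-run gaps
from [20, 150] bp, targets derived by copying a stated fraction of
query genes at a stated protein identity. One integer seed governs
everything through per-gene counter-derived substreams, so enlarging a
simulation never perturbs earlier genes and identical configurations
serialize to byte-identical GenBank. Proteins are mutated by
amino-acid substitution at exactly ⌈(1 − identity)·n⌉ positions (never
the initial M) and back-translated with uniform synonymous codons —
indels are excluded, so planted Hamming identity is exact to within
rounding (±2 points, asserted per gene). Elements are inserted with a
real TSD (the target-site bases duplicated around the insert);
truncated elements omit one IR, and nested insertion into an existing
element widens the parent's recorded span. Every ground-truth
assertion is re-checked against the emitted record by an independent
validator at generation time.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: codon-usage and GC biases (codons are
uniform synonymous draws), insertions/deletions and rearrangements
within genes, gene-length and intergenic-length distributions of real
replicons, IS proliferation, or homology below the hit thresholds.
Planted-truth recovery on this data demonstrates algorithmic
correctness under the stated model, not annotation-grade performance
on biological sequences.

## Problem sizes and numerical choices

Test and acceptance runs use plasmids of 4–50 genes (proteins 60–200
aa) and panels of ≤5 targets — sizes chosen so the whole suite
exercises every code path, including the 100-replicate element-
recovery study, in well under a minute of alignment time. Alignment
scores are integers; percentages are reported to two decimals.
Deterministic tie-breaks are stated everywhere order matters (hit
ties, ranking ties, IR merge order, TSD length preference), so all
primary TSV outputs are byte-reproducible.

## Known limitations

- The relative-similarity statistic depends on the aligner
  parameterization and hit thresholds; published rankings produced
  with unspecified search tools are reproducible only to within a few
  percentage points.
- Element delineation requires a descriptor per family; there is no
  de-novo transposon discovery, and two same-family copies closer
  together than their IR spacing can confuse nearest-IR pairing.
- The direct-repeat scan is not built for megabase inputs.
- Multi-record GenBank files, features other than CDS/source, and
  qualifier preservation beyond those used are out of scope.
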