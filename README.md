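# plascomp

Comparative analysis of bacterial plasmids — in particular the large
(often >350 kb) conjugative megaplasmids of *Pseudomonas* and related
soil bacteria, whose backbones (replication, partitioning, conjugation
machinery) are conserved within incompatibility groups while their
accessory cargo (heavy-metal resistance, solvent efflux, degradation
pathways) is shuffled by Tn3-family transposons. `plascomp` is a
library (plus a thin CLI) for the recurring computations of such
studies:

- **Relative similarity ranking.** For a query plasmid *Q* with
  proteome {q₁…qₙ} and a target plasmid *T*, every query CDS is aligned
  locally (Smith–Waterman, affine gaps, BLOSUM62; gap of length *L*
  costs 11 + *L*) against the target's CDS, and

  &nbsp;&nbsp;&nbsp;&nbsp;S(Q,T) = Σᵢ score(qᵢ, best unused hit in T),&nbsp;&nbsp;
  rel(Q,T) = 100 · S(Q,T) / S(Q,Q)

  with hits accepted above identity/coverage thresholds (30% / 50% by
  default) and each target gene credited at most once. rel(Q,Q) = 100.00
  exactly; a panel of targets is ranked by rel, and a per-CDS "ring
  matrix" records which query genes each target carries (blank = no
  homologue), the information content of a circular comparison plot.
- **Operon calling.** An operon is a maximal run of same-strand genes
  with every intergenic gap strictly below 20 bp (half-open
  coordinates; overlapping genes always join; circular records join
  across the origin, so calls are rotation-invariant).
- **Gene-duplication census.** Within-plasmid families as connected
  components of the ≥90% identity / ≥90% mutual-coverage alignment
  graph.
- **Repeat and transposon analysis.** Tandem direct-repeat (iteron)
  arrays; inverted-repeat pairs by seeded anti-diagonal search;
  target-site duplications; and full Tn3-family element delineation
  from descriptors (transposase + terminal IR), including truncated
  elements and nested insertions.
- **Synteny chaining.** The longest order-consistent chain of best-hit
  homologue pairs between a gene cluster and a target replicon, in
  either orientation — the "shares synteny for N genes" count.
- **In-silico PCR** with a 3-base 3' clamp, and GenBank/FASTA/TSV/GFF3
  I/O throughout.
- **A synthetic-data generator** that emits seeded circular plasmids
  with machine-readable ground truth for every stage: strand-run
  operon geometry, proteomes at controlled divergence, planted iterons
  and transposable elements (IR mismatches, TSDs, truncation,
  nesting).

## Worked example

```sh
python examples/simulate_and_rank.py
```

```text
query: synplasmid_42 (9,220 bp, 20 CDS)

rank  target            rel.similarity  n_hits
   1  shares_100pct            100.00%     20
   2  shares_075pct             73.38%     15
   3  shares_050pct             45.39%     10
   4  shares_010pct              6.87%      2
```

Four targets were derived from the query sharing 100/75/50/10% of its
genes; `n_hits` counts query CDS with an accepted homologue, and the
relative-similarity percentage tracks the planted sharing fraction (a
target with 75% of the genes scores ≈73% because the shared genes'
lengths, hence scores, vary). Other examples cover operon calling
(`operon_calling.py`, recovering a planted 4/3/2 run geometry),
transposon delineation with a nested insertion
(`transposon_delineation.py`), iteron and inverted-repeat detection,
synteny chaining on shuffled targets, and in-silico PCR.

The same operations are available as subcommands of the `plascomp`
CLI (`rank`, `ring`, `operons`, `census`, `repeats`, `elements`,
`synteny`, `pcr`, `simulate`), each writing TSV with a parameter-echo
header.

## Layout

- `src/plascomp/` — library modules (`records`, `io`, `pcr`, `align`,
  `ranking`, `operons`, `repeats`, `synteny`, `simulate`, `plots`,
  `cli`).
- `src/plascomp/data/elements_synthetic.toml` — synthetic Tn3-family
  descriptors (published IR lengths 39/25/38 bp and 5-bp TSD; the
  sequences themselves are generated stand-ins).
- `examples/` — one short narrative script per capability.
- `docs/methods.md` — models, parameters, numerical choices and
  limitations.
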