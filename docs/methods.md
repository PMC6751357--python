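# Methods

This document records the model behind `cavescreen`, the conventions it
commits to, the default parameters and why they are what they are, what
the synthetic-data generator does and does not emulate, and the known
limitations.

## Coordinate model

All coordinates — genomic, cDNA and protein — are 1-based and fully
closed (`[start, end]` includes both endpoints). A gene model is an
ordered list of exons on a named scaffold with a strand; cDNA position
1 is the transcript 5′ end, so on the minus strand cDNA coordinates run
antiparallel to genomic coordinates. `genomic_to_cdna` and
`cdna_to_genomic` are exact inverses over every exonic base (tested
exhaustively on both strands); intronic genomic positions map to a
sentinel, never to a nearest exon.

Protein residue numbering uses `residue = ceil((cpos − cds_offset)/3)`
with `cds_offset` defaulting to 0, i.e. cDNA position 1 is the first
base of the first codon unless a model supplies an explicit offset. An
insertion of `3k` bases adds `k` residues only when its length is a
multiple of 3; `residue_gain` refuses frameshift lesions rather than
returning a misleading number.

## Indel calling from spliced alignments

Events are read directly from CIGAR strings (`I` and `D` operations),
with `N` operations treated as splice gaps that advance the reference
but contribute neither depth nor events. Soft-clipped bases are
ignored. Every event is **left-aligned** against the reference before
counting, so equivalent placements of an indel inside a repeat collapse
to one canonical site; left alignment is idempotent and tested as a
property.

### Depth versus support (a deliberate convention)

The two counts at a site are defined differently, and the distinction
matters:

- **Depth** counts reads whose aligned segments cover the *site
  position*: for an insertion after base `p`, both flanking bases
  `(p, p+1)`; for a deletion starting at base `p`, the first deleted
  base and its left flank `(p−1, p)`.
- **Support** (the alt count) requires a read to span the *entire
  event*: `(p, p+1)` for an insertion, `(p−1, p+L)` for an `L`-bp
  deletion, so a read only counts as carrying a deletion if it aligns
  across both breakpoints.

With depth defined over the full deleted interval instead, a long
deletion would have systematically *lower* depth than its flanks (fewer
reads span 36 bp plus both flanks than span a point), and a genuinely
fixed 36-bp deletion sequenced at 60× would fail a depth-50 cutoff even
though every informative read carries it. Defining depth at the site
position and support over the full event keeps `alt ≤ depth` as an
invariant, yields allele fraction exactly 1.0 for fixed differences on
error-free reads, and makes the depth filter measure coverage rather
than event length.

## Filter cascade

Filters are conjunctive and inclusive at their thresholds; the audit
table records every site against every filter with the first failing
reason. Defaults:

| parameter | default | rationale |
|---|---|---|
| `min_scaffold_bp` | 1,000,000 | loci on short scaffolds cannot be placed relative to QTL intervals; 1 Mb keeps only assembly-anchored genes |
| `min_depth` | 50 | below ~50 spanning reads, a 0.98 fraction cannot be distinguished from heterozygosity or mapping noise |
| `min_allele_fraction` | 0.98 | "fixed in the population" with a small tolerance for residual sequencing/mapping error |
| `min_exon_boundary_bp` | 10 | indels within a few bases of a splice junction are predominantly spliced-alignment artifacts |

Exon-boundary distance is measured to *splice* boundaries only:
transcript ends (the outer edges of the first and last exon) are not
splice sites and do not count. A single-exon transcript therefore has
infinite boundary distance.

Thresholds are validated at construction (non-negative, fraction in
a sane range); filter survival is monotone in every threshold, which is
tested as a property (tightening any threshold can only shrink the
survivor set).

## Annotation and naming

Lesions at the same gene are annotated together. Names use the form
`gene^Ins{a}–{b}` / `gene^Δ{a}–{b}` with an en dash and Greek delta;
single-base lesions drop the range. An ASCII alias (`del`, hyphen) is
provided for 7-bit contexts such as VCF INFO fields, and
`parse_mutation_name` inverts both spellings. Compound lesions get a
frame track: cumulative frame offset after each event, the net offset,
and — when a frameshifting event is cancelled by a later one — the cDNA
position at which the frame is restored.

Protein-domain impact is closed-interval overlap between the lesion's
residue span and a per-gene domain table (a packaged table covers the
synthetic universe's genes; any TSV with the same columns works).

## Population comparison and reference inversion

Per population, each candidate locus is genotyped as variant-fixed,
reference-fixed or ambiguous using the same depth/fraction thresholds
as the screen. Sharing classes:

- **shared-cave** — surface differs from both caves, in either
  orientation: the reference assembly may carry the *cave* allele, in
  which case the fixed difference is observed in the surface alignment.
- **single-cave(X)** — exactly one cave population carries the variant.
- **surface-specific** — shared-cave topology where outgroup
  polarization shows the *cave* allele is ancestral, i.e. the change
  happened on the surface lineage.
- **uninformative** — anything else (ambiguous genotypes, no fixed
  difference).

When the reference carries the cave allele ("flip"), observed events
are re-expressed in cave-allele coordinates with a cumulative shift:
an observed deletion of reference bases `[a..b]` is a cave insertion
`Ins a–b`; an observed insertion after reference base `r` is a cave
deletion whose cDNA start accounts for all earlier events' length
changes. A metamorphic test builds the same lesion both ways
(reference carrying cave vs surface allele) and checks that the
reported name, frame class, sharing class and polarization are
identical even though the raw observed events differ in kind.

Polarization aligns the surface and cave alleles (a ±60 bp window
around the lesion) against an outgroup ortholog with Biopython's global
`PairwiseAligner` (match +1, mismatch −1, gap open −2, extend −0.5) and
calls ancestral the allele with higher identity
(`identities / alignment length`); ties are reported as such, never
broken arbitrarily.

## QTL colocalization

Markers carry a trait from a fixed vocabulary (pigmentation, body
morphology, sensory, craniofacial morphology, eye morphology, jaw
morphology). Distance from a gene to a marker on the same scaffold is 0
if the marker falls inside the gene span, otherwise the gap to the
nearer gene boundary (a midpoint mode is also available). Markers on
other scaffolds are incomparable, and genes on scaffolds declared
unplaced are reported `unplaced` rather than given a fake distance.
Markers per gene are ranked by distance; rank is invariant under input
permutation.

## The synthetic universe

The generator is the package's oracle: it builds a genome whose
reference scaffolds carry the *cave* allele for the cave-shared lesions
(so they surface, literally, in the surface alignment) and the surface
allele for the Tinaja-private lesion, plants seven known lesions across
seven genes plus two decoys (one on a 0.5 Mb scaffold to fail the
scaffold filter, one 2 bp from a splice boundary to fail the exonic
filter), and emits FASTA, GFF3, per-population SAM, outgroup cDNAs,
QTL markers and a truth table.

What it emulates:

- spliced RNA-seq reads (evenly spaced starts, `N` CIGAR ops across
  introns, soft clips at edges, minus-strand reads reverse-complemented);
- guard bases flanking every planted event so left-alignment cannot
  move it — caller positions byte-match the truth table;
- an outgroup at ~2% divergence outside a protected window around each
  lesion;
- optional uniform substitution errors.

What it deliberately does not emulate: base-quality strings, PCR
duplicates, mapping ambiguity or multi-mappers, alignment-induced indel
errors, paired-end structure, or expression-level variation in
coverage. Substitution errors never touch CIGARs, and planted insertion
bases are shielded from substitution: a fixed difference must stay a
fixed difference, because an "error" inside the inserted bases would
change the event's sequence key rather than model sequencing noise at
that site — the event would no longer be the planted one at all.

Everything is deterministic given a seed: the RNG for read simulation
is keyed on `(seed, crc32(population))` (never Python's per-process
string hash), records are emitted in sorted order, and two builds at
the same seed are byte-identical.

## Numerical choices

- Counting is exact integer arithmetic throughout; allele fraction is
  the only floating division, compared against thresholds with `>=`
  (inclusive), never with tolerance bands.
- Genome synthesis uses a `numpy` uint8 lookup table into a `bytearray`
  for speed; sequence identity in polarization uses exact match counts,
  not score heuristics.
- VCF output follows the 4.2 anchor-base convention (insertion at POS
  `p` with REF = base `p`; deletion anchored at `p−1`); a deletion
  starting at scaffold position 1 cannot be anchored and is rejected
  explicitly. Round-tripping through an independent parser (`pysam`)
  back to caller site keys is tested as a property.

## Limitations

- The caller trusts the aligner: it does not realign, so systematic
  alignment errors (e.g. indels pushed into splice junctions) are
  handled only by the exon-boundary filter, not corrected.
- Genotyping is population-pooled; there is no individual-level or
  likelihood-based genotype model, so the fixed/ambiguous boundary is
  a hard threshold.
- Polarization uses a single outgroup and a local window; it cannot
  detect parallel changes in the outgroup lineage.
- QTL colocalization is distance ranking only — no linkage intervals,
  no significance model.
- The screen targets indels observable within single reads; events
  longer than the read length (minus flanks) are invisible by
  construction.
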