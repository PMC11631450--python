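# Methods

This note records the models, conventions, numerical choices, and open
design decisions behind `orchardqc`, and what the synthetic fixtures do and
do not establish about real data.

## Coordinates and interval algebra

All internal coordinates are 0-based half-open `[start, end)`. GFF3 (1-based
closed) is converted only at the I/O boundary; BED passes through natively.
Interval union, coverage, and pairwise overlap are computed on merged
(sorted, disjoint) interval lists; all higher-level rules (repeat burial,
evidence coverage, isoform overlap) reduce to these two primitives, which
the tests check against per-base bitmap oracles on hundreds of random
instances. Feature lines other than gene/mRNA/exon/CDS are carried opaquely
and re-emitted verbatim; they never influence filtering. Genes whose
transcripts disagree on seqid or strand are rejected at load — such input
indicates an upstream error rather than a case to repair silently.

## Gene-model curation

Three error classes are handled in a fixed order (1 → 2 → 3); the pipeline
is idempotent because Type 3 splitting produces exon-disjoint genes that
cannot re-trigger Types 1–2 at the same loci.

* **Type 1 (repeat-buried genes).** The "coding region" of a gene is the
  union of CDS intervals across all isoforms — a gene is one locus, so
  per-isoform fractions would double-count shared exons. Repeats are merged
  before overlap. The threshold comparison is inclusive (fraction ≥ 0.90
  removes); the default 0.90 is configurable. Genes with zero CDS bases are
  logged and treated as fraction 0 (they cannot be shown to be repeat
  artefacts by this rule).
* **Type 2 (same-strand overlapping models).** Overlap is evaluated on gene
  spans. The pairwise "remove the shorter" rule is extended to arbitrary
  overlap chains by a deterministic iteration: while any same-strand span
  overlap remains, remove the involved gene with the globally smallest span
  (ties: larger start, then lexicographically smaller id). This is the
  minimal deterministic generalization of the pairwise rule; the test suite
  cross-checks it against a naive O(n²) re-simulation.
* **Type 3 (disjoint "isoforms").** Transcripts of one gene are nodes of a
  graph with edges where merged exon footprints share ≥ 1 bp; each connected
  component becomes a gene (`<id>.1`, `<id>.2`, … ordered by leftmost
  start). Exon footprint (not CDS, not span) is the basis because "no
  overlap" between splice variants refers to their transcribed extents.
  Transcript count is conserved.

## Evidence tiering

"Full" support means the evidence union covers 100% of the exonic footprint
(RNA) or CDS footprint (protein) — not the genomic span, which alignments
cannot cover across introns. "Any" support is ≥ 1 bp overlap with the
genomic span, the most permissive reading of "covering part of the gene".
A gene without coding bases is never granted full protein support.
Functional-annotation and orthogroup flags arrive as precomputed gene-id
lists (outputs of external annotation pipelines); this module performs no
database search. Subsets follow the literal set-union definitions
(S3 = S1 ∪ {functional ∧ orthogroup}, S4 = S1 ∪ {functional ∨ orthogroup})
without additionally requiring evidence overlap for the S3/S4 additions.

## Nomenclature

Identifiers follow the GDR convention
(`<tolPrefix>.<cultivar>.vMAJaMIN.chNN[hap].gNNNNN[.tN]`). Gene numbering is
per chromosome token, step 1, width-5 zero padding, restarting at `g00001`
on each chromosome, in ascending span-start order — inferred from the single
published example and therefore configurable. "Longest isoform" means
maximal spliced (summed-exon) length, with ties broken by CDS length then
lexicographic id; genomic span is deliberately not used because a short
transcript with a long intron is not "longer" in any sequence-content sense.

## Orthogroup QC

The CROG matrix counts genes per (orthogroup, genome). Row z-scores use the
population SD (divide by n), matching common clustermap defaults; rows with
zero SD — including all-zero rows from orthogroups absent everywhere — carry
no contrast and are dropped and reported. Clustering for display order is
agglomerative with average linkage on Euclidean distances, with scipy's
deterministic input-index tie-breaking. UpSet counts are exact membership
patterns, so categories partition the orthogroup union by construction.
A per-genome mean z-score depends on which genomes enter the matrix, so the
boxplot summary reports per-genome statistics without asserting any
cross-dataset constant.

## Haplome binning

Canonical k-mers (lexicographic min of a k-mer and its reverse complement)
are 2-bit packed into `uint64` (k ≤ 32; default k = 21, the standard choice
for genome-scale k-mer work) and held as sorted unique arrays, giving
vectorised set algebra at multi-megabase scale. Two operating modes:

* **Two-parent marker mode** (default, and the mode the simulations test):
  markers are the set differences `A\B` and `B\A`; a scaffold's informative
  k-mers are those hitting either side, and scores are the two fractions
  (summing to 1). At 1.35% substitution divergence ≈ 25% of all 21-mer
  windows span a diagnostic site, so informative counts are large and
  margins near 1.
* **Single-reference mode** (when only one parent's assembly exists):
  score_A is plain containment in the reference set, score_B ≡ 0.

A call is `ambiguous` when the margin |score_A − score_B| < 0.02 or fewer
than 1,000 informative k-mers exist; both thresholds are configurable and
reported per call. The defaults are deliberately conservative: a true
single-parent chromosome in the simulated regime has margin > 0.9.

Chromosome renaming/orientation consumes PAF rows: aligned bases (alignment
block length) are summed per reference chromosome, the argmax is assigned if
it holds ≥ 50% (configurable) of the scaffold's aligned bases, and
orientation is reversed when minus-strand bases to the assigned chromosome
exceed plus-strand bases (ties → forward).

## Sequence statistics and telomeres

N50/L50 use the standard sort-and-accumulate definition; ambiguous bases are
excluded from the GC denominator; fold coverage is rounded half away from
zero. Note that N50 is not monotone under lengthening an arbitrary sequence
(growing a short sequence can raise the half-total past the old N50); it is
monotone when the longest sequence grows, and the tests assert exactly that.

The telomere scanner examines terminal windows (default 50 kb) for tandem
repeats of unit length 2–20. For each unit length u, positions with
`s[i] == s[i+u]` mark period-u tracts; the unit class whose single longest
tract holds the most non-overlapping copies wins, with smaller unit lengths
winning ties so a 7-mer array is not reported as its 14-mer doubling.
Scoring the longest tract rather than a window-wide sum is what keeps
dinucleotide background in random sequence from outscoring a genuine
terminal array. Units are reported as a canonical rotation class (minimal
rotation over the unit and its reverse complement), so `AAACCCT`,
`AACCCTA` and `AGGGTTT` are one class. Hits under 50 copies (configurable)
are suppressed; under that default, 20-seed random-sequence nulls produce no
hits. The published tool's internal enrichment statistic is not documented,
so this tandem-count scheme is an explicit, documented stand-in.

## Plastome structure

Quadripartite detection finds the longest pair of exact reverse-complement
repeats with non-overlapping circular placements, by 64-bp seed matching and
maximal extension; the circle is handled by doubling the sequence and
reducing coordinates modulo its length, which makes detection rotation
invariant. Ambiguity symbols break extension. The longer inter-IR arc is
LSC, the shorter SSC; IRa = revcomp(IRb) is asserted on every reported
structure. Exact matching only — published apple plastomes report
identical-length IRs, and approximate repeats are out of scope. Gene
tallies expose an explicit multi-copy rule (`all_copies` default vs
`unique_names`) because published organelle gene counts mix both
conventions.

## Synthetic fixtures: what they emulate, and what they don't

The generators are deterministic per seed and emit machine-readable truth.

* Background sequence is i.i.d. at 38% GC (typical of apple sequencing
  reads). Planted Type 1 genes have ~97% of their CDS in a repeat, with
  near-misses at ~70%; Type 2 pairs nest the shorter gene inside an intron
  of the longer so evidence tracks stay clean; Type 3 genes carry two
  disjoint isoform clusters. Default planted counts are (3, 2, 1).
* Evidence support classes (defaults 60% full / 30% any-only / 10% none)
  are realized exactly over the gene list, with overlapping-pair partners
  ordered so coverage from one cannot contaminate a "none" partner.
* The cross simulator applies substitutions only (default 1.35%, the
  k-mer-estimated heterozygosity typical of apple) plus a 0.1% scaffold
  error rate. No indels, no recombination, no repeats — sufficient to
  exercise k-mer binning, whose marker logic is indifferent to indel
  placement, but deliberately easier than a real F1: real assemblies add
  collapsed repeats, switch errors and organelle contamination that this
  fixture does not model. Passing the binning tests therefore shows the
  scoring machinery is correct, not that real binning is error-free.
* The plastome fixture pins the four junction-adjacent bases so exact
  repeat extension stops precisely at the planted boundaries, making
  coordinate recovery exact rather than probabilistically off by a base.

Problem sizes were chosen for quick, repeated desk runs: 3 × 120 kb
chromosomes with 38 genes for the annotated genome, 10 × 200 kb chromosomes
per parent for the cross (20 F1 scaffolds), a 17 kb plastome circle for
structure tests, and the published region lengths (159,915 bp circle) in
the acceptance script.

## Known limitations

* Type 2 chain resolution and the 90% boundary semantics are documented
  choices where upstream practice varies; both are configurable.
* The telomere and binning scores are stand-ins for external tools whose
  exact statistics are unpublished; they reproduce the tools' decisions in
  the regimes tested, not their internals.
* No SAM/BAM or alignment parsing: evidence arrives as BED, alignment
  summaries as PAF, both produced upstream.
* Approximate (mismatch-tolerant) IR detection and indel-aware cross
  simulation are out of scope.
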