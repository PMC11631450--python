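# orchardqc

A desk-scale QC toolkit for haplotype-phased plant genome assembly and
annotation projects — the kind of work behind recent chromosome-level apple
(*Malus domestica*) genomes, where a diploid F1 cultivar is assembled into
two parental haplomes and a draft annotation must be curated, tiered by
evidence, renamed, and sanity-checked against related genomes.

It is written for genome-project bioinformaticians who need the bespoke
steps between the big external tools (assemblers, repeat annotators, gene
predictors, orthogroup classifiers) as reusable, tested library code rather
than one-off scripts:

* **Gene-model curation** (`curation`) — three rule-based filters applied in
  order. Type 1: remove genes whose coding region (union of CDS over all
  isoforms, `C_g`) is ≥ 90% buried in repeats, i.e.
  `|C_g ∩ R| / |C_g| ≥ 0.9` for the merged repeat track `R`. Type 2:
  repeatedly remove the globally shortest gene (by genomic span) that
  overlaps another gene on the same strand. Type 3: split a gene whose
  isoform exon-footprint overlap graph is disconnected into one gene per
  connected component.
* **Evidence tiering** (`evidence`) — per-gene support flags (full/any RNA,
  full/any protein, functional annotation, orthogroup assignment) and the
  four nested stringency subsets S1 = full support, S2 = any support,
  S3 = S1 ∪ {functional ∧ orthogroup}, S4 = S1 ∪ {functional ∨ orthogroup};
  S1 ⊆ S2 and S1 ⊆ S3 ⊆ S4 by construction.
* **Nomenclature** (`nomenclature`) — GDR-convention identifiers such as
  `drMalDome.wa38.v1a1.ch10A.g00001.t1` (render/parse are exact inverses),
  per-chromosome gene numbering, and longest-isoform extraction.
* **Orthogroup QC** (`orthostats`) — core-orthogroup (CROG) gene-count
  matrices; per-row z-scores `z = (x − μ_row)/σ_row` with population σ and
  zero-σ rows dropped; deterministic average-linkage/Euclidean clustermap
  leaf orders; per-genome z-score summaries; exact UpSet membership-pattern
  counts and unique-orthogroup queries.
* **Haplome binning** (`haplobin`) — canonical k-mer (k = 21) containment
  against parent-specific marker sets (`A\B`, `B\A`); a scaffold is called
  for the parent winning the informative-k-mer vote, with configurable
  margin and count thresholds. Plus reference-guided chromosome
  renaming/orientation from PAF alignment summaries (majority aligned
  bases; reverse-complement when minus-strand bases dominate).
* **Sequence statistics** (`seqstats`) — N50/L50, GC, fold coverage
  (total bases / haploid genome size), and tidk-style terminal telomere
  scanning over unit lengths 2–20 with rotation+strand canonical unit
  classes (`AAACCCT` ≡ `AGGGTTT`).
* **Organelle structure** (`organelle`) — plastome quadripartite detection
  (longest exact reverse-complement repeat pair on the circle →
  LSC–IRb–SSC–IRa, total = LSC + SSC + 2·IR) and organelle gene tallies.
* **Fixtures** (`fixtures`) — seeded generators for every input above with
  machine-readable planted truth, including a two-parent cross at 1.35%
  divergence (typical apple heterozygosity).

## Worked example

Generate a synthetic annotated genome with planted errors, curate it, and
look at the assembly:

```text
$ orchardqc simulate genome --seed 11 --out fx
wrote genome fixture to fx

$ orchardqc curate --gff fx/annotation.gff3 --repeats fx/repeats.bed \
      --out curated.gff3 --report report.tsv
38 genes in; removed 3 (type 1), 2 (type 2); split 1 (type 3) -> 34 genes out

$ orchardqc stats fx/genome.fa
sequences       3
total_length    360000
N50     120000
L50     2
GC      0.3796

$ orchardqc telomere fx/genome.fa
sequence        end     unit    copies
chr01   5prime  AAACCCT 100

$ orchardqc coverage --bases 261.3e9 --genome-size 650e6
402.00 (402x)

$ orchardqc simulate plastome --seed 11 --out pl
$ orchardqc plastome pl/plastome.fa --min-ir 1000
plastome        LSC=10000       SSC=4000        IR=1500 total=17000
```

The curation line reads: of 38 input gene models, 3 were repeat-buried
transposon artefacts, 2 were the shorter members of same-strand overlapping
pairs, and 1 carried two disjoint isoform clusters and was split in two —
exactly the errors the generator planted (`fx/truth.json`). The telomere
line reports a 100-copy tandem array of the plant telomere unit class at
the 5′ end of chr01, and the plastome line recovers the planted
quadripartite region lengths. `orchardqc run --config pipeline.yaml` chains
the stages (curate → evidence → subset → rename → orthostats → haplobin →
stats) and writes a `report.json` with parameters and output digests.

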