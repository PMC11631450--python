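"""Seeded synthetic fixtures for every input the toolkit consumes.

Three generators, all deterministic for a fixed seed:

* :func:`simulate_annotated_genome` — chromosomes of random sequence at 38%
  GC (matching typical apple read composition) carrying non-overlapping
  gene models plus planted curation errors with machine-readable truth:
  repeat-buried genes (Type 1, CDS-in-repeat fraction >= 0.95, with
  configurable near-misses at <= 0.85), same-strand overlapping gene pairs
  (Type 2, the shorter partner nested in an intron of the longer), and
  genes whose isoforms form two disjoint clusters (Type 3).  Evidence
  tracks (RNA/protein BED) realize configured full / any-only / none
  support proportions exactly, and orthogroup tables with a controlled
  sharing structure are emitted for the comparative-QC module.
* :func:`simulate_cross` — a two-parent diploid cross: parent B derives
  from parent A by substitutions at the configured divergence (default
  1.35%, typical apple heterozygosity), and the F1 haplome scaffolds copy
  one parent each with a small assembly-error rate.
* :func:`simulate_plastome` — a circular plastome with an exact planted
  inverted-repeat pair and a feature table with configured gene-category
  counts.

Limitations: divergence is substitution-only (no indels/recombination) and
background sequence is i.i.d.; real repeat landscapes, GC heterogeneity
and alignment noise are out of scope here.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .annotation_io import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    RepeatTrack,
    TranscriptModel,
    UsageError,
    write_bed,
    write_gff3,
)
from .evidence import EvidenceCoverage
from .haplobin import revcomp
from .seqstats import write_fasta

_REPEAT_CLASSES = ("LTR/Copia", "LTR/Gypsy", "TIR/Mutator", "TIR/hAT", "Helitron")


@dataclass
class FixtureConfig:
    seed: int = 0
    # annotated genome
    n_chromosomes: int = 3
    chromosome_length: int = 120_000
    genes_per_chromosome: int = 12
    n_type1: int = 3
    n_type1_near_miss: int = 2
    n_type2_pairs: int = 2
    n_type3: int = 1
    repeat_density: float = 0.05
    full_support_fraction: float = 0.6
    any_support_fraction: float = 0.3
    functional_fraction: float = 0.8
    orthogroup_fraction: float = 0.8
    gc_content: float = 0.38
    # orthogroup sharing design (standalone comparative tables)
    og_genomes: tuple[str, ...] = ("genomeA", "genomeB", "genomeC", "genomeD")
    n_core_orthogroups: int = 25
    n_unique_orthogroups_per_genome: int = 5
    # cross
    divergence: float = 0.0135
    assembly_error_rate: float = 0.001
    cross_n_chromosomes: int = 10
    cross_chromosome_length: int = 200_000
    # telomere
    telomere_unit: str = "AAACCCT"
    telomere_copies: int = 100
    # plastome
    plastome_lsc: int = 10_000
    plastome_ssc: int = 4_000
    plastome_ir: int = 1_500
    plastome_rrna: int = 4
    plastome_trna: int = 20
    plastome_protein: int = 40

    def __post_init__(self):
        if self.full_support_fraction + self.any_support_fraction > 1 + 1e-9:
            raise UsageError("support fractions must sum to <= 1")
        if not (0 <= self.divergence <= 1):
            raise UsageError("divergence must be in [0, 1]")


@dataclass
class FixtureTruth:
    type1_ids: list[str] = field(default_factory=list)
    type1_near_miss_ids: list[str] = field(default_factory=list)
    type2_removed_ids: list[str] = field(default_factory=list)
    type2_kept_ids: list[str] = field(default_factory=list)
    type3_ids: list[str] = field(default_factory=list)
    evidence_class: dict[str, str] = field(default_factory=dict)
    orthogroup_patterns: dict[str, list[str]] = field(default_factory=dict)
    scaffold_origin: dict[str, str] = field(default_factory=dict)
    telomere: dict[str, list[str]] = field(default_factory=dict)
    plastome_regions: dict[str, list[int]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def random_sequence(rng: np.random.Generator, length: int,
                    gc: float = 0.38) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[rng.choice(4, size=length, p=p)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute bases at the given per-site rate (always to a new base)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    base_idx = np.full(256, 0, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        base_idx[b] = i
    sites = np.flatnonzero(rng.random(arr.size) < rate)
    shifts = rng.integers(1, 4, size=sites.size)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    arr[sites] = lut[(base_idx[arr[sites]] + shifts) % 4]
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Annotated genome
# ---------------------------------------------------------------------------


def _make_gene(gid: str, seqid: str, strand: str, start: int,
               kind: str) -> tuple[GeneModel, int]:
    """Build one gene starting at ``start``; returns (gene, end-of-locus)."""

    def exon(a, b):
        return GenomicInterval(seqid, a, b, strand)

    if kind == "type3":
        # two disjoint isoform clusters inside one nominal gene
        c1 = [exon(start, start + 600), exon(start + 800, start + 1200)]
        c2 = [exon(start + 3000, start + 3500), exon(start + 3700, start + 4100)]
        txs = [
            TranscriptModel(f"{gid}.t1", gid, exons=c1, cds=list(c1)),
            TranscriptModel(f"{gid}.t2", gid, exons=c2, cds=list(c2)),
        ]
        return GeneModel(gid, seqid, strand, txs), start + 4100
    if kind == "pair":
        # long gene with a large intron; the shorter partner nests inside it
        host_exons = [exon(start, start + 500), exon(start + 4500, start + 5000)]
        host = GeneModel(
            gid, seqid, strand,
            [TranscriptModel(f"{gid}.t1", gid, exons=host_exons,
                             cds=list(host_exons))],
        )
        nested_exons = [exon(start + 1500, start + 2200),
                        exon(start + 2600, start + 3200)]
        nested = GeneModel(
            gid + "n", seqid, strand,
            [TranscriptModel(f"{gid}n.t1", gid + "n", exons=nested_exons,
                             cds=list(nested_exons))],
        )
        return (host, nested), start + 5000  # type: ignore[return-value]
    # single-cluster gene, two overlapping isoforms for "normal"
    exons = [exon(start, start + 700), exon(start + 1100, start + 1700),
             exon(start + 2100, start + 2600)]
    txs = [TranscriptModel(f"{gid}.t1", gid, exons=exons, cds=list(exons))]
    if kind == "normal":
        iso2 = [exon(start, start + 700), exon(start + 1100, start + 1700)]
        txs.append(TranscriptModel(f"{gid}.t2", gid, exons=iso2, cds=list(iso2)))
    return GeneModel(gid, seqid, strand, txs), start + 2600


@dataclass
class AnnotatedGenomeFixture:
    sequences: list[tuple[str, str]]
    annotation: AnnotationSet
    repeats: RepeatTrack
    coverage: EvidenceCoverage
    functional_ids: set[str]
    orthogroup_ids: set[str]
    orthogroup_sets: dict[str, set[str]]
    assignments: dict[str, dict[str, str]]  # genome -> gene -> orthogroup
    truth: FixtureTruth


def simulate_annotated_genome(
    config: FixtureConfig | None = None, outdir: str | Path | None = None
) -> AnnotatedGenomeFixture:
    """Generate the annotated-genome fixture (optionally written to disk)."""
    config = config or FixtureConfig()
    rng = np.random.default_rng(config.seed)
    truth = FixtureTruth()

    n_special = (config.n_type1 + config.n_type1_near_miss
                 + config.n_type2_pairs + config.n_type3)
    total_slots = config.n_chromosomes * config.genes_per_chromosome
    if n_special > total_slots:
        raise UsageError(
            f"{n_special} planted features do not fit in {total_slots} gene slots"
        )

    # slot plan: one kind per slot, distributed round-robin over chromosomes
    kinds = (["type1"] * config.n_type1
             + ["near_miss"] * config.n_type1_near_miss
             + ["pair"] * config.n_type2_pairs
             + ["type3"] * config.n_type3)
    kinds += ["normal"] * (total_slots - len(kinds))
    rng.shuffle(kinds)

    genes: dict[str, GeneModel] = {}
    repeat_ivs: list[GenomicInterval] = []
    repeat_labels: list[str] = []
    sequence_regions: dict[str, int] = {}
    gaps: list[GenomicInterval] = []  # intergenic space for background repeats
    counter = 0
    slot_iter = iter(kinds)
    for c in range(config.n_chromosomes):
        seqid = f"chr{c + 1:02d}"
        sequence_regions[seqid] = config.chromosome_length
        cursor = 2_000
        for _ in range(config.genes_per_chromosome):
            kind = next(slot_iter)
            counter += 1
            gid = f"G{counter:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            build_kind = {"type1": "simple", "near_miss": "simple"}.get(kind, kind)
            made, end = _make_gene(gid, seqid, strand, cursor, build_kind)
            if end + 2_000 > config.chromosome_length:
                raise UsageError(
                    f"genes do not fit on {seqid}: increase chromosome_length"
                )
            if kind == "pair":
                host, nested = made  # type: ignore[misc]
                genes[host.id] = host
                genes[nested.id] = nested
                truth.type2_kept_ids.append(host.id)
                truth.type2_removed_ids.append(nested.id)
            else:
                gene = made  # type: ignore[assignment]
                genes[gene.id] = gene
                if kind == "type1":
                    truth.type1_ids.append(gene.id)
                    # cover ~97% of the coding region with one repeat
                    cds = gene.merged_cds()
                    total = sum(len(iv) for iv in cds)
                    skip = int(total * 0.03)
                    for iv in cds:
                        s = iv.start + min(skip, len(iv) - 1)
                        skip = max(0, skip - (s - iv.start))
                        if s < iv.end:
                            repeat_ivs.append(GenomicInterval(seqid, s, iv.end))
                            repeat_labels.append("LTR/Gypsy")
                elif kind == "near_miss":
                    truth.type1_near_miss_ids.append(gene.id)
                    # cover ~70% of the coding region (well under threshold)
                    for iv in gene.merged_cds():
                        mid = iv.start + int(len(iv) * 0.30)
                        repeat_ivs.append(GenomicInterval(seqid, mid, iv.end))
                        repeat_labels.append("LTR/Copia")
                elif kind == "type3":
                    truth.type3_ids.append(gene.id)
            gap_start = end + 200
            cursor = end + rng.integers(1_500, 3_000)
            if gap_start < cursor - 200:
                gaps.append(GenomicInterval(seqid, gap_start, cursor - 200))

    # background repeats confined to intergenic gaps
    for gap in gaps:
        if rng.random() < config.repeat_density * 10 and len(gap) > 400:
            s = gap.start + int(rng.integers(0, len(gap) - 300))
            e = min(gap.end, s + int(rng.integers(150, 300)))
            repeat_ivs.append(GenomicInterval(gap.seqid, s, e))
            repeat_labels.append(
                _REPEAT_CLASSES[int(rng.integers(0, len(_REPEAT_CLASSES)))]
            )

    annotation = AnnotationSet(genes=genes, source="fixture",
                               sequence_regions=sequence_regions)
    repeats = RepeatTrack(intervals=repeat_ivs, class_labels=repeat_labels)

    # evidence classes realized exactly; nested pair partners come last so a
    # "none" class never collides with coverage bleeding from their host gene
    ordered = (truth.type2_kept_ids
               + [g for g in sorted(genes) if g not in set(truth.type2_kept_ids)
                  and g not in set(truth.type2_removed_ids)]
               + truth.type2_removed_ids)
    n = len(ordered)
    n_full = round(config.full_support_fraction * n)
    n_any = round(config.any_support_fraction * n)
    coverage = EvidenceCoverage()
    for i, gid in enumerate(ordered):
        gene = genes[gid]
        if i < n_full:
            cls = "full"
            for iv in gene.merged_exons():
                coverage.rna.setdefault(gene.seqid, []).append(iv)
            for iv in gene.merged_cds():
                coverage.protein.setdefault(gene.seqid, []).append(iv)
        elif i < n_full + n_any:
            cls = "any"
            first = gene.merged_exons()[0]
            part = GenomicInterval(gene.seqid, first.start,
                                   min(first.start + 30, first.end))
            coverage.rna.setdefault(gene.seqid, []).append(part)
            coverage.protein.setdefault(gene.seqid, []).append(part)
        else:
            cls = "none"
        truth.evidence_class[gid] = cls

    # functional / orthogroup id lists for the fixture genome itself
    ordered_ids = sorted(genes)
    n_func = round(config.functional_fraction * len(ordered_ids))
    n_og = round(config.orthogroup_fraction * len(ordered_ids))
    functional_ids = set(ordered_ids[:n_func])
    orthogroup_ids = set(ordered_ids[:n_og])

    # standalone orthogroup sharing design across several genomes
    orthogroup_sets: dict[str, set[str]] = {g: set() for g in config.og_genomes}
    assignments: dict[str, dict[str, str]] = {g: {} for g in config.og_genomes}
    og_counter = 0

    def add_og(members: list[str]) -> None:
        nonlocal og_counter
        og_counter += 1
        og = f"OG{og_counter:04d}"
        truth.orthogroup_patterns[og] = sorted(members)
        for g in members:
            orthogroup_sets[g].add(og)
            for copy in range(int(rng.integers(1, 4))):
                assignments[g][f"{g}_gene{og_counter:04d}_{copy + 1}"] = og

    for _ in range(config.n_core_orthogroups):
        add_og(list(config.og_genomes))
    for g in config.og_genomes:
        for _ in range(config.n_unique_orthogroups_per_genome):
            add_og([g])

    # chromosome sequences, with the telomere unit planted at chr01's 5' end
    sequences: list[tuple[str, str]] = []
    for c in range(config.n_chromosomes):
        seqid = f"chr{c + 1:02d}"
        seq = random_sequence(rng, config.chromosome_length, config.gc_content)
        if c == 0 and config.telomere_copies > 0:
            tel = config.telomere_unit * config.telomere_copies
            seq = tel + seq[len(tel):]
            truth.telomere[seqid] = ["5prime", config.telomere_unit]
        sequences.append((seqid, seq))

    fixture = AnnotatedGenomeFixture(
        sequences=sequences, annotation=annotation, repeats=repeats,
        coverage=coverage, functional_ids=functional_ids,
        orthogroup_ids=orthogroup_ids, orthogroup_sets=orthogroup_sets,
        assignments=assignments, truth=truth,
    )
    if outdir is not None:
        _write_annotated_genome(fixture, Path(outdir))
    return fixture


def _write_annotated_genome(fx: AnnotatedGenomeFixture, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(fx.sequences, outdir / "genome.fa")
    write_gff3(fx.annotation, outdir / "annotation.gff3")
    write_bed(fx.repeats.intervals, outdir / "repeats.bed",
              names=fx.repeats.class_labels)
    rna = [iv for seqid in sorted(fx.coverage.rna) for iv in fx.coverage.rna[seqid]]
    prot = [iv for seqid in sorted(fx.coverage.protein)
            for iv in fx.coverage.protein[seqid]]
    write_bed(sorted(rna), outdir / "rna.bed")
    write_bed(sorted(prot), outdir / "protein.bed")
    (outdir / "functional_ids.txt").write_text(
        "\n".join(sorted(fx.functional_ids)) + "\n")
    (outdir / "orthogroup_ids.txt").write_text(
        "\n".join(sorted(fx.orthogroup_ids)) + "\n")
    for genome, mapping in fx.assignments.items():
        lines = [f"{gene}\t{og}" for gene, og in sorted(mapping.items())]
        (outdir / f"{genome}.orthogroups.tsv").write_text("\n".join(lines) + "\n")
    fx.truth.to_json(outdir / "truth.json")


# ---------------------------------------------------------------------------
# Two-parent cross
# ---------------------------------------------------------------------------


@dataclass
class CrossFixture:
    parent_a: list[tuple[str, str]]
    parent_b: list[tuple[str, str]]
    child_scaffolds: list[tuple[str, str]]
    truth: FixtureTruth


def simulate_cross(
    config: FixtureConfig | None = None, outdir: str | Path | None = None
) -> CrossFixture:
    """Simulate parents A/B and an F1 whose scaffolds copy one parent each."""
    config = config or FixtureConfig()
    rng = np.random.default_rng(config.seed)
    truth = FixtureTruth()

    parent_a = [
        (f"A_chr{i + 1:02d}",
         random_sequence(rng, config.cross_chromosome_length, config.gc_content))
        for i in range(config.cross_n_chromosomes)
    ]
    parent_b = [
        (f"B_chr{i + 1:02d}", _mutate(rng, seq, config.divergence))
        for i, (_, seq) in enumerate(parent_a)
    ]

    child: list[tuple[str, str]] = []
    sources = [("A", rec) for rec in parent_a] + [("B", rec) for rec in parent_b]
    order = rng.permutation(len(sources))
    for rank, idx in enumerate(order.tolist(), start=1):
        origin, (src_name, seq) = sources[idx]
        name = f"scaffold_{rank:02d}"
        child.append((name, _mutate(rng, seq, config.assembly_error_rate)))
        truth.scaffold_origin[name] = origin
    fixture = CrossFixture(parent_a, parent_b, child, truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(parent_a, outdir / "parentA.fa")
        write_fasta(parent_b, outdir / "parentB.fa")
        write_fasta(child, outdir / "child.fa")
        truth.to_json(outdir / "truth.json")
    return fixture


# ---------------------------------------------------------------------------
# Plastome
# ---------------------------------------------------------------------------


@dataclass
class PlastomeFixture:
    sequence: str
    features: list[tuple[str, str]]
    truth: FixtureTruth


def simulate_plastome(
    config: FixtureConfig | None = None, outdir: str | Path | None = None
) -> PlastomeFixture:
    """Circular plastome with an exact planted IR pair and a feature table."""
    config = config or FixtureConfig()
    rng = np.random.default_rng(config.seed)
    lsc = random_sequence(rng, config.plastome_lsc, config.gc_content)
    ssc = random_sequence(rng, config.plastome_ssc, config.gc_content)
    ir = random_sequence(rng, config.plastome_ir, config.gc_content)
    # pin the bases flanking the IR junctions so exact repeat extension stops
    # precisely at the planted boundaries (a base never complements itself)
    lsc = lsc[-1] + lsc[1:]
    ssc = ssc[:-1] + ssc[0]
    seq = lsc + ir + ssc + revcomp(ir)

    truth = FixtureTruth()
    n_lsc, n_ir, n_ssc = config.plastome_lsc, config.plastome_ir, config.plastome_ssc
    truth.plastome_regions = {
        "LSC": [0, n_lsc],
        "IRb": [n_lsc, n_lsc + n_ir],
        "SSC": [n_lsc + n_ir, n_lsc + n_ir + n_ssc],
        "IRa": [n_lsc + n_ir + n_ssc, n_lsc + 2 * n_ir + n_ssc],
    }
    features = (
        [(f"rrn{i + 1}", "rRNA") for i in range(config.plastome_rrna)]
        + [(f"trn{i + 1}", "tRNA") for i in range(config.plastome_trna)]
        + [(f"pcg{i + 1}", "protein_coding") for i in range(config.plastome_protein)]
    )
    fixture = PlastomeFixture(seq, features, truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta([("plastome", seq)], outdir / "plastome.fa")
        lines = ["gene\tcategory"] + [f"{n}\t{c}" for n, c in features]
        (outdir / "features.tsv").write_text("\n".join(lines) + "\n")
        truth.to_json(outdir / "truth.json")
    return fixture
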