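"""Evidence-source mapping and stringency subsets.

Each gene is screened against transcriptome (RNA) and homologous-protein
coverage tracks plus two external annotation signals (a functional
annotation hit and an orthogroup assignment).  Four nested-by-construction
stringency subsets are then extracted:

* Subset 1: full RNA or full protein support,
* Subset 2: any RNA or any protein support,
* Subset 3: Subset 1 plus genes with functional AND orthogroup annotation,
* Subset 4: Subset 1 plus genes with functional OR orthogroup annotation.

"Full" support means the evidence union covers 100% of the gene's exonic
footprint (RNA) or CDS footprint (protein); "any" means >= 1 bp overlap
with the genomic span.  S1 ⊆ S2, S1 ⊆ S3 ⊆ S4 always hold; S2 vs S3/S4
can go either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .annotation_io import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    StructuralError,
    UsageError,
    covers,
    overlap_bp,
    read_bed,
)


@dataclass(frozen=True)
class SupportFlags:
    full_rna: bool = False
    any_rna: bool = False
    full_protein: bool = False
    any_protein: bool = False
    has_functional: bool = False
    has_orthogroup: bool = False

    def __post_init__(self):
        if self.full_rna and not self.any_rna:
            raise ValueError("full_rna implies any_rna")
        if self.full_protein and not self.any_protein:
            raise ValueError("full_protein implies any_protein")


@dataclass
class EvidenceCoverage:
    """Per-seqid RNA and protein alignment coverage intervals (BED-derived)."""

    rna: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    protein: dict[str, list[GenomicInterval]] = field(default_factory=dict)

    @classmethod
    def from_bed(cls, rna_path=None, protein_path=None) -> "EvidenceCoverage":
        cov = cls()
        if rna_path is not None:
            for iv in read_bed(rna_path):
                cov.rna.setdefault(iv.seqid, []).append(iv)
        if protein_path is not None:
            for iv in read_bed(protein_path):
                cov.protein.setdefault(iv.seqid, []).append(iv)
        return cov


def compute_support(
    gene: GeneModel,
    coverage: EvidenceCoverage,
    has_functional: bool = False,
    has_orthogroup: bool = False,
) -> SupportFlags:
    """Evaluate the six support flags for one gene against the tracks."""
    rna = coverage.rna.get(gene.seqid, [])
    prot = coverage.protein.get(gene.seqid, [])
    span = [gene.span]
    exon_fp = gene.merged_exons()
    cds_fp = gene.merged_cds()

    any_rna = overlap_bp(rna, span) >= 1
    full_rna = any_rna and covers(rna, exon_fp)
    any_protein = overlap_bp(prot, span) >= 1
    # a gene without coding bases cannot have full protein support
    full_protein = any_protein and bool(cds_fp) and covers(prot, cds_fp)
    return SupportFlags(
        full_rna=full_rna,
        any_rna=any_rna,
        full_protein=full_protein,
        any_protein=any_protein,
        has_functional=has_functional,
        has_orthogroup=has_orthogroup,
    )


def compute_support_table(
    annotation: AnnotationSet,
    coverage: EvidenceCoverage,
    functional_ids: set[str] | None = None,
    orthogroup_ids: set[str] | None = None,
) -> dict[str, SupportFlags]:
    functional_ids = functional_ids or set()
    orthogroup_ids = orthogroup_ids or set()
    return {
        g.id: compute_support(
            g, coverage, g.id in functional_ids, g.id in orthogroup_ids
        )
        for g in annotation.sorted_genes()
    }


def select_subset(
    annotation: AnnotationSet,
    flags_by_gene: dict[str, SupportFlags],
    level: int,
) -> set[str]:
    """Gene ids belonging to stringency subset ``level`` (1..4)."""
    if level not in (1, 2, 3, 4):
        raise UsageError(f"unknown subset level {level}; expected 1..4")
    missing = sorted(set(annotation.genes) - set(flags_by_gene))
    if missing:
        raise StructuralError(f"missing support flags for genes: {', '.join(missing)}")

    def s1(f: SupportFlags) -> bool:
        return f.full_rna or f.full_protein

    members: set[str] = set()
    for gid in annotation.genes:
        f = flags_by_gene[gid]
        if level == 1:
            keep = s1(f)
        elif level == 2:
            keep = f.any_rna or f.any_protein
        elif level == 3:
            keep = s1(f) or (f.has_functional and f.has_orthogroup)
        else:
            keep = s1(f) or (f.has_functional or f.has_orthogroup)
        if keep:
            members.add(gid)
    return members


FLAG_COLUMNS = ("full_rna", "any_rna", "full_protein", "any_protein",
                "has_functional", "has_orthogroup")


def write_flags_tsv(flags_by_gene: dict[str, SupportFlags], path) -> None:
    lines = ["gene_id\t" + "\t".join(FLAG_COLUMNS)]
    for gid in sorted(flags_by_gene):
        f = flags_by_gene[gid]
        lines.append(
            gid + "\t" + "\t".join(str(int(getattr(f, c))) for c in FLAG_COLUMNS)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_flags_tsv(path) -> dict[str, SupportFlags]:
    flags: dict[str, SupportFlags] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[1:] != list(FLAG_COLUMNS):
            raise UsageError(f"unexpected flags header in {path}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            flags[parts[0]] = SupportFlags(
                **{c: bool(int(v)) for c, v in zip(FLAG_COLUMNS, parts[1:])}
            )
    return flags
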