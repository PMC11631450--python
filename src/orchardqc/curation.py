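"""Rule-based gene-model curation.

Three recurring classes of annotation error are handled, in order:

* **Type 1** — a transposon (or other repeat) mis-annotated as a gene.
  Removed when >= 90% (configurable) of the gene's coding region — the
  union of CDS intervals over all isoforms — falls inside repeat regions.
* **Type 2** — one locus annotated as several overlapping gene models on
  the same strand.  Resolved by repeatedly removing the globally shortest
  (by genomic span) gene that still overlaps another same-strand gene.
* **Type 3** — distinct genes mis-merged as splice variants of one model.
  Resolved by splitting each gene into the connected components of its
  isoform overlap graph (edges where merged exon footprints share >= 1 bp).

The pipeline is idempotent: curating an already-curated annotation is a
no-op with an all-zero report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .annotation_io import (
    AnnotationSet,
    GeneModel,
    RepeatTrack,
    covered_bp,
    overlap_bp,
)

logger = logging.getLogger("orchardqc")


@dataclass
class CurationConfig:
    """Thresholds and overlap bases for the three filters.

    repeat_fraction_threshold
        Minimum repeat-overlap fraction of the coding region at which a gene
        is treated as a repeat artefact; comparison is inclusive (>=).
    """

    repeat_fraction_threshold: float = 0.90
    overlap_basis_type2: str = "gene_span"
    isoform_overlap_basis: str = "exon_footprint"

    def __post_init__(self):
        if not (0 < self.repeat_fraction_threshold <= 1):
            raise ValueError("repeat_fraction_threshold must be in (0, 1]")


@dataclass
class CurationReport:
    n_input_genes: int = 0
    n_removed_type1: int = 0
    n_removed_type2: int = 0
    n_genes_split_type3: int = 0
    n_genes_created_type3: int = 0
    n_output_genes: int = 0
    type1_ids: list[str] = field(default_factory=list)
    type2_ids: list[str] = field(default_factory=list)
    type3_ids: list[str] = field(default_factory=list)

    def check(self) -> None:
        expected = (
            self.n_input_genes
            - self.n_removed_type1
            - self.n_removed_type2
            - self.n_genes_split_type3
            + self.n_genes_created_type3
        )
        if expected != self.n_output_genes:
            raise AssertionError(
                f"curation bookkeeping broken: expected {expected} output genes, "
                f"have {self.n_output_genes}"
            )
        if set(self.type1_ids) & set(self.type2_ids):
            raise AssertionError("a gene cannot be removed by both Type 1 and Type 2")


def repeat_overlap_fraction(gene: GeneModel, repeats: RepeatTrack) -> float:
    """Fraction of the gene's merged CDS covered by merged repeat regions.

    Genes without any coding base are flagged and treated as fraction 0.
    """
    cds = gene.merged_cds()
    cds_len = covered_bp(cds)
    if cds_len == 0:
        logger.warning("gene %s has no coding region; repeat fraction treated as 0",
                       gene.id)
        return 0.0
    merged_rep = repeats.merged(gene.seqid)
    if not merged_rep:
        return 0.0
    return overlap_bp(cds, merged_rep) / cds_len


def filter_type1(
    annotation: AnnotationSet,
    repeats: RepeatTrack,
    config: CurationConfig | None = None,
) -> tuple[AnnotationSet, list[str]]:
    """Drop genes whose coding region sits (almost) entirely in repeats."""
    config = config or CurationConfig()
    removed = [
        g.id
        for g in annotation.sorted_genes()
        if repeat_overlap_fraction(g, repeats) >= config.repeat_fraction_threshold
    ]
    kept = {gid: g for gid, g in annotation.genes.items() if gid not in set(removed)}
    return (
        AnnotationSet(genes=kept, source=annotation.source,
                      sequence_regions=dict(annotation.sequence_regions)),
        removed,
    )


def _span_overlap_pairs(genes: list[GeneModel]) -> set[frozenset[str]]:
    """Same-seqid, same-strand span overlaps (>=1 bp), by sweep."""
    pairs: set[frozenset[str]] = set()
    by_key: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        by_key.setdefault((g.seqid, g.strand), []).append(g)
    for group in by_key.values():
        group.sort(key=lambda g: (g.start, g.end))
        active: list[GeneModel] = []
        for g in group:
            active = [a for a in active if a.end > g.start]
            for a in active:
                pairs.add(frozenset((a.id, g.id)))
            active.append(g)
    return pairs


def filter_type2(
    annotation: AnnotationSet, config: CurationConfig | None = None
) -> tuple[AnnotationSet, list[str]]:
    """Resolve same-strand gene-span overlaps by shortest-first removal.

    While any two retained genes overlap on the same strand, the gene with
    the globally smallest span length among the currently-overlapping ones
    is removed; ties broken by larger start, then lexicographically smaller
    id.  Deterministic for arbitrary overlap chains.
    """
    genes = {g.id: g for g in annotation.genes.values()}
    removed: list[str] = []
    while True:
        pairs = _span_overlap_pairs(list(genes.values()))
        if not pairs:
            break
        involved = {gid for pair in pairs for gid in pair}
        victim = min(
            involved,
            key=lambda gid: (
                len(genes[gid].span),
                -genes[gid].start,
                gid,
            ),
        )
        removed.append(victim)
        del genes[victim]
    return (
        AnnotationSet(genes=genes, source=annotation.source,
                      sequence_regions=dict(annotation.sequence_regions)),
        removed,
    )


def _isoform_components(gene: GeneModel) -> list[list[int]]:
    """Connected components of the isoform exon-footprint overlap graph."""
    fps = [tr.exon_footprint() for tr in gene.transcripts]
    n = len(fps)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if overlap_bp(fps[i], fps[j]) >= 1:
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    out = list(comps.values())
    out.sort(key=lambda idxs: min(gene.transcripts[i].start for i in idxs))
    return out


def split_type3(annotation: AnnotationSet) -> tuple[AnnotationSet, dict[str, list[str]]]:
    """Split genes whose isoforms fall into disjoint overlap components.

    New gene ids are ``<original>.<k>`` with components numbered left to
    right by their leftmost transcript start.  Returns the new annotation
    and a map ``original id -> [new ids]`` for every split gene.
    """
    genes: dict[str, GeneModel] = {}
    split_map: dict[str, list[str]] = {}
    for gene in annotation.sorted_genes():
        comps = _isoform_components(gene)
        if len(comps) == 1:
            genes[gene.id] = gene
            continue
        new_ids = []
        for k, idxs in enumerate(comps, start=1):
            new_id = f"{gene.id}.{k}"
            txs = [gene.transcripts[i] for i in idxs]
            for tx in txs:
                tx.gene_id = new_id
            genes[new_id] = GeneModel(
                id=new_id, seqid=gene.seqid, strand=gene.strand, transcripts=txs
            )
            new_ids.append(new_id)
        split_map[gene.id] = new_ids
    return (
        AnnotationSet(genes=genes, source=annotation.source,
                      sequence_regions=dict(annotation.sequence_regions)),
        split_map,
    )


def curate(
    annotation: AnnotationSet,
    repeats: RepeatTrack,
    config: CurationConfig | None = None,
) -> tuple[AnnotationSet, CurationReport]:
    """Run the three filters in order (Type 1 -> Type 2 -> Type 3)."""
    config = config or CurationConfig()
    report = CurationReport(n_input_genes=len(annotation))

    after1, removed1 = filter_type1(annotation, repeats, config)
    report.n_removed_type1 = len(removed1)
    report.type1_ids = removed1

    after2, removed2 = filter_type2(after1, config)
    report.n_removed_type2 = len(removed2)
    report.type2_ids = removed2

    after3, split_map = split_type3(after2)
    report.n_genes_split_type3 = len(split_map)
    report.n_genes_created_type3 = sum(len(v) for v in split_map.values())
    report.type3_ids = sorted(split_map)

    report.n_output_genes = len(after3)
    report.check()
    logger.info(
        "curation: %d in, %d type1, %d type2, %d split -> %d out",
        report.n_input_genes, report.n_removed_type1, report.n_removed_type2,
        report.n_genes_split_type3, report.n_output_genes,
    )
    return after3, report


def write_report_tsv(report: CurationReport, path) -> None:
    """Tab-separated report: one row per affected gene plus a summary block."""
    lines = ["gene_id\taction"]
    lines += [f"{gid}\tremoved_type1" for gid in report.type1_ids]
    lines += [f"{gid}\tremoved_type2" for gid in report.type2_ids]
    lines += [f"{gid}\tsplit_type3" for gid in report.type3_ids]
    lines += [
        "#summary\t",
        f"#n_input_genes\t{report.n_input_genes}",
        f"#n_removed_type1\t{report.n_removed_type1}",
        f"#n_removed_type2\t{report.n_removed_type2}",
        f"#n_genes_split_type3\t{report.n_genes_split_type3}",
        f"#n_genes_created_type3\t{report.n_genes_created_type3}",
        f"#n_output_genes\t{report.n_output_genes}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
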