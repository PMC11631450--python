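"""GDR-convention gene/transcript identifiers and longest-isoform extraction.

Identifiers follow the Genome Database for Rosaceae convention, e.g.
``drMalDome.wa38.v1a1.ch10A.g00001.t1``: tree-of-life prefix, cultivar tag,
assembly/annotation version (vMAJaMIN), chromosome token (``chNN`` with an
optional haplome letter, or an unplaced token such as ``chun``), a 5-digit
zero-padded gene ordinal and a transcript ordinal.  Gene numbering restarts
at g00001 on every chromosome and increments by 1 in ascending span-start
order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from .annotation_io import (
    AnnotationSet,
    GeneModel,
    IdFormatError,
    TranscriptModel,
    UsageError,
)

_ID_RE = re.compile(
    r"^(?P<tol>[A-Za-z0-9]+)\."
    r"(?P<cultivar>[A-Za-z0-9_-]+)\."
    r"(?P<version>v\d+a\d+)\."
    r"(?P<chrom>ch[A-Za-z0-9]+)\."
    r"g(?P<gene>\d{5,})"
    r"(?:\.t(?P<tx>\d+))?$"
)


@dataclass(frozen=True)
class GeneIdentifier:
    tol_prefix: str
    cultivar: str
    version: str
    chromosome: str
    gene_ordinal: int
    transcript_ordinal: int | None = None

    def __post_init__(self):
        if self.gene_ordinal < 1:
            raise ValueError("gene_ordinal must be >= 1")
        if self.transcript_ordinal is not None and self.transcript_ordinal < 1:
            raise ValueError("transcript_ordinal must be >= 1")


def render_id(identifier: GeneIdentifier) -> str:
    base = (
        f"{identifier.tol_prefix}.{identifier.cultivar}.{identifier.version}."
        f"{identifier.chromosome}.g{identifier.gene_ordinal:05d}"
    )
    if identifier.transcript_ordinal is not None:
        base += f".t{identifier.transcript_ordinal}"
    return base


def parse_id(text: str) -> GeneIdentifier:
    """Invert :func:`render_id`; malformed strings raise :class:`IdFormatError`."""
    m = _ID_RE.match(text)
    if m is None:
        # name the failing token for actionable errors
        parts = text.split(".")
        if len(parts) >= 5 and re.fullmatch(r"g\d{1,4}", parts[4]):
            raise IdFormatError(
                f"gene ordinal token {parts[4]!r} violates 5-digit zero padding"
            )
        token = next(
            (p for i, p in enumerate(parts)
             if i == 2 and not re.fullmatch(r"v\d+a\d+", p)
             or i == 3 and not p.startswith("ch")),
            text,
        )
        raise IdFormatError(f"malformed identifier {text!r} (failing token {token!r})")
    tx = m.group("tx")
    return GeneIdentifier(
        tol_prefix=m.group("tol"),
        cultivar=m.group("cultivar"),
        version=m.group("version"),
        chromosome=m.group("chrom"),
        gene_ordinal=int(m.group("gene")),
        transcript_ordinal=int(tx) if tx is not None else None,
    )


def rename_annotation(
    annotation: AnnotationSet,
    tol_prefix: str,
    cultivar: str,
    version: str,
    chromosome_map: dict[str, str],
    unplaced_token: str | None = None,
) -> tuple[AnnotationSet, list[tuple[str, str]]]:
    """Re-identify every gene/transcript per the naming convention.

    ``chromosome_map`` maps assembly seqids to chromosome tokens (``ch01A``
    ...).  Genes are numbered per chromosome token in ascending span-start
    (then id) order; transcripts t1... in ascending start then id order.
    Returns the renamed annotation plus an old->new mapping table covering
    genes and transcripts.  Idempotent given the same ordering inputs.
    """
    missing = sorted(
        {g.seqid for g in annotation.genes.values()} - set(chromosome_map)
    )
    if missing and unplaced_token is None:
        raise UsageError(
            "no chromosome token for seqid(s) "
            + ", ".join(missing)
            + "; provide a chromosome map entry or an unplaced token"
        )

    by_token: dict[str, list[GeneModel]] = {}
    for gene in annotation.genes.values():
        token = chromosome_map.get(gene.seqid, unplaced_token)
        by_token.setdefault(token, []).append(gene)

    new_genes: dict[str, GeneModel] = {}
    mapping: list[tuple[str, str]] = []
    for token in sorted(by_token):
        genes = sorted(by_token[token], key=lambda g: (g.start, g.id))
        for ordinal, gene in enumerate(genes, start=1):
            gid = render_id(
                GeneIdentifier(tol_prefix, cultivar, version, token, ordinal)
            )
            mapping.append((gene.id, gid))
            new_txs = []
            txs = sorted(gene.transcripts, key=lambda t: (t.start, t.id))
            for t_ord, tx in enumerate(txs, start=1):
                tid = render_id(
                    GeneIdentifier(tol_prefix, cultivar, version, token, ordinal, t_ord)
                )
                mapping.append((tx.id, tid))
                new_txs.append(
                    TranscriptModel(
                        id=tid, gene_id=gid, exons=list(tx.exons),
                        cds=list(tx.cds), extra_lines=list(tx.extra_lines),
                    )
                )
            new_genes[gid] = GeneModel(
                id=gid, seqid=gene.seqid, strand=gene.strand, transcripts=new_txs
            )
    return (
        AnnotationSet(genes=new_genes, source=annotation.source,
                      sequence_regions=dict(annotation.sequence_regions)),
        mapping,
    )


def longest_isoform(annotation: AnnotationSet) -> AnnotationSet:
    """Keep, per gene, the isoform with the greatest spliced (summed-exon)
    length; ties broken by greater CDS length, then lexicographically
    smaller id.  Gene count is unchanged and intervals are untouched."""
    new_genes: dict[str, GeneModel] = {}
    for gene in annotation.genes.values():
        best = min(
            gene.transcripts,
            key=lambda t: (-t.spliced_length(), -t.cds_length(), t.id),
        )
        new_genes[gene.id] = replace(gene, transcripts=[best])
    return AnnotationSet(genes=new_genes, source=annotation.source,
                         sequence_regions=dict(annotation.sequence_regions))
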