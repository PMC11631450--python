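"""Genomic interval algebra and annotation I/O.

All coordinates inside the toolkit are 0-based, half-open ``[start, end)``.
GFF3 files (1-based, closed) are converted at the boundary on read/write;
BED files are already 0-based half-open and pass through unchanged.

The gene hierarchy is the minimal one the downstream curation filters need:
``GeneModel`` -> ``TranscriptModel`` -> exon/CDS intervals.  Feature lines
other than gene/mRNA/exon/CDS (UTRs and friends) are carried opaquely and
re-emitted verbatim; they never participate in filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from gffutils.feature import feature_from_line

logger = logging.getLogger("orchardqc")

STRANDS = ("+", "-", ".")

GENE_TYPES = frozenset({"gene"})
TRANSCRIPT_TYPES = frozenset({"mRNA", "transcript"})
SUBFEATURE_TYPES = frozenset({"exon", "CDS"})


class OrchardQCError(Exception):
    """Base class for toolkit errors."""


class GFF3ParseError(OrchardQCError):
    """A GFF3 line could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class StructuralError(OrchardQCError):
    """The parsed features do not form a valid gene/mRNA/exon hierarchy."""


class UsageError(OrchardQCError):
    """An operation was called with arguments outside its contract."""


class IdFormatError(OrchardQCError):
    """A rendered identifier does not follow the naming convention."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on one sequence."""

    seqid: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.seqid:
            raise ValueError("seqid must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seqid}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seqid == other.seqid
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """One transcript (isoform): sorted disjoint exons plus CDS segments."""

    id: str
    gene_id: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)
    extra_lines: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"transcript {self.id} has no exons")
        seqids = {iv.seqid for iv in self.exons} | {iv.seqid for iv in self.cds}
        strands = {iv.strand for iv in self.exons} | {iv.strand for iv in self.cds}
        if len(seqids) > 1 or len(strands) > 1:
            raise StructuralError(
                f"transcript {self.id}: intervals disagree on seqid/strand"
            )
        self.exons = merge_check_sorted_disjoint(self.exons, f"transcript {self.id} exons")
        self.cds = sorted(self.cds, key=lambda iv: (iv.start, iv.end))
        cds_fp = merge_intervals(self.cds) if self.cds else []
        if overlap_bp(cds_fp, merge_intervals(self.exons)) != covered_bp(cds_fp):
            raise StructuralError(
                f"transcript {self.id}: CDS footprint extends outside exons"
            )

    @property
    def seqid(self) -> str:
        return self.exons[0].seqid

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    def spliced_length(self) -> int:
        return sum(len(iv) for iv in self.exons)

    def cds_length(self) -> int:
        return covered_bp(merge_intervals(self.cds)) if self.cds else 0

    def exon_footprint(self) -> list[GenomicInterval]:
        return merge_intervals(self.exons)


@dataclass
class GeneModel:
    """One gene locus with >= 1 transcript."""

    id: str
    seqid: str
    strand: str
    transcripts: list[TranscriptModel]

    def __post_init__(self):
        if not self.transcripts:
            raise StructuralError(f"gene {self.id} has no transcripts")
        for tr in self.transcripts:
            if tr.seqid != self.seqid or tr.strand != self.strand:
                raise StructuralError(
                    f"gene {self.id}: transcript {tr.id} disagrees on seqid/strand"
                )
        ids = [tr.id for tr in self.transcripts]
        if len(set(ids)) != len(ids):
            raise StructuralError(f"gene {self.id}: duplicate transcript ids")

    @property
    def start(self) -> int:
        return min(tr.start for tr in self.transcripts)

    @property
    def end(self) -> int:
        return max(tr.end for tr in self.transcripts)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.seqid, self.start, self.end, self.strand)

    def merged_cds(self) -> list[GenomicInterval]:
        """Union of CDS intervals over all isoforms (the gene's coding region)."""
        segs = [iv for tr in self.transcripts for iv in tr.cds]
        return merge_intervals(segs) if segs else []

    def merged_exons(self) -> list[GenomicInterval]:
        segs = [iv for tr in self.transcripts for iv in tr.exons]
        return merge_intervals(segs)


@dataclass
class AnnotationSet:
    """A collection of genes keyed by id, plus carried header/extra lines."""

    genes: dict[str, GeneModel] = field(default_factory=dict)
    source: str = "orchardqc"
    sequence_regions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for gid, gene in self.genes.items():
            if gene.id != gid:
                raise StructuralError(f"gene keyed {gid} but carries id {gene.id}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def n_transcripts(self) -> int:
        return sum(len(g.transcripts) for g in self.genes.values())

    def sorted_genes(self) -> list[GeneModel]:
        return sorted(self.genes.values(), key=lambda g: (g.seqid, g.start, g.id))


@dataclass
class RepeatTrack:
    """Classified repeat intervals; overlaps between entries are allowed."""

    intervals: list[GenomicInterval] = field(default_factory=list)
    class_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.class_labels and len(self.class_labels) != len(self.intervals):
            raise ValueError("class_labels length must match intervals")
        if not self.class_labels:
            self.class_labels = ["repeat"] * len(self.intervals)

    def by_seqid(self, seqid: str) -> list[GenomicInterval]:
        return [iv for iv in self.intervals if iv.seqid == seqid]

    def merged(self, seqid: str) -> list[GenomicInterval]:
        return merge_intervals(self.by_seqid(seqid))


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------


def _require_single_seqid(intervals: Sequence[GenomicInterval], what: str) -> None:
    seqids = {iv.seqid for iv in intervals}
    if len(seqids) > 1:
        raise UsageError(f"{what}: intervals span multiple seqids {sorted(seqids)}")


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals on one seqid as a sorted, pairwise-disjoint list.

    Strand information is dropped (the union is strandless by construction).
    """
    if not intervals:
        return []
    _require_single_seqid(intervals, "merge_intervals")
    seqid = intervals[0].seqid
    pts = sorted((iv.start, iv.end) for iv in intervals)
    merged: list[tuple[int, int]] = [pts[0]]
    for s, e in pts[1:]:
        ls, le = merged[-1]
        if s <= le:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return [GenomicInterval(seqid, s, e) for s, e in merged]


def merge_check_sorted_disjoint(
    intervals: Sequence[GenomicInterval], what: str
) -> list[GenomicInterval]:
    out = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    for a, b in zip(out, out[1:]):
        if b.start < a.end:
            raise StructuralError(f"{what}: intervals overlap ({a} vs {b})")
    return out


def covered_bp(intervals: Sequence[GenomicInterval]) -> int:
    """Total bases covered by the union of the intervals."""
    return sum(len(iv) for iv in merge_intervals(list(intervals)))


def overlap_bp(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> int:
    """``|union(a) ∩ union(b)|`` in bases; both inputs on the same seqid."""
    if not a or not b:
        return 0
    _require_single_seqid(list(a) + list(b), "overlap_bp")
    ma, mb = merge_intervals(list(a)), merge_intervals(list(b))
    total = 0
    i = j = 0
    while i < len(ma) and j < len(mb):
        lo = max(ma[i].start, mb[j].start)
        hi = min(ma[i].end, mb[j].end)
        if lo < hi:
            total += hi - lo
        if ma[i].end <= mb[j].end:
            i += 1
        else:
            j += 1
    return total


def covers(cover: Sequence[GenomicInterval], target: Sequence[GenomicInterval]) -> bool:
    """True iff the union of *cover* contains every base of *target*."""
    t = covered_bp(target)
    return t == 0 or overlap_bp(cover, target) == t


# ---------------------------------------------------------------------------
# GFF3 I/O
# ---------------------------------------------------------------------------


def read_gff3(path: str | Path, source: str | None = None) -> AnnotationSet:
    """Parse a GFF3 file into an :class:`AnnotationSet`.

    Accepts both BRAKER- and PASA-style ID/Parent attribute dialects (any
    spec-conformant GFF3).  1-based closed coordinates become internal
    0-based half-open.  Features whose ``Parent`` does not resolve raise a
    :class:`StructuralError` listing the orphan ids.
    """
    path = Path(path)
    sequence_regions: dict[str, int] = {}
    file_source: str | None = None
    gene_rows: dict[str, dict] = {}
    tx_rows: dict[str, dict] = {}
    sub_rows: list[dict] = []
    extra_rows: list[dict] = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    sequence_regions[parts[1]] = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
                start0 = int(feat.start) - 1
                end0 = int(feat.end)
                if start0 < 0 or end0 <= start0:
                    raise ValueError(f"bad coordinates {feat.start}..{feat.end}")
            except GFF3ParseError:
                raise
            except Exception as exc:  # gffutils raises assorted types
                raise GFF3ParseError(str(exc), lineno) from exc
            if file_source is None and feat.source not in (".", ""):
                file_source = feat.source
            strand = feat.strand if feat.strand in ("+", "-") else "."
            fid = feat.attributes.get("ID", [None])[0]
            parents = list(feat.attributes.get("Parent", []))
            row = {
                "lineno": lineno,
                "type": feat.featuretype,
                "seqid": feat.seqid,
                "start": start0,
                "end": end0,
                "strand": strand,
                "id": fid,
                "parents": parents,
                "raw": line,
            }
            if feat.featuretype in GENE_TYPES:
                if fid is None:
                    raise GFF3ParseError("gene feature without ID", lineno)
                if fid in gene_rows:
                    raise StructuralError(f"duplicate gene id {fid}")
                gene_rows[fid] = row
            elif feat.featuretype in TRANSCRIPT_TYPES:
                if fid is None:
                    raise GFF3ParseError("transcript feature without ID", lineno)
                if fid in tx_rows:
                    raise StructuralError(f"duplicate transcript id {fid}")
                tx_rows[fid] = row
            elif feat.featuretype in SUBFEATURE_TYPES:
                sub_rows.append(row)
            else:
                extra_rows.append(row)

    # attach exon/CDS to transcripts
    children: dict[str, dict[str, list[GenomicInterval]]] = {
        tid: {"exon": [], "CDS": []} for tid in tx_rows
    }
    orphans: list[str] = []
    for row in sub_rows:
        if not row["parents"]:
            orphans.append(f"{row['type']}@line{row['lineno']}")
            continue
        for parent in row["parents"]:
            if parent not in tx_rows:
                orphans.append(f"{row['type']}@line{row['lineno']}->'{parent}'")
                continue
            children[parent][row["type"]].append(
                GenomicInterval(row["seqid"], row["start"], row["end"], row["strand"])
            )
    extra_by_tx: dict[str, list[str]] = {tid: [] for tid in tx_rows}
    loose_extra: list[str] = []
    for row in extra_rows:
        target = next((p for p in row["parents"] if p in tx_rows), None)
        if target is not None:
            extra_by_tx[target].append(row["raw"])
        else:
            loose_extra.append(row["raw"])
    if loose_extra:
        logger.warning("%d non-canonical features without mRNA parent dropped "
                       "from hierarchy (first: %s)", len(loose_extra), loose_extra[0])

    tx_by_gene: dict[str, list[TranscriptModel]] = {gid: [] for gid in gene_rows}
    for tid, row in tx_rows.items():
        gparents = [p for p in row["parents"] if p in gene_rows]
        if not gparents:
            orphans.append(f"mRNA:{tid}")
            continue
        try:
            tx = TranscriptModel(
                id=tid,
                gene_id=gparents[0],
                exons=children[tid]["exon"],
                cds=children[tid]["CDS"],
                extra_lines=extra_by_tx[tid],
            )
        except ValueError as exc:
            raise StructuralError(str(exc)) from exc
        tx_by_gene[gparents[0]].append(tx)

    if orphans:
        raise StructuralError(
            "features with unresolvable parents: " + ", ".join(sorted(orphans))
        )

    genes: dict[str, GeneModel] = {}
    for gid, row in gene_rows.items():
        txs = sorted(tx_by_gene[gid], key=lambda t: (t.start, t.id))
        if not txs:
            logger.warning("gene %s has no transcripts; dropped", gid)
            continue
        genes[gid] = GeneModel(
            id=gid, seqid=row["seqid"], strand=row["strand"], transcripts=txs
        )
    return AnnotationSet(
        genes=genes,
        source=source or file_source or path.name,
        sequence_regions=sequence_regions,
    )


def _fmt_attrs(**kv: str) -> str:
    return ";".join(f"{k}={v}" for k, v in kv.items() if v is not None)


def write_gff3(annotation: AnnotationSet, path: str | Path) -> None:
    """Write a deterministic, spec-conformant GFF3 (round-trips with read_gff3)."""
    path = Path(path)
    src = annotation.source or "orchardqc"
    lines = ["##gff-version 3"]
    for seqid in sorted(annotation.sequence_regions):
        lines.append(f"##sequence-region {seqid} 1 {annotation.sequence_regions[seqid]}")
    for gene in annotation.sorted_genes():
        lines.append(
            "\t".join(
                [gene.seqid, src, "gene", str(gene.start + 1), str(gene.end), ".",
                 gene.strand, ".", _fmt_attrs(ID=gene.id)]
            )
        )
        for tx in sorted(gene.transcripts, key=lambda t: (t.start, t.id)):
            lines.append(
                "\t".join(
                    [gene.seqid, src, "mRNA", str(tx.start + 1), str(tx.end), ".",
                     gene.strand, ".", _fmt_attrs(ID=tx.id, Parent=gene.id)]
                )
            )
            for iv in tx.exons:
                lines.append(
                    "\t".join(
                        [gene.seqid, src, "exon", str(iv.start + 1), str(iv.end), ".",
                         gene.strand, ".", _fmt_attrs(Parent=tx.id)]
                    )
                )
            for iv in tx.cds:
                lines.append(
                    "\t".join(
                        [gene.seqid, src, "CDS", str(iv.start + 1), str(iv.end), ".",
                         gene.strand, "0", _fmt_attrs(Parent=tx.id)]
                    )
                )
            lines.extend(tx.extra_lines)
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED I/O (native 0-based half-open)
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals; extra columns are ignored."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GFF3ParseError(f"BED line has {len(parts)} columns", lineno)
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
            try:
                out.append(
                    GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand)
                )
            except ValueError as exc:
                raise GFF3ParseError(str(exc), lineno) from exc
    return out


def read_repeat_bed(path: str | Path) -> RepeatTrack:
    """Read a repeat annotation BED; column 4 (name) is the repeat class."""
    intervals: list[GenomicInterval] = []
    labels: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
            intervals.append(
                GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand)
            )
            labels.append(parts[3] if len(parts) >= 4 else "repeat")
    return RepeatTrack(intervals=intervals, class_labels=labels)


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              names: Sequence[str] | None = None) -> None:
    path = Path(path)
    rows = []
    for i, iv in enumerate(intervals):
        name = names[i] if names else "."
        rows.append(f"{iv.seqid}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}")
    path.write_text("\n".join(rows) + ("\n" if rows else ""))


# quiet gffutils' own chatter; our logger reports what matters
logging.getLogger("gffutils").setLevel(logging.ERROR)
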