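import numpy as np
import pytest

from orchardqc import GeneModel, GenomicInterval, TranscriptModel


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def bitmap(intervals, size):
    """Per-base boolean occupancy — the brute-force oracle for interval math."""
    arr = np.zeros(size, dtype=bool)
    for iv in intervals:
        arr[iv.start:iv.end] = True
    return arr


def random_intervals(rng, n, size, seqid="chr1", max_len=40):
    out = []
    for _ in range(n):
        s = int(rng.integers(0, size - 1))
        e = s + int(rng.integers(1, max_len))
        out.append(GenomicInterval(seqid, s, min(e, size)))
    return out


def make_gene(gid, exon_groups, seqid="chr1", strand="+", cds_groups=None):
    """Build a gene whose transcripts have the given exon tuples.

    exon_groups: list (one per transcript) of lists of (start, end) tuples.
    CDS defaults to the exons themselves.
    """
    cds_groups = cds_groups if cds_groups is not None else exon_groups
    txs = []
    for i, (exons, cds) in enumerate(zip(exon_groups, cds_groups), start=1):
        txs.append(
            TranscriptModel(
                id=f"{gid}.t{i}",
                gene_id=gid,
                exons=[GenomicInterval(seqid, a, b, strand) for a, b in exons],
                cds=[GenomicInterval(seqid, a, b, strand) for a, b in cds],
            )
        )
    return GeneModel(id=gid, seqid=seqid, strand=strand, transcripts=txs)
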