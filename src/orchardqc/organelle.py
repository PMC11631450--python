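"""Plastome quadripartite-structure detection and organelle gene tallies.

A typical land-plant chloroplast genome is a circle tiled by four regions:
a long single-copy (LSC) region, a short single-copy (SSC) region, and two
inverted repeats (IRb, IRa) of identical length separating them, with IRa
the exact reverse complement of IRb.  ``detect_quadripartite`` finds the
longest pair of exact reverse-complement repeats on the circle by seed
k-mer matching plus maximal extension (the circle is handled by doubling
the sequence and reducing coordinates modulo its length), then labels the
longer inter-IR arc LSC and the shorter SSC.

``tally_genes`` counts annotated organelle genes per category
(protein-coding / tRNA / rRNA), with an explicit rule for multi-copy
genes: count every copy (the default) or deduplicate by gene name.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .annotation_io import UsageError
from .haplobin import revcomp

_ACGT = frozenset("ACGT")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class Region:
    """Circular region [start, end) modulo the sequence length."""

    start: int
    length: int

    def end(self, n: int) -> int:
        return (self.start + self.length) % n

    def extract(self, seq: str) -> str:
        n = len(seq)
        s = self.start % n
        if s + self.length <= n:
            return seq[s:s + self.length]
        return seq[s:] + seq[: (s + self.length) - n]


@dataclass
class QuadripartiteStructure:
    lsc_length: int
    ssc_length: int
    ir_length: int
    lsc: Region
    irb: Region
    ssc: Region
    ira: Region

    @property
    def total(self) -> int:
        return self.lsc_length + self.ssc_length + 2 * self.ir_length


def quadripartite_total(lsc: int, ssc: int, ir: int,
                        expected_total: int | None = None) -> int:
    """LSC + SSC + 2*IR, optionally checked against an independent total."""
    if min(lsc, ssc, ir) <= 0:
        raise UsageError("all region lengths must be positive")
    total = lsc + ssc + 2 * ir
    if expected_total is not None and expected_total != total:
        raise UsageError(
            f"quadripartite lengths sum to {total} but expected {expected_total}"
        )
    return total


def _extend_pair(D: str, i: int, j: int, seed: int, limit: int) -> tuple[int, int, int]:
    """Maximally extend a seed pair where D[j:j+seed] == revcomp(D[i:i+seed]).

    Returns (a, b, length): repeat copy 1 = D[a:a+length], copy 2 =
    D[b:b+length] with copy2 == revcomp(copy1).  Ambiguity symbols stop the
    extension.  ``limit`` caps the repeat length.
    """
    a1, b1 = i, i + seed       # copy 1 bounds [a1, b1)
    a2, b2 = j, j + seed       # copy 2 bounds
    n2 = len(D)
    # extend copy1 right <-> copy2 left
    while (b1 < n2 and a2 > 0 and b1 - a1 < limit
           and D[b1] in _ACGT and _COMP[D[b1]] == D[a2 - 1]):
        b1 += 1
        a2 -= 1
    # extend copy1 left <-> copy2 right
    while (a1 > 0 and b2 < n2 and b1 - a1 < limit
           and D[a1 - 1] in _ACGT and _COMP[D[a1 - 1]] == D[b2]):
        a1 -= 1
        b2 += 1
    return a1, a2, b1 - a1


def _circular_disjoint(s1: int, s2: int, length: int, n: int) -> bool:
    """True iff [s1, s1+len) and [s2, s2+len) do not overlap modulo n."""
    if 2 * length > n:
        return False
    gap = (s2 - s1) % n
    return length <= gap <= n - length


def detect_quadripartite(
    sequence: str, min_ir_length: int = 1000
) -> QuadripartiteStructure | None:
    """Locate the IR pair and the derived LSC/SSC arcs on a circular plastome.

    Returns ``None`` when no pair of exact reverse-complement repeats of at
    least ``min_ir_length`` with non-overlapping circular placements
    exists.  Rotation-invariant: any rotation of the input yields the same
    region lengths.
    """
    seq = sequence.upper()
    n = len(seq)
    if n == 0 or min_ir_length < 20:
        raise UsageError("need a non-empty sequence and min_ir_length >= 20")
    if n < 2 * min_ir_length:
        return None
    seed = min(min_ir_length, 64)
    D = seq + seq
    limit = n // 2  # two disjoint copies cannot each exceed half the circle

    index: dict[str, list[int]] = {}
    for i in range(n):
        index.setdefault(D[i:i + seed], []).append(i)

    covered = bytearray(n)
    best: tuple[int, int, int] | None = None  # (length, start1, start2)
    for j in range(n):
        if covered[j]:
            continue
        rw = revcomp(D[j:j + seed])
        for i0 in index.get(rw, []):
            for i in (i0, i0 + n):
                a1, a2, length = _extend_pair(D, i, j, seed, limit)
                if length < min_ir_length:
                    continue
                s1, s2 = a1 % n, a2 % n
                if not _circular_disjoint(s1, s2, length, n):
                    continue
                # mark both copies so later seeds inside them are skipped
                for start in (a1, a2):
                    for p in range(start, start + length):
                        covered[p % n] = 1
                if best is None or length > best[0]:
                    best = (length, s1, s2)
    if best is None:
        return None

    length, s1, s2 = best
    e1 = (s1 + length) % n
    e2 = (s2 + length) % n
    arc_12 = (s2 - e1) % n  # arc after copy1, before copy2
    arc_21 = (s1 - e2) % n  # arc after copy2, before copy1
    if arc_12 >= arc_21:
        # copy2 follows the longer (LSC) arc, so copy2 = IRb and copy1 = IRa
        lsc = Region(e1, arc_12)
        irb = Region(s2, length)
        ssc = Region(e2, arc_21)
        ira = Region(s1, length)
        lsc_len, ssc_len = arc_12, arc_21
    else:
        lsc = Region(e2, arc_21)
        irb = Region(s1, length)
        ssc = Region(e1, arc_12)
        ira = Region(s2, length)
        lsc_len, ssc_len = arc_21, arc_12

    structure = QuadripartiteStructure(
        lsc_length=lsc_len, ssc_length=ssc_len, ir_length=length,
        lsc=lsc, irb=irb, ssc=ssc, ira=ira,
    )
    assert structure.ira.extract(seq) == revcomp(structure.irb.extract(seq))
    return structure


# ---------------------------------------------------------------------------
# Gene tallies
# ---------------------------------------------------------------------------

CATEGORIES = ("protein_coding", "tRNA", "rRNA")


@dataclass
class GeneTally:
    protein_coding: int = 0
    tRNA: int = 0
    rRNA: int = 0

    @property
    def total(self) -> int:
        return self.protein_coding + self.tRNA + self.rRNA


def tally_genes(
    features: list[tuple[str, str]], dedup: str = "all_copies"
) -> GeneTally:
    """Count organelle genes per category from (gene name, category) rows.

    ``dedup="all_copies"`` counts every row (matching how multi-copy
    organelle genes are usually reported); ``dedup="unique_names"`` counts
    each (name, category) once.
    """
    if dedup not in ("all_copies", "unique_names"):
        raise UsageError(f"unknown dedup rule {dedup!r}")
    rows = features if dedup == "all_copies" else sorted(set(features))
    tally = GeneTally()
    for name, category in rows:
        if category not in CATEGORIES:
            raise UsageError(
                f"feature {name!r}: unknown category {category!r}; "
                f"expected one of {CATEGORIES}"
            )
        setattr(tally, category, getattr(tally, category) + 1)
    return tally


def read_feature_table(path: str | Path) -> list[tuple[str, str]]:
    """Two-column (gene name, category) TSV."""
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene\t"):
                continue
            name, category = line.split("\t")[:2]
            rows.append((name, category))
    return rows
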