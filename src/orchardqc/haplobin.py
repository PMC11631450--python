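"""k-mer haplome binning and reference-guided chromosome renaming/orientation.

A diploid F1 assembly phased into two haplomes can be attributed to its
parents by canonical k-mer content: k-mers private to one parent act as
markers, and each assembled chromosome is called for the parent whose
markers dominate its informative k-mers.  At ~1.35% parental sequence
divergence (typical apple heterozygosity) every 21-mer window has a good
chance of spanning a diagnostic site, so margins are large.

Canonical k-mers (min of a k-mer and its reverse complement) are stored as
sorted unique 2-bit-packed ``uint64`` codes (k <= 32), giving C-speed set
algebra on multi-megabase inputs.

Chromosome renaming/orientation consumes whole-genome alignment summaries
in PAF: each query scaffold is assigned the reference chromosome holding
the majority of its aligned bases, and is flipped when most of those bases
align to the minus strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .annotation_io import UsageError

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _c in zip(b"ACGT", range(4)):
    _BASE_CODE[_b] = _c
    _BASE_CODE[_b + 32] = _c  # lowercase

_CODE_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _unique_sorted(arr: np.ndarray) -> np.ndarray:
    """Sort-based unique (markedly faster than np.unique's hash path here)."""
    if arr.size == 0:
        return arr
    arr = np.sort(arr)
    keep = np.empty(arr.size, dtype=bool)
    keep[0] = True
    np.not_equal(arr[1:], arr[:-1], out=keep[1:])
    return arr[keep]


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (non-ACGT passed through)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class KmerSet:
    """Canonical k-mer collection as sorted unique uint64 codes."""

    k: int
    codes: np.ndarray  # sorted unique uint64

    def __post_init__(self):
        if not (3 <= self.k <= 32):
            raise UsageError(f"k must be in [3, 32], got {self.k}")

    def __len__(self) -> int:
        return int(self.codes.size)

    def __contains__(self, kmer: str) -> bool:
        if len(kmer) != self.k:
            return False
        code = _encode_kmer(kmer)
        if code is None:
            return False
        i = int(np.searchsorted(self.codes, code))
        return i < self.codes.size and int(self.codes[i]) == code

    def to_strings(self) -> set[str]:
        """Decode back to canonical k-mer strings (small sets only)."""
        return {_decode(code, self.k) for code in self.codes.tolist()}

    def intersection(self, other: "KmerSet") -> "KmerSet":
        self._check(other)
        return KmerSet(self.k, np.intersect1d(self.codes, other.codes,
                                              assume_unique=True))

    def difference(self, other: "KmerSet") -> "KmerSet":
        self._check(other)
        return KmerSet(self.k, np.setdiff1d(self.codes, other.codes,
                                            assume_unique=True))

    def union(self, other: "KmerSet") -> "KmerSet":
        self._check(other)
        return KmerSet(self.k,
                       _unique_sorted(np.concatenate([self.codes, other.codes])))

    def jaccard(self, other: "KmerSet") -> float:
        self._check(other)
        inter = len(self.intersection(other))
        union = len(self) + len(other) - inter
        return inter / union if union else 0.0

    def _check(self, other: "KmerSet") -> None:
        if self.k != other.k:
            raise UsageError(f"k mismatch: {self.k} vs {other.k}")


def _encode_kmer(kmer: str) -> int | None:
    code = 0
    rc = 0
    k = len(kmer)
    for i, ch in enumerate(kmer):
        v = int(_BASE_CODE[ord(ch) & 0xFF])
        if v == 255:
            return None
        code = (code << 2) | v
        rc |= (3 - v) << (2 * i)
    return min(code, rc)


def _decode(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append("ACGT"[(code >> shift) & 3])
    return "".join(out)


def canonical_kmers(sequence: str, k: int = 21) -> KmerSet:
    """All canonical k-mers of a sequence (windows with non-ACGT skipped).

    Vectorised: forward and reverse-complement codes are built by
    convolving the 2-bit base values with powers of four; the canonical
    code is the elementwise minimum.
    """
    if not (3 <= k <= 32):
        raise UsageError(f"k must be in [3, 32], got {k}")
    n = len(sequence)
    if n < k:
        return KmerSet(k, np.empty(0, dtype=np.uint64))
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    vals = _BASE_CODE[raw]
    valid = vals != 255
    v64 = np.where(valid, vals, 0).astype(np.uint64)

    # windows: w[i] = vals[i:i+k]; forward code sum v[i+j] * 4^(k-1-j)
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(v64, k)
    pow_f = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    pow_r = (np.uint64(4) ** np.arange(k, dtype=np.uint64))
    fwd = win @ pow_f
    rev = (np.uint64(3) - win) @ pow_r
    canon = np.minimum(fwd, rev)
    if not valid.all():
        ok = sliding_window_view(valid, k).all(axis=1)
        canon = canon[ok]
    return KmerSet(k, _unique_sorted(canon))


def kmerset_from_sequences(sequences: Iterable[tuple[str, str]],
                           k: int = 21) -> KmerSet:
    """Union of canonical k-mers over a genome's sequences."""
    parts = [canonical_kmers(seq, k).codes for _, seq in sequences]
    if not parts:
        return KmerSet(k, np.empty(0, dtype=np.uint64))
    return KmerSet(k, _unique_sorted(np.concatenate(parts)))


def containment(query: KmerSet, reference: KmerSet) -> float:
    """``|query ∩ reference| / |query|``."""
    if query.k != reference.k:
        raise UsageError(f"k mismatch: {query.k} vs {reference.k}")
    if len(query) == 0:
        raise UsageError("containment undefined for an empty query set")
    return len(query.intersection(reference)) / len(query)


@dataclass
class HaplomeCall:
    scaffold: str
    score_a: float
    score_b: float
    call: str  # "A" | "B" | "ambiguous"
    informative_kmers: int

    @property
    def margin(self) -> float:
        return abs(self.score_a - self.score_b)


def assign_haplomes(
    scaffolds: Iterable[tuple[str, str]],
    markers_a: KmerSet,
    markers_b: KmerSet | None = None,
    min_margin: float = 0.02,
    min_count: int = 1000,
    k: int | None = None,
) -> list[HaplomeCall]:
    """Call the parental origin of each scaffold from marker k-mers.

    Two-set mode (default): parent-specific markers are ``A \\ B`` and
    ``B \\ A``; a scaffold's informative k-mers are those hitting either
    specific set and scores are the fractions hitting each side (they sum
    to 1).  Single-reference mode (``markers_b`` None): score_a is the
    containment of the scaffold in the reference set, score_b is 0, and the
    informative count is the scaffold's total canonical k-mer count.

    A call is ``ambiguous`` iff the margin |score_a - score_b| is below
    ``min_margin`` or fewer than ``min_count`` informative k-mers exist.
    """
    k = k or markers_a.k
    if markers_b is not None and markers_b.k != markers_a.k:
        raise UsageError("marker sets must share k")
    if markers_b is not None:
        spec_a = markers_a.difference(markers_b)
        spec_b = markers_b.difference(markers_a)
    calls: list[HaplomeCall] = []
    for name, seq in scaffolds:
        kms = canonical_kmers(seq, k)
        if len(kms) == 0:
            calls.append(HaplomeCall(name, 0.0, 0.0, "ambiguous", 0))
            continue
        if markers_b is None:
            score_a = containment(kms, markers_a)
            score_b = 0.0
            informative = len(kms)
        else:
            hits_a = len(kms.intersection(spec_a))
            hits_b = len(kms.intersection(spec_b))
            informative = hits_a + hits_b
            if informative == 0:
                calls.append(HaplomeCall(name, 0.0, 0.0, "ambiguous", 0))
                continue
            score_a = hits_a / informative
            score_b = hits_b / informative
        margin = abs(score_a - score_b)
        if margin < min_margin or informative < min_count:
            call = "ambiguous"
        else:
            call = "A" if score_a > score_b else "B"
        calls.append(HaplomeCall(name, score_a, score_b, call, informative))
    return calls


# ---------------------------------------------------------------------------
# Reference-guided renaming and orientation (PAF input)
# ---------------------------------------------------------------------------


@dataclass
class PafRecord:
    query: str
    query_length: int
    strand: str
    target: str
    aligned_bases: int  # alignment block length (PAF column 11)


def read_paf(path: str | Path) -> list[PafRecord]:
    """Parse the PAF columns the orientation logic needs (first 12)."""
    records: list[PafRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise UsageError(f"PAF line {lineno}: expected >= 12 columns, "
                                 f"got {len(parts)}")
            try:
                records.append(
                    PafRecord(
                        query=parts[0],
                        query_length=int(parts[1]),
                        strand=parts[4],
                        target=parts[5],
                        aligned_bases=int(parts[10]),
                    )
                )
            except ValueError as exc:
                raise UsageError(f"PAF line {lineno}: {exc}") from exc
            if records[-1].strand not in "+-":
                raise UsageError(f"PAF line {lineno}: bad strand {parts[4]!r}")
    return records


@dataclass
class OrientationDecision:
    scaffold: str
    reference_chromosome: str  # "unplaced" when no candidate qualifies
    orientation: str  # "forward" | "reverse"
    aligned_fraction: dict[str, float] = field(default_factory=dict)


def orient_and_rename(
    records: Sequence[PafRecord], min_assign_fraction: float = 0.5
) -> list[OrientationDecision]:
    """Assign each query scaffold a reference chromosome and an orientation.

    Aligned bases are summed per reference chromosome; the argmax wins if
    its share of the scaffold's aligned bases reaches
    ``min_assign_fraction``, otherwise the scaffold is left "unplaced".
    Orientation is reverse iff minus-strand aligned bases to the assigned
    chromosome exceed plus-strand ones (ties -> forward).
    """
    per_query: dict[str, dict[str, dict[str, int]]] = {}
    for rec in records:
        tgt = per_query.setdefault(rec.query, {}).setdefault(
            rec.target, {"+": 0, "-": 0}
        )
        tgt[rec.strand] += rec.aligned_bases
    decisions: list[OrientationDecision] = []
    for query in sorted(per_query):
        by_target = per_query[query]
        totals = {t: v["+"] + v["-"] for t, v in by_target.items()}
        grand = sum(totals.values())
        fractions = {t: totals[t] / grand for t in totals} if grand else {}
        best = max(sorted(totals), key=lambda t: totals[t]) if totals else None
        if best is None or grand == 0 or fractions[best] < min_assign_fraction:
            decisions.append(
                OrientationDecision(query, "unplaced", "forward", fractions)
            )
            continue
        minus = by_target[best]["-"]
        plus = by_target[best]["+"]
        orientation = "reverse" if minus > plus else "forward"
        decisions.append(OrientationDecision(query, best, orientation, fractions))
    return decisions
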