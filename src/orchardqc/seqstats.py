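"""Assembly statistics, sequencing-coverage arithmetic, telomere scanning.

* ``assembly_stats`` — sequence count, total length, N50/L50, GC fraction
  (ambiguous bases excluded from the GC denominator).
* ``coverage_fold`` — fold coverage of a sequencing run given total bases
  and a haploid genome size, as both float and nearest integer.
* ``telomere_scan`` — terminal-window tandem-repeat search over unit
  lengths 2..20 (the plant telomere unit is typically the 7-mer AAACCCT /
  AGGGTTT class); units are reported as a canonical rotation class so
  every phase and strand of the same motif maps to one name.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .annotation_io import UsageError
from .haplobin import revcomp


@dataclass
class AssemblyStats:
    n_sequences: int
    total_length: int
    n50: int
    l50: int
    gc_fraction: float


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Linear FASTA read as (id, uppercase sequence) pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def n50_l50(lengths: Sequence[int]) -> tuple[int, int]:
    """N50 = smallest length among the longest sequences covering half the
    assembly; L50 = how many of them it takes."""
    if not lengths:
        raise UsageError("N50 of an empty assembly is undefined")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for i, length in enumerate(ordered, start=1):
        acc += length
        if acc >= half:
            return length, i
    raise AssertionError("unreachable")


def assembly_stats(sequences: Sequence[tuple[str, str]]) -> AssemblyStats:
    if not sequences:
        raise UsageError("assembly_stats requires at least one sequence")
    lengths = [len(seq) for _, seq in sequences]
    n50, l50 = n50_l50(lengths)
    gc = at = 0
    for _, seq in sequences:
        up = seq.upper()
        gc += up.count("G") + up.count("C")
        at += up.count("A") + up.count("T")
    denom = gc + at
    return AssemblyStats(
        n_sequences=len(sequences),
        total_length=sum(lengths),
        n50=n50,
        l50=l50,
        gc_fraction=gc / denom if denom else 0.0,
    )


def coverage_fold(total_bases: float, genome_size: float) -> tuple[float, int]:
    """Fold coverage (float, and rounded half away from zero)."""
    if genome_size <= 0:
        raise UsageError("genome size must be positive")
    fold = total_bases / genome_size
    return fold, int(math.floor(fold + 0.5))


# ---------------------------------------------------------------------------
# Telomere scanning
# ---------------------------------------------------------------------------


def canonical_rotation_class(unit: str) -> str:
    """Lexicographically minimal rotation over the unit and its reverse
    complement — one name per motif regardless of phase or strand."""
    candidates = []
    for s in (unit.upper(), revcomp(unit.upper())):
        candidates.extend(s[i:] + s[:i] for i in range(len(s)))
    return min(candidates)


@dataclass
class TelomereHit:
    sequence_id: str
    end: str  # "5prime" | "3prime"
    unit: str  # canonical rotation class
    copies: int

    def __post_init__(self):
        if not (2 <= len(self.unit) <= 20):
            raise ValueError("telomere unit length must be in [2, 20]")


def _best_tandem(window: str, min_unit: int, max_unit: int) -> tuple[str, int] | None:
    """Best (canonical unit class, tandem copies of the longest tract).

    For each unit length u, positions where ``s[i] == s[i+u]`` mark
    period-u tracts; a maximal matched run of length L is a tract of
    ``(L + u) // u`` non-overlapping tandem copies of the unit starting the
    run.  The class whose single longest tract holds the most copies wins;
    smaller unit lengths win ties, so a 7-mer motif is not reported as its
    14-mer doubling.  Scoring the longest tract (rather than a window-wide
    sum) keeps short-period background in random sequence from outscoring a
    genuine terminal repeat array.
    """
    n = len(window)
    arr = np.frombuffer(window.encode("ascii"), dtype=np.uint8)
    best: tuple[int, str] | None = None  # (copies, class)
    for u in range(min_unit, max_unit + 1):
        if n < 2 * u:
            break
        eq = arr[:-u] == arr[u:]
        if not eq.any():
            continue
        # maximal runs of True in eq
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for s, e in zip(starts.tolist(), ends.tolist()):
            run = e - s  # matched positions; repeat tract length = run + u
            copies = (run + u) // u
            if copies < 2:
                continue
            if best is None or copies > best[0]:
                best = (copies, canonical_rotation_class(window[s:s + u]))
    if best is None:
        return None
    return best[1], best[0]


def telomere_scan(
    sequence_id: str,
    sequence: str,
    min_unit: int = 2,
    max_unit: int = 20,
    window: int = 50_000,
    min_copies: int = 50,
) -> list[TelomereHit]:
    """Scan both terminal windows of a sequence for tandem repeat units.

    Returns at most one hit per end — the unit class with the highest
    non-overlapping tandem copy count — suppressing hits below
    ``min_copies``.
    """
    if min_unit < 2 or max_unit < min_unit:
        raise UsageError("need 2 <= min_unit <= max_unit")
    seq = sequence.upper()
    w = min(window, len(seq))
    hits: list[TelomereHit] = []
    for end, sub in (("5prime", seq[:w]), ("3prime", seq[-w:])):
        found = _best_tandem(sub, min_unit, max_unit)
        if found is None:
            continue
        unit, copies = found
        if copies >= min_copies:
            hits.append(TelomereHit(sequence_id, end, unit, copies))
    return hits


def telomere_scan_assembly(
    sequences: Sequence[tuple[str, str]], **kwargs
) -> list[TelomereHit]:
    hits: list[TelomereHit] = []
    for name, seq in sequences:
        hits.extend(telomere_scan(name, seq, **kwargs))
    return hits
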