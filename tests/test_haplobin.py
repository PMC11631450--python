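"""Canonical k-mers, containment, haplome binning and PAF orientation."""

import numpy as np
import pytest

from orchardqc import (
    FixtureConfig,
    KmerSet,
    UsageError,
    assign_haplomes,
    canonical_kmers,
    containment,
    kmerset_from_sequences,
    orient_and_rename,
    read_paf,
    revcomp,
    simulate_cross,
)
from orchardqc.fixtures import random_sequence
from orchardqc.haplobin import PafRecord


def brute_canonical(seq, k):
    """Independent string-set oracle for canonical k-mer enumeration."""
    out = set()
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k].upper()
        if set(w) <= set("ACGT"):
            out.add(min(w, revcomp(w)))
    return out


class TestCanonicalKmers:
    def test_palindrome_and_short_sequence(self):
        ks = canonical_kmers("ACGT", 4)
        assert ks.to_strings() == {"ACGT"}
        assert len(canonical_kmers("ACG", 4)) == 0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            seq = random_sequence(rng, 2000)
            for k in (5, 15, 21):
                assert canonical_kmers(seq, k).to_strings() == \
                    brute_canonical(seq, k)

    def test_non_acgt_windows_skipped(self):
        seq = "ACGTNACGTA"
        got = canonical_kmers(seq, 4).to_strings()
        assert got == brute_canonical(seq, 4)
        assert all("N" not in kmer for kmer in got)

    def test_strand_symmetry(self, rng):
        seq = random_sequence(rng, 3000)
        fwd = canonical_kmers(seq, 21)
        rev = canonical_kmers(revcomp(seq), 21)
        assert np.array_equal(fwd.codes, rev.codes)

    def test_k_bounds_validated(self):
        with pytest.raises(UsageError):
            canonical_kmers("ACGT" * 20, 2)
        with pytest.raises(UsageError):
            canonical_kmers("ACGT" * 20, 33)


class TestContainment:
    def test_extremes(self, rng):
        seq = random_sequence(rng, 5000)
        whole = canonical_kmers(seq, 21)
        part = canonical_kmers(seq[:1000], 21)
        assert containment(part, whole) == 1.0
        other = canonical_kmers(random_sequence(rng, 5000), 21)
        assert containment(part, other) < 0.01

    def test_matches_brute_force(self, rng):
        a = random_sequence(rng, 800)
        b = a[:400] + random_sequence(rng, 400)
        ka, kb = canonical_kmers(a, 11), canonical_kmers(b, 11)
        sa, sb = brute_canonical(a, 11), brute_canonical(b, 11)
        assert containment(ka, kb) == pytest.approx(len(sa & sb) / len(sa))

    def test_k_mismatch_and_empty_query_rejected(self):
        a = canonical_kmers("ACGTACGTACGT", 5)
        b = canonical_kmers("ACGTACGTACGT", 7)
        with pytest.raises(UsageError):
            containment(a, b)
        empty = KmerSet(5, np.empty(0, dtype=np.uint64))
        with pytest.raises(UsageError):
            containment(empty, a)


class TestAssignHaplomes:
    def test_pure_parent_scaffold_has_zero_opposite_score(self, rng):
        a = random_sequence(rng, 30_000)
        b = random_sequence(rng, 30_000)
        ka, kb = canonical_kmers(a, 21), canonical_kmers(b, 21)
        calls = assign_haplomes([("s", a[:10_000])], ka, kb, min_count=100)
        assert calls[0].call == "A"
        assert calls[0].score_b == 0.0
        assert calls[0].margin == pytest.approx(calls[0].score_a)

    def test_identical_scores_ambiguous(self, rng):
        seq = random_sequence(rng, 5000)
        shared = canonical_kmers(seq, 21)
        calls = assign_haplomes([("s", seq)], shared, shared, min_count=1)
        assert calls[0].call == "ambiguous"

    def test_simulated_f1_fully_recovered(self):
        fx = simulate_cross(FixtureConfig(seed=7))
        ka = kmerset_from_sequences(fx.parent_a)
        kb = kmerset_from_sequences(fx.parent_b)
        calls = assign_haplomes(fx.child_scaffolds, ka, kb)
        assert len(calls) == 20
        for c in calls:
            assert c.call == fx.truth.scaffold_origin[c.scaffold]
            assert c.margin > 0.5

    def test_zero_divergence_is_uninformative(self):
        cfg = FixtureConfig(seed=3, divergence=0.0, cross_n_chromosomes=2,
                            cross_chromosome_length=30_000)
        fx = simulate_cross(cfg)
        ka = kmerset_from_sequences(fx.parent_a)
        kb = kmerset_from_sequences(fx.parent_b)
        calls = assign_haplomes(fx.child_scaffolds, ka, kb)
        assert all(c.call == "ambiguous" for c in calls)

    def test_jaccard_decreases_with_divergence(self):
        jaccards = []
        for d in (0.001, 0.005, 0.0135, 0.03, 0.05):
            cfg = FixtureConfig(seed=11, divergence=d, cross_n_chromosomes=1,
                                cross_chromosome_length=50_000)
            fx = simulate_cross(cfg)
            ka = kmerset_from_sequences(fx.parent_a)
            kb = kmerset_from_sequences(fx.parent_b)
            jaccards.append(ka.jaccard(kb))
        assert jaccards == sorted(jaccards, reverse=True)


class TestOrientation:
    def _paf_line(self, q, qlen, strand, t, blocklen):
        return (f"{q}\t{qlen}\t0\t{blocklen}\t{strand}\t{t}\t50000\t0"
                f"\t{blocklen}\t{blocklen}\t{blocklen}\t60")

    def test_majority_rules(self, tmp_path):
        p = tmp_path / "aln.paf"
        p.write_text("\n".join([
            self._paf_line("scaf1", 40000, "-", "chr10", 30000),
            self._paf_line("scaf1", 40000, "+", "chr10", 2000),
            self._paf_line("scaf1", 40000, "+", "chr03", 4000),
        ]) + "\n")
        decisions = orient_and_rename(read_paf(p))
        d = decisions[0]
        assert d.reference_chromosome == "chr10"
        assert d.orientation == "reverse"

    def test_below_fraction_unplaced_and_tie_forward(self):
        recs = [
            PafRecord("s", 1000, "+", "chrA", 100),
            PafRecord("s", 1000, "-", "chrB", 100),
            PafRecord("s", 1000, "+", "chrC", 100),
        ]
        d = orient_and_rename(recs, min_assign_fraction=0.5)[0]
        assert d.reference_chromosome == "unplaced"
        tie = [PafRecord("s", 1000, "+", "chrA", 100),
               PafRecord("s", 1000, "-", "chrA", 100)]
        assert orient_and_rename(tie)[0].orientation == "forward"

    def test_shuffled_flipped_fixture_recovered(self, rng):
        truth = {}
        records = []
        chroms = [f"chr{i:02d}" for i in range(1, 9)]
        names = [f"scaffold_{i}" for i in range(1, 9)]
        perm = rng.permutation(8)
        for name, ci in zip(names, perm.tolist()):
            flipped = bool(rng.integers(2))
            truth[name] = (chroms[ci], "reverse" if flipped else "forward")
            major, minor = ("-", "+") if flipped else ("+", "-")
            records.append(PafRecord(name, 10_000, major, chroms[ci], 8000))
            records.append(PafRecord(name, 10_000, minor, chroms[ci], 500))
            records.append(PafRecord(name, 10_000, "+",
                                     chroms[(ci + 1) % 8], 300))
        for d in orient_and_rename(records):
            assert (d.reference_chromosome, d.orientation) == truth[d.scaffold]

    def test_malformed_paf_names_line(self, tmp_path):
        p = tmp_path / "bad.paf"
        p.write_text("q\t100\t0\t50\t+\tt\t200\n")
        with pytest.raises(UsageError, match="line 1"):
            read_paf(p)
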