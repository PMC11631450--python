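"""Orthogroup count matrix, z-scores, clustering order and UpSet counts."""

import math

import numpy as np
import pandas as pd
import pytest

from orchardqc import (
    OrthogroupAssignment,
    UsageError,
    build_crog_matrix,
    cluster_order,
    simulate_annotated_genome,
    unique_orthogroups,
    upset_counts,
    zscore_normalize,
    zscore_summary,
)


def asn(genome, mapping):
    return OrthogroupAssignment(genome=genome, gene_to_orthogroup=mapping)


class TestCountMatrix:
    def test_counts_by_definition(self):
        mat = build_crog_matrix(
            [asn("g", {"g1": "o1", "g2": "o1", "g3": "o2"})]
        )
        assert mat.loc["o1", "g"] == 2 and mat.loc["o2", "g"] == 1

    def test_universe_rows_kept_as_zero(self):
        mat = build_crog_matrix([asn("g", {"g1": "o1"})],
                                orthogroup_universe=["o1", "o9"])
        assert mat.loc["o9", "g"] == 0

    def test_column_sums_equal_assigned_genes(self, rng):
        assignments = []
        for gi in range(4):
            n = int(rng.integers(10, 300))
            mapping = {f"g{gi}_{i}": f"OG{int(rng.integers(0, 40)):03d}"
                       for i in range(n)}
            assignments.append(asn(f"genome{gi}", mapping))
        mat = build_crog_matrix(assignments)
        for a in assignments:
            assert mat[a.genome].sum() == len(a.gene_to_orthogroup)

    def test_duplicate_genome_labels_rejected(self):
        with pytest.raises(UsageError):
            build_crog_matrix([asn("g", {}), asn("g", {})])


class TestZScore:
    def test_closed_form_row(self):
        mat = pd.DataFrame([[2, 4, 6]], index=["o1"], columns=list("abc"))
        z, dropped = zscore_normalize(mat)
        sd = math.sqrt(8 / 3)  # population SD of (2,4,6)
        assert dropped == []
        assert z.loc["o1"].tolist() == pytest.approx(
            [-2 / sd, 0.0, 2 / sd], abs=1e-12)
        assert z.loc["o1", "a"] == pytest.approx(-1.2247, abs=5e-5)

    def test_constant_and_all_zero_rows_dropped(self):
        mat = pd.DataFrame([[5, 5, 5], [0, 0, 0], [1, 2, 3]],
                           index=["const", "zero", "ok"], columns=list("abc"))
        z, dropped = zscore_normalize(mat)
        assert sorted(dropped) == ["const", "zero"]
        assert list(z.index) == ["ok"]

    def test_rows_standardized_within_tolerance(self, rng):
        mat = pd.DataFrame(rng.integers(0, 20, size=(40, 6)))
        z, _ = zscore_normalize(mat)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.to_numpy().std(axis=1, ddof=0), 1, atol=1e-9)

    def test_shift_invariance_and_scale_equivariance(self, rng):
        mat = pd.DataFrame(rng.integers(0, 50, size=(20, 5)).astype(float))
        z0, _ = zscore_normalize(mat)
        z_shift, _ = zscore_normalize(mat + 7)
        z_scale, _ = zscore_normalize(mat * 3)
        assert np.allclose(z0, z_shift, atol=1e-9)
        assert np.allclose(z0, z_scale, atol=1e-9)

    def test_single_column_rejected(self):
        with pytest.raises(UsageError):
            zscore_normalize(pd.DataFrame({"only": [1, 2]}))


class TestClusterOrder:
    def test_duplicate_columns_end_up_adjacent(self, rng):
        base = pd.DataFrame(rng.normal(size=(12, 4)),
                            columns=["w", "x", "y", "z"])
        base["x"] = base["w"]  # zero distance pair merges first
        rows, cols = cluster_order(base)
        assert abs(cols.index("w") - cols.index("x")) == 1

    def test_planted_two_group_split_recovered(self, rng):
        left = rng.normal(loc=-3, size=(30, 3))
        right = rng.normal(loc=+3, size=(30, 3))
        mat = pd.DataFrame(np.hstack([left, right]),
                           columns=["a1", "a2", "a3", "b1", "b2", "b3"])
        _, cols = cluster_order(mat)
        groups = ["a" if c.startswith("a") else "b" for c in cols]
        assert groups in (["a"] * 3 + ["b"] * 3, ["b"] * 3 + ["a"] * 3)

    def test_too_small_matrix_rejected(self):
        with pytest.raises(UsageError):
            cluster_order(pd.DataFrame([[1.0, 2.0]]))

    def test_deterministic(self, rng):
        mat = pd.DataFrame(rng.normal(size=(15, 5)))
        assert cluster_order(mat) == cluster_order(mat.copy())


class TestSummary:
    def test_two_column_means_are_negatives(self, rng):
        mat = pd.DataFrame(rng.integers(0, 9, size=(25, 2)).astype(float))
        mat = mat.loc[mat.std(axis=1, ddof=0) > 0]
        z, _ = zscore_normalize(mat)
        s = zscore_summary(z)
        assert s["mean"].iloc[0] == pytest.approx(-s["mean"].iloc[1], abs=1e-9)

    def test_hand_computed_column_means(self):
        z, _ = zscore_normalize(pd.DataFrame(
            [[1, 2, 3], [4, 6, 8], [10, 10, 13]], columns=list("abc")))
        s = zscore_summary(z)
        expected = z.mean(axis=0)
        for col in "abc":
            assert s.loc[col, "mean"] == pytest.approx(expected[col])
        # grand mean over all cells is 0 because every row is centred
        assert z.to_numpy().mean() == pytest.approx(0, abs=1e-9)


class TestUpset:
    def test_two_set_example(self):
        counts = upset_counts({"A": {"o1", "o2"}, "B": {"o2", "o3"}})
        assert counts == {
            frozenset({"A"}): 1, frozenset({"B"}): 1, frozenset({"A", "B"}): 1,
        }
        assert sum(counts.values()) == 3

    def test_partition_against_brute_force(self, rng):
        universe = [f"OG{i:04d}" for i in range(500)]
        sets = {
            f"genome{j}": {og for og in universe if rng.random() < 0.4}
            for j in range(6)
        }
        counts = upset_counts(sets)
        union = set().union(*sets.values())
        assert sum(counts.values()) == len(union)
        brute: dict[frozenset, int] = {}
        for og in union:
            key = frozenset(g for g, s in sets.items() if og in s)
            brute[key] = brute.get(key, 0) + 1
        assert counts == brute

    def test_unique_orthogroups_matches_definition(self, rng):
        sets = {
            f"g{j}": {f"OG{int(i):03d}" for i in rng.integers(0, 60, size=30)}
            for j in range(5)
        }
        focal = ["g0", "g1"]
        got = unique_orthogroups(sets, focal)
        expected = {
            og for og in set().union(*sets.values())
            if all(og in sets[g] for g in focal)
            and all(og not in sets[g] for g in sets if g not in focal)
        }
        assert got == expected
        assert unique_orthogroups(sets, list(sets)) == \
            set.intersection(*sets.values())
        with pytest.raises(UsageError):
            unique_orthogroups(sets, ["nope"])

    def test_fixture_sharing_design_recovered(self):
        fx = simulate_annotated_genome()
        counts = upset_counts(fx.orthogroup_sets)
        all_genomes = frozenset(fx.orthogroup_sets)
        assert counts[all_genomes] == 25
        for g in fx.orthogroup_sets:
            assert counts[frozenset({g})] == 5
            assert unique_orthogroups(fx.orthogroup_sets, [g]) == {
                og for og, members in fx.truth.orthogroup_patterns.items()
                if members == [g]
            }
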