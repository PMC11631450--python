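"""Gene-model error filters: repeat burial, same-strand overlap, disjoint isoforms."""

import networkx as nx
import pytest

from orchardqc import (
    AnnotationSet,
    GenomicInterval,
    RepeatTrack,
    CurationConfig,
    curate,
    filter_type1,
    filter_type2,
    overlap_bp,
    repeat_overlap_fraction,
    simulate_annotated_genome,
    split_type3,
)
from orchardqc.curation import _span_overlap_pairs

from conftest import bitmap, make_gene, random_intervals


def annotation_of(*genes):
    return AnnotationSet(genes={g.id: g for g in genes})


class TestRepeatFraction:
    def test_no_repeats_is_zero(self):
        g = make_gene("g", [[(100, 200)]])
        assert repeat_overlap_fraction(g, RepeatTrack()) == 0.0

    def test_cds_inside_repeat_is_one(self):
        g = make_gene("g", [[(100, 200)]])
        track = RepeatTrack(intervals=[GenomicInterval("chr1", 50, 300)])
        assert repeat_overlap_fraction(g, track) == 1.0

    def test_zero_cds_gene_treated_as_zero(self):
        g = make_gene("g", [[(100, 200)]], cds_groups=[[]])
        track = RepeatTrack(intervals=[GenomicInterval("chr1", 0, 1000)])
        assert repeat_overlap_fraction(g, track) == 0.0

    def test_matches_bitmap_oracle(self, rng):
        for _ in range(100):
            n_ex = int(rng.integers(1, 4))
            exons, pos = [], int(rng.integers(0, 100))
            for _ in range(n_ex):
                end = pos + int(rng.integers(20, 80))
                exons.append((pos, end))
                pos = end + int(rng.integers(10, 50))
            g = make_gene("g", [exons])
            reps = random_intervals(rng, int(rng.integers(0, 15)), 600, max_len=120)
            track = RepeatTrack(intervals=reps)
            cds_map = bitmap(g.merged_cds(), 1000)
            rep_map = bitmap(reps, 1000)
            expected = (cds_map & rep_map).sum() / cds_map.sum()
            assert repeat_overlap_fraction(g, track) == pytest.approx(expected)


class TestType1:
    def _gene_with_fraction(self, frac):
        g = make_gene("g", [[(0, 100)]])
        cov = int(100 * frac)
        track = RepeatTrack(intervals=[GenomicInterval("chr1", 0, cov)]) if cov \
            else RepeatTrack()
        return g, track

    @pytest.mark.parametrize("frac,removed", [(0.95, True), (0.90, True),
                                              (0.89, False), (0.0, False)])
    def test_threshold_is_inclusive(self, frac, removed):
        g, track = self._gene_with_fraction(frac)
        _, gone = filter_type1(annotation_of(g), track)
        assert (g.id in gone) == removed

    def test_planted_fixture_exact_recovery(self):
        fx = simulate_annotated_genome()
        kept, removed = filter_type1(fx.annotation, fx.repeats)
        assert sorted(removed) == sorted(fx.truth.type1_ids)
        # near-misses stay
        assert set(fx.truth.type1_near_miss_ids) <= set(kept.genes)


class TestType2:
    def test_shorter_of_pair_removed(self):
        long_g = make_gene("long", [[(0, 500)]])
        short_g = make_gene("short", [[(400, 700)]])
        _, removed = filter_type2(annotation_of(long_g, short_g))
        assert removed == ["short"]

    def test_opposite_strands_kept(self):
        a = make_gene("a", [[(0, 500)]], strand="+")
        b = make_gene("b", [[(100, 400)]], strand="-")
        kept, removed = filter_type2(annotation_of(a, b))
        assert removed == [] and len(kept) == 2

    def test_chain_removes_shortest_first(self):
        # A(100) overlaps B(200), B overlaps C(300), A and C disjoint:
        # the declared rule removes A then B and keeps only C
        a = make_gene("A", [[(0, 100)]])
        b = make_gene("B", [[(80, 280)]])
        c = make_gene("C", [[(250, 550)]])
        kept, removed = filter_type2(annotation_of(a, b, c))
        assert removed == ["A", "B"]
        assert list(kept.genes) == ["C"]

    def test_no_retained_overlap_on_random_fixtures(self, rng):
        for _ in range(30):
            genes = []
            for i, iv in enumerate(random_intervals(rng, 15, 800, max_len=150)):
                strand = "+" if rng.integers(2) else "-"
                genes.append(make_gene(f"g{i:02d}", [[(iv.start, iv.end)]],
                                       strand=strand))
            kept, removed = filter_type2(annotation_of(*genes))
            assert not _span_overlap_pairs(list(kept.genes.values()))
            assert len(kept) + len(removed) == len(genes)


class TestType3:
    def test_disjoint_isoforms_split(self):
        g = make_gene("g", [[(0, 1000)], [(11_000, 12_000)]])
        out, split_map = split_type3(annotation_of(g))
        assert split_map == {"g": ["g.1", "g.2"]}
        assert len(out) == 2
        assert out.genes["g.1"].transcripts[0].start == 0

    def test_transitive_overlap_stays_one_gene(self):
        g = make_gene("g", [[(0, 100)], [(80, 200)], [(180, 300)]])
        out, split_map = split_type3(annotation_of(g))
        assert split_map == {} and len(out) == 1

    def test_components_match_networkx_oracle(self, rng):
        for trial in range(100):
            n_tx = int(rng.integers(2, 7))
            exon_groups = []
            for _ in range(n_tx):
                s = int(rng.integers(0, 500))
                exon_groups.append([(s, s + int(rng.integers(20, 200)))])
            g = make_gene("g", exon_groups)
            out, split_map = split_type3(annotation_of(g))

            graph = nx.Graph()
            graph.add_nodes_from(range(n_tx))
            for i in range(n_tx):
                for j in range(i + 1, n_tx):
                    if overlap_bp(g.transcripts[i].exon_footprint(),
                                  g.transcripts[j].exon_footprint()) >= 1:
                        graph.add_edge(i, j)
            n_comp = nx.number_connected_components(graph)
            assert len(out) == n_comp
            # transcripts conserved
            assert out.n_transcripts() == n_tx

    def test_outputs_of_one_split_are_pairwise_disjoint(self):
        fx = simulate_annotated_genome()
        out, split_map = split_type3(fx.annotation)
        for new_ids in split_map.values():
            for i, a in enumerate(new_ids):
                for b in new_ids[i + 1:]:
                    assert overlap_bp(out.genes[a].merged_exons(),
                                      out.genes[b].merged_exons()) == 0


class TestCuratePipeline:
    def test_planted_truth_report(self):
        fx = simulate_annotated_genome()
        curated, report = curate(fx.annotation, fx.repeats)
        assert report.n_removed_type1 == 3
        assert report.n_removed_type2 == 2
        assert report.n_genes_split_type3 == 1
        assert report.n_genes_created_type3 == 2
        assert sorted(report.type1_ids) == sorted(fx.truth.type1_ids)
        assert sorted(report.type2_ids) == sorted(fx.truth.type2_removed_ids)
        assert report.type3_ids == fx.truth.type3_ids

    def test_idempotent(self):
        fx = simulate_annotated_genome()
        once, _ = curate(fx.annotation, fx.repeats)
        twice, report2 = curate(once, fx.repeats)
        assert set(twice.genes) == set(once.genes)
        assert report2.n_removed_type1 == 0
        assert report2.n_removed_type2 == 0
        assert report2.n_genes_split_type3 == 0

    def test_empty_annotation(self):
        out, report = curate(AnnotationSet(), RepeatTrack())
        assert len(out) == 0
        assert report.n_input_genes == report.n_output_genes == 0

    def test_custom_threshold_validated(self):
        with pytest.raises(ValueError):
            CurationConfig(repeat_fraction_threshold=0.0)
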