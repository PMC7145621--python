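import numpy as np
import pytest

from oracles import exhaustive_rgp_windows
from panplast.io import GeneRecord
from panplast.pangenome import presence_absence  # noqa: F401  (shared fixture deps)
from panplast.rgp import (
    RGP,
    ProjectedGene,
    RGPScoring,
    detect_rgps,
    detect_rgps_genome,
    match_rgps,
    project_partitions,
    rgp_annotation_crosslinks,
)


def _contig(labels, gene_len=900, gap=140):
    """Projected genes with the given labels, evenly spaced."""
    out = []
    pos = 0
    for i, lab in enumerate(labels):
        out.append(ProjectedGene(f"g{i:03d}", f"F{i:03d}", pos, pos + gene_len, lab))
        pos += gene_len + gap
    return out


class TestProjection:
    def test_labels_follow_family_partition(self):
        genes = [
            GeneRecord("a", "g1", "c", 0, 90, "+"),
            GeneRecord("b", "g1", "c", 100, 190, "+"),
        ]
        proj = project_partitions(genes, {"a": "F1", "b": "F2"}, {"F1": "shell", "F2": "persistent"})
        labels = [p.label for p in proj[("g1", "c")]]
        assert labels == ["shell", "persistent"]

    def test_order_matches_coordinates(self):
        genes = [
            GeneRecord("b", "g1", "c", 500, 590, "+"),
            GeneRecord("a", "g1", "c", 0, 90, "+"),
        ]
        proj = project_partitions(genes, {"a": "F1", "b": "F1"}, {"F1": "cloud"})
        assert [p.gene_id for p in proj[("g1", "c")]] == ["a", "b"]

    def test_unlabeled_family_is_an_error(self):
        genes = [GeneRecord("a", "g1", "c", 0, 90, "+")]
        with pytest.raises(KeyError):
            project_partitions(genes, {"a": "F1"}, {})


class TestDetection:
    def test_cloud_run_flanked_by_persistent(self):
        labels = ["persistent"] * 3 + ["cloud"] * 5 + ["persistent"] * 3
        genes = _contig(labels)  # 5 genes * 900bp + 4 gaps = 5060 bp span
        (r,) = detect_rgps(genes, "g1", "c")
        assert [g for g in r.genes] == [f"g{i:03d}" for i in range(3, 8)]
        assert r.score == 5 and r.span > 3000

    def test_short_island_rejected_by_length_rule(self):
        labels = ["persistent"] * 3 + ["cloud"] * 4 + ["persistent"] * 3
        genes = _contig(labels, gene_len=480, gap=60)  # 4*480+3*60 = 2100 bp
        island = [g for g in genes if g.label == "cloud"]
        assert island[-1].end - island[0].start == 2100
        assert detect_rgps(genes, "g1", "c") == []

    def test_all_persistent_contig_empty(self):
        assert detect_rgps(_contig(["persistent"] * 10), "g1", "c") == []

    def test_one_interspersed_persistent_gene_tolerated(self):
        labels = ["persistent"] * 2 + ["cloud"] * 4 + ["persistent"] + ["cloud"] * 4 + ["persistent"] * 2
        (r,) = detect_rgps(_contig(labels), "g1", "c")
        assert len(r.genes) == 9 and r.score == 4 + 4 - 3

    def test_two_consecutive_persistent_genes_break_a_region(self):
        labels = ["cloud"] * 5 + ["persistent"] * 2 + ["cloud"] * 5
        rgps = detect_rgps(_contig(labels), "g1", "c")
        assert len(rgps) == 2
        assert all(len(r.genes) == 5 for r in rgps)

    def test_reported_regions_satisfy_score_and_span_rules(self):
        rng = np.random.default_rng(0)
        scoring = RGPScoring()
        for _ in range(50):
            labels = rng.choice(
                ["persistent", "shell", "cloud"], size=rng.integers(1, 50), p=[0.6, 0.2, 0.2]
            ).tolist()
            for r in detect_rgps(_contig(labels), "g", "c", scoring):
                assert r.score >= scoring.min_score
                assert r.span > scoring.min_length

    def test_scan_matches_exhaustive_window_enumeration(self):
        """On random contigs of <= 50 genes, the linear scan reproduces the
        greedy exhaustive maximal-window reference."""
        rng = np.random.default_rng(1)
        scoring = RGPScoring()
        for _ in range(200):
            labels = rng.choice(
                ["persistent", "shell", "cloud"],
                size=rng.integers(1, 50),
                p=[0.5, 0.25, 0.25],
            ).tolist()
            genes = _contig(labels, gene_len=int(rng.integers(200, 1500)), gap=100)
            detected = {
                (r.genes[0], r.genes[-1], r.score)
                for r in detect_rgps(genes, "g", "c", scoring)
            }
            oracle = {
                (genes[i].gene_id, genes[j].gene_id, s)
                for i, j, s in exhaustive_rgp_windows(
                    [(g.start, g.end, g.label) for g in genes], scoring
                )
            }
            assert detected == oracle

    def test_regions_on_one_contig_are_gene_disjoint(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            labels = rng.choice(
                ["persistent", "cloud"], size=40, p=[0.4, 0.6]
            ).tolist()
            rgps = detect_rgps(_contig(labels), "g", "c")
            seen = set()
            for r in rgps:
                assert not (seen & set(r.genes))
                seen |= set(r.genes)

    def test_determinism(self):
        labels = ["persistent"] * 2 + ["cloud"] * 6 + ["persistent"] * 2
        a = detect_rgps(_contig(labels), "g1", "c")
        b = detect_rgps(_contig(labels), "g1", "c")
        assert [(r.rgp_id, r.start, r.end) for r in a] == [
            (r.rgp_id, r.start, r.end) for r in b
        ]

    def test_circular_contig_region_crossing_origin_found_once(self):
        labels = ["cloud"] * 3 + ["persistent"] * 8 + ["cloud"] * 3
        genes = _contig(labels)
        contig_length = genes[-1].end + 140
        rgps = detect_rgps(
            genes, "g1", "c", circular=True, contig_length=contig_length
        )
        assert len(rgps) == 1
        (r,) = rgps
        assert set(r.genes) == {"g000", "g001", "g002", "g011", "g012", "g013"}
        assert r.end > contig_length  # wraps the origin

    def test_linear_scan_of_same_genes_finds_nothing(self):
        labels = ["cloud"] * 3 + ["persistent"] * 8 + ["cloud"] * 3
        assert detect_rgps(_contig(labels), "g1", "c") == []


class TestPlantedIslands:
    def test_precision_and_recall_one_on_planted_islands(self, island_pangenome):
        sim = island_pangenome
        proj = project_partitions(sim.genes, sim.family_truth, sim.partition_truth)
        detected = {
            (r.genome_id, r.contig_id, r.start, r.end)
            for r in detect_rgps_genome(proj)
        }
        truth = {
            (genome, contig, s, e)
            for genome, spans in sim.rgp_truth.items()
            for contig, s, e in spans
            if e - s > 3000
        }
        assert truth  # the fixture plants long islands
        assert detected == truth

    def test_sub3kb_planted_island_rejected(self, island_pangenome):
        sim = island_pangenome
        short = [
            (genome, s, e)
            for genome, spans in sim.rgp_truth.items()
            for _, s, e in spans
            if e - s <= 3000
        ]
        assert short  # the fixture plants a 2.1 kb island
        proj = project_partitions(sim.genes, sim.family_truth, sim.partition_truth)
        detected = {
            (r.genome_id, r.start, r.end) for r in detect_rgps_genome(proj)
        }
        assert not (set(short) & detected)


class TestMatching:
    def _rgp(self, rid, fams, genome="g1"):
        return RGP(rid, genome, "c", 0, 5000, ["x"], set(fams), 5)

    def test_identical_content_full_match(self):
        q = self._rgp("q", {"F1", "F2"})
        t = self._rgp("t", {"F1", "F2"}, genome="g2")
        assert match_rgps(q, [t]) == [("t", 100.0)]

    def test_disjoint_content_zero(self):
        q = self._rgp("q", {"F1"})
        t = self._rgp("t", {"F9"}, genome="g2")
        assert match_rgps(q, [t]) == [("t", 0.0)]

    def test_partial_overlap_query_denominator(self):
        q = self._rgp("q", {"F1", "F2", "F3", "F4"})
        t = self._rgp("t", {"F1", "F2"}, genome="g2")
        assert match_rgps(q, [t]) == [("t", 50.0)]

    def test_sorted_descending_with_id_tiebreak(self):
        q = self._rgp("q", {"F1", "F2"})
        ts = [
            self._rgp("b", {"F1", "F2"}, "g2"),
            self._rgp("a", {"F1", "F2"}, "g3"),
            self._rgp("c", {"F1"}, "g4"),
        ]
        assert match_rgps(q, ts) == [("a", 100.0), ("b", 100.0), ("c", 50.0)]

    def test_empty_query_family_set_rejected(self):
        q = RGP("q", "g1", "c", 0, 5000, [], set(), 5)
        with pytest.raises(ValueError):
            match_rgps(q, [])


class TestCrosslinks:
    def test_no_tables_gives_zero_counts(self):
        r = RGP("r1", "g", "c", 0, 4000, ["a", "b"], {"F1"}, 4)
        assert rgp_annotation_crosslinks([r]) == {"r1": {}}

    def test_counts_per_category(self):
        r = RGP("r1", "g", "c", 0, 4000, ["a", "b", "c"], {"F1"}, 4)
        table = [("a", "AMR"), ("b", "AMR"), ("c", "virulence"), ("zz", "AMR")]
        out = rgp_annotation_crosslinks([r], table, known_genes={"a", "b", "c", "out"})
        assert out == {"r1": {"AMR": 2, "virulence": 1}}

    def test_flag_outside_any_rgp_ignored(self):
        r = RGP("r1", "g", "c", 0, 4000, ["a"], {"F1"}, 4)
        out = rgp_annotation_crosslinks([r], [("other", "AMR")], known_genes={"a", "other"})
        assert out == {"r1": {"AMR": 0}}
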