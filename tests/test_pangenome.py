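import numpy as np
import pytest

from panplast.io import GeneRecord
from panplast.pangenome import (
    PangenomeParams,
    PresenceAbsenceMatrix,
    build_pangenome_graph,
    pangenome_summary,
    partition_em,
    presence_absence,
    strict_components,
)


def _gene(gene_id, genome, contig, start, end=None):
    return GeneRecord(gene_id, genome, contig, start, end or start + 90, "+")


class TestPresenceAbsence:
    def test_paralogs_binarize(self):
        fams = {"g1_a": "F1", "g1_b": "F1", "g2_a": "F1"}
        genomes = {"g1_a": "g1", "g1_b": "g1", "g2_a": "g2"}
        pa = presence_absence(fams, genomes, min_genomes=2)
        assert pa.x.tolist() == [[1, 1]]

    def test_refuses_fewer_than_min_genomes(self):
        fams = {f"g{i}_a": "F1" for i in range(14)}
        genomes = {f"g{i}_a": f"g{i}" for i in range(14)}
        with pytest.raises(ValueError, match="15"):
            presence_absence(fams, genomes)

    def test_override_logged(self, caplog):
        fams = {"g1_a": "F1", "g2_a": "F1"}
        genomes = {"g1_a": "g1", "g2_a": "g2"}
        with caplog.at_level("WARNING"):
            pa = presence_absence(fams, genomes, allow_fewer=True)
        assert pa.x.shape == (1, 2)
        assert any("overridden" in r.message for r in caplog.records)

    def test_all_zero_family_rejected(self):
        with pytest.raises(ValueError):
            PresenceAbsenceMatrix(["F1"], ["g1"], np.array([[0]]))


class TestPangenomeGraph:
    def test_linear_path_edges(self):
        genes = [_gene("a", "g1", "c", 0), _gene("b", "g1", "c", 100), _gene("c", "g1", "c", 200)]
        fams = {"a": "F1", "b": "F2", "c": "F3"}
        g = build_pangenome_graph(genes, fams)
        assert set(map(frozenset, g.edges)) == {frozenset({"F1", "F2"}), frozenset({"F2", "F3"})}
        assert all(d["weight"] == 1 for _, _, d in g.edges(data=True))

    def test_shared_gene_order_accumulates_weight(self):
        genes = []
        for gm in ("g1", "g2"):
            genes += [_gene(f"{gm}_a", gm, "c", 0), _gene(f"{gm}_b", gm, "c", 100)]
        fams = {"g1_a": "F1", "g1_b": "F2", "g2_a": "F1", "g2_b": "F2"}
        g = build_pangenome_graph(genes, fams)
        assert g["F1"]["F2"]["weight"] == 2

    def test_circular_contig_closes_the_loop(self):
        genes = [_gene("a", "g1", "c", 0), _gene("b", "g1", "c", 100), _gene("c", "g1", "c", 200)]
        fams = {"a": "F1", "b": "F2", "c": "F3"}
        g = build_pangenome_graph(genes, fams, circular_contigs={("g1", "c")})
        assert g.has_edge("F3", "F1")

    def test_tandem_duplicates_make_no_self_loop(self):
        genes = [_gene("a", "g1", "c", 0), _gene("b", "g1", "c", 100)]
        fams = {"a": "F1", "b": "F1"}
        g = build_pangenome_graph(genes, fams)
        assert g.number_of_edges() == 0
        assert g.nodes["F1"]["n_genes"] == 2

    def test_unknown_family_rejected(self):
        with pytest.raises(KeyError):
            build_pangenome_graph([_gene("a", "g1", "c", 0)], {})


class TestStrictComponents:
    def test_core_variable_complement(self):
        x = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1], [0, 0, 1]])
        pa = PresenceAbsenceMatrix(["F1", "F2", "F3", "F4"], ["a", "b", "c"], x)
        core, variable = strict_components(pa)
        assert core == {"F1", "F3"}
        assert variable == {"F2", "F4"}
        assert len(core) + len(variable) == 4


class TestPartitionEM:
    def test_first_estep_equals_hand_bayes_rule(self):
        """With beta=0 and the deterministic init (eps rows 0.9/0.5/0.1, pi
        uniform), responsibilities after one iteration follow Bayes' rule."""
        x = np.array([[1, 1, 1], [0, 0, 1]], dtype=np.uint8)
        pa = PresenceAbsenceMatrix(["F1", "F2"], ["a", "b", "c"], x)
        model = partition_em(pa, None, PangenomeParams(beta=0.0, max_iter=1, min_genomes=2))
        eps = np.array([0.9, 0.5, 0.1])
        expected = []
        for row in x:
            lik = np.array(
                [np.prod(np.where(row == 1, e, 1 - e)) for e in eps]
            )
            expected.append(lik / lik.sum())
        assert np.allclose(model.responsibilities, np.array(expected))

    def test_beta_zero_loglik_monotone(self, planted_pangenome):
        sim = planted_pangenome
        pa = presence_absence(sim.family_truth, sim.genome_of())
        model = partition_em(pa, None, PangenomeParams(beta=0.0))
        trace = np.array(model.objective_trace)
        assert np.all(np.diff(trace) >= -1e-8 * np.abs(trace[:-1]))

    def test_penalized_objective_converges_with_beta(self, planted_pangenome):
        sim = planted_pangenome
        pa = presence_absence(sim.family_truth, sim.genome_of())
        graph = build_pangenome_graph(sim.genes, sim.family_truth)
        model = partition_em(pa, graph, PangenomeParams(beta=0.5))
        assert model.converged
        tr = model.objective_trace
        assert abs(tr[-1] - tr[-2]) < 1e-4 * abs(tr[-1])

    def test_planted_labels_recovered(self, planted_pangenome):
        sim = planted_pangenome
        pa = presence_absence(sim.family_truth, sim.genome_of())
        graph = build_pangenome_graph(sim.genes, sim.family_truth)
        model = partition_em(pa, graph, PangenomeParams(beta=0.5))
        acc = np.mean([model.labels[f] == sim.partition_truth[f] for f in pa.families])
        assert acc >= 0.95

    def test_ubiquitous_family_persistent_and_rare_family_cloud(self, planted_pangenome):
        sim = planted_pangenome
        pa = presence_absence(sim.family_truth, sim.genome_of())
        model = partition_em(pa, None, PangenomeParams(beta=0.0))
        sums = pa.x.sum(axis=1)
        full = [f for f, s in zip(pa.families, sums) if s == len(pa.genomes)]
        single = [f for f, s in zip(pa.families, sums) if s == 1]
        assert full and single
        assert all(model.labels[f] == "persistent" for f in full)
        assert all(model.labels[f] == "cloud" for f in single)

    def test_relabeling_invariant_persistent_has_highest_mean_eps(self, planted_pangenome):
        sim = planted_pangenome
        pa = presence_absence(sim.family_truth, sim.genome_of())
        model = partition_em(pa, None, PangenomeParams(beta=0.0))
        means = model.eps.mean(axis=1)
        assert means[0] >= means[1] >= means[2]

    def test_family_order_permutation_invariance(self, planted_pangenome):
        sim = planted_pangenome
        pa = presence_absence(sim.family_truth, sim.genome_of())
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(pa.families))
        pa2 = PresenceAbsenceMatrix(
            [pa.families[i] for i in perm], pa.genomes, pa.x[perm]
        )
        m1 = partition_em(pa, None, PangenomeParams(beta=0.0))
        m2 = partition_em(pa2, None, PangenomeParams(beta=0.0))
        assert m1.labels == m2.labels


class TestSummary:
    def test_counts_conserved(self, planted_pangenome):
        sim = planted_pangenome
        pa = presence_absence(sim.family_truth, sim.genome_of())
        model = partition_em(pa, None, PangenomeParams(beta=0.0))
        sizes = {}
        for fam in sim.family_truth.values():
            sizes[fam] = sizes.get(fam, 0) + 1
        table = pangenome_summary(model, pa, sizes)
        assert table["n_families"].sum() == len(pa.families)
        assert table["n_genes"].sum() == len(sim.genes)

    def test_summary_close_to_planted_counts(self, planted_pangenome):
        sim = planted_pangenome
        pa = presence_absence(sim.family_truth, sim.genome_of())
        graph = build_pangenome_graph(sim.genes, sim.family_truth)
        model = partition_em(pa, graph, PangenomeParams(beta=0.5))
        table = pangenome_summary(model, pa).set_index("partition")
        planted = {"persistent": 300, "shell": 300, "cloud": 400}
        for name, n in planted.items():
            assert abs(table.loc[name, "n_families"] - n) <= 0.05 * n
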