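"""Generators: determinism, planted structure, and event-rate calibration."""

import itertools
import math

import numpy as np
import pytest

from clademark import parse_newick, rf_distance
from clademark.classify import pairwise_identity
from clademark.records import GenomeRecord, genome_of
from clademark.simulate import (
    GeneFamilySimParams,
    GroupSeqSimParams,
    SpeciesTreeSimParams,
    crossing_transfers,
    evolve_sequences,
    jc_expected_p_distance,
    simulate_16s_groups,
    simulate_annotation_table,
    simulate_gene_family,
    simulate_marker_families,
    simulate_read_counts,
    simulate_species_tree,
)


class TestSpeciesTree:
    def test_one_taxon_per_clade(self):
        t, cmap = simulate_species_tree(
            SpeciesTreeSimParams(clades={"A": 1, "B": 1, "C": 1}, seed=0)
        )
        assert t.n_leaves == 3
        assert set(cmap.values()) == {"A", "B", "C"}

    def test_deterministic_under_seed(self):
        p = SpeciesTreeSimParams(clades={"A": 4, "B": 3}, seed=42)
        t1, _ = simulate_species_tree(p)
        t2, _ = simulate_species_tree(p)
        assert t1.to_newick() == t2.to_newick()

    def test_clades_monophyletic_across_seeds(self):
        for seed in range(100):
            t, cmap = simulate_species_tree(
                SpeciesTreeSimParams(clades={"F": 5, "X": 3, "Y": 2}, seed=seed)
            )
            focal = {l for l, c in cmap.items() if c == "F"}
            assert t.is_monophyletic(focal)

    def test_nested_clades_and_parent_monophyly(self):
        spec = {"Phy": {"g1": 3, "g2": 2, "g3": 2}, "Out1": 3, "Out2": 2}
        for seed in range(20):
            t, cmap = simulate_species_tree(SpeciesTreeSimParams(clades=spec, seed=seed))
            for sub in ("g1", "g2", "g3"):
                assert t.is_monophyletic({l for l, c in cmap.items() if c == sub})
            phylum = {l for l, c in cmap.items() if c in ("g1", "g2", "g3")}
            assert t.is_monophyletic(phylum)

    def test_ultrametric_depth(self):
        p = SpeciesTreeSimParams(clades={"A": 4, "B": 3}, depth=0.3, seed=7)
        t, _ = simulate_species_tree(p)
        dt = t.dendropy_tree
        for lf in dt.leaf_node_iter():
            d = 0.0
            nd = lf
            while nd.parent_node is not None:
                d += nd.edge.length
                nd = nd.parent_node
            assert d == pytest.approx(0.3, abs=1e-9)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            SpeciesTreeSimParams(clades={})
        with pytest.raises(ValueError):
            SpeciesTreeSimParams(clades={"A": 0})


@pytest.fixture(scope="module")
def species():
    return simulate_species_tree(
        SpeciesTreeSimParams(clades={"Kor": 5, "Eury": 3, "DPANN": 2}, seed=11)
    )


class TestGeneFamily:
    def test_zero_rates_congruent_single_copy(self, species):
        tree, cmap = species
        fam, events = simulate_gene_family(tree, GeneFamilySimParams(seed=5))
        assert events == []
        assert all(c == 1 for c in fam.copy_counts.values())
        relabeled = parse_newick(fam.tree.to_newick().replace("|1", ""))
        assert rf_distance(relabeled, tree) == 0

    def test_deterministic_under_seed(self, species):
        tree, _ = species
        p = GeneFamilySimParams(dup_rate=0.3, transfer_rate=0.5, loss_rate=0.2, seed=9)
        f1, e1 = simulate_gene_family(tree, p)
        f2, e2 = simulate_gene_family(tree, p)
        assert f1.tree.to_newick() == f2.tree.to_newick()
        assert f1.members == f2.members
        assert e1 == e2

    def test_duplication_count_matches_branching_expectation(self, species):
        """Mean duplication count matches the exact branching-process expectation.

        With duplication rate d and no loss, the expected number of events is
        d * integral of e^(d * depth) over the tree (copies compound), which
        reduces per branch spanning depths [a, b] to e^(d b) - e^(d a).
        """
        tree, _ = species
        d = 0.5
        # independent expectation from the species tree structure
        dt = tree.dendropy_tree
        depth = {dt.seed_node: 0.0}
        expected = 0.0
        for nd in dt.preorder_node_iter():
            if nd.parent_node is None:
                continue
            a = depth[nd.parent_node]
            b = a + (nd.edge.length or 0.0)
            depth[nd] = b
            expected += math.exp(d * b) - math.exp(d * a)
        counts = []
        for seed in range(2000):
            _, events = simulate_gene_family(
                tree, GeneFamilySimParams(dup_rate=d, seq_length=0, seed=seed)
            )
            counts.append(sum(1 for e in events if e.kind == "duplication"))
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / math.sqrt(len(counts))
        assert abs(mean - expected) < 3 * se + 1e-12

    def test_no_transfer_no_dup_preserves_focal_monophyly(self, species):
        """Losses alone can never break focal monophyly in the gene tree.

        Duplications are deliberately off: a duplication ancestral to the
        split between focal and non-focal clades yields paralog subtrees that
        interleave the label-level focal set, so only transfer-free AND
        duplication-free families carry the guarantee.
        """
        tree, cmap = species
        focal_genomes = {l for l, c in cmap.items() if c == "Kor"}
        for seed in range(200):
            fam, _ = simulate_gene_family(
                tree, GeneFamilySimParams(loss_rate=0.3, seq_length=0, seed=seed)
            )
            if fam.tree is None:
                continue
            focal = {lf for lf in fam.tree.leaf_labels if genome_of(lf) in focal_genomes}
            if focal:
                assert fam.tree.is_monophyletic(focal)

    def test_ancestral_duplication_can_break_focal_monophyly(self, species):
        """Documented counterexample: pre-divergence duplications interleave paralogs."""
        tree, cmap = species
        focal_genomes = {l for l, c in cmap.items() if c == "Kor"}
        broken = 0
        for seed in range(100):
            fam, events = simulate_gene_family(
                tree, GeneFamilySimParams(dup_rate=0.5, seq_length=0, seed=seed)
            )
            focal = {lf for lf in fam.tree.leaf_labels if genome_of(lf) in focal_genomes}
            if len(focal) >= 2 and not fam.tree.is_monophyletic(focal):
                broken += 1
        assert broken > 0

    def test_all_lineages_lost_gives_empty_family(self, species):
        tree, _ = species
        fam, _ = simulate_gene_family(
            tree, GeneFamilySimParams(loss_rate=500.0, seq_length=0, seed=0)
        )
        assert fam.tree is None
        assert all(c == 0 for c in fam.copy_counts.values())

    def test_crossing_transfer_detection(self, species):
        tree, cmap = species
        focal_genomes = {l for l, c in cmap.items() if c == "Kor"}
        found = 0
        for seed in range(30):
            _, events = simulate_gene_family(
                tree, GeneFamilySimParams(transfer_rate=1.0, seq_length=0, seed=seed)
            )
            found += bool(crossing_transfers(events, tree, focal_genomes))
        assert found > 0

    def test_planted_marker_dataset(self, species):
        tree, cmap = species
        fams, vertical = simulate_marker_families(
            tree, cmap, focal="Kor", n_vertical=5, n_disrupted=3, seq_length=0, seed=2
        )
        assert len(fams) == 8 and len(vertical) == 5
        assert {f.id for f in fams} >= vertical


class TestEvolveSequences:
    def test_zero_lengths_identical(self):
        t = parse_newick("((A:0,B:0):0,C:0);")
        aln = evolve_sequences(t, 50, seed=0)
        assert len(set(aln.rows)) == 1

    def test_deterministic(self):
        t = parse_newick("((A:0.1,B:0.1):0.05,C:0.2);")
        a1 = evolve_sequences(t, 100, seed=3)
        a2 = evolve_sequences(t, 100, seed=3)
        assert a1.rows == a2.rows

    def test_expected_p_distance_at_0p1(self):
        """Two leaves at distance 0.1: mean p-distance matches (3/4)(1-e^(-0.4/3))."""
        expected = 0.75 * (1.0 - math.exp(-4.0 * 0.1 / 3.0))
        assert expected == pytest.approx(0.0936, abs=5e-5)
        t = parse_newick("(A:0.05,B:0.05);")
        n_sites, reps = 1000, 30
        ps = []
        for seed in range(reps):
            aln = evolve_sequences(t, n_sites, seed=seed)
            diff = sum(x != y for x, y in zip(aln.rows[0], aln.rows[1]))
            ps.append(diff / n_sites)
        se = math.sqrt(expected * (1 - expected) / (n_sites * reps))
        assert abs(np.mean(ps) - expected) < 3 * se


class TestSixteenSGroups:
    def test_single_group_no_divergence(self):
        recs, truth = simulate_16s_groups(
            GroupSeqSimParams(
                n_groups=1, seqs_per_group=4, intra_identity=1.0,
                length=800, length_range=(800, 800), core=500, seed=0,
            )
        )
        assert len({r.sequence for r in recs}) == 1
        assert all(pairwise_identity(a, b) == 1.0 for a, b in itertools.combinations(recs, 2))

    def test_deterministic(self):
        p = GroupSeqSimParams(seed=8)
        r1, _ = simulate_16s_groups(p)
        r2, _ = simulate_16s_groups(p)
        assert [(r.id, r.sequence) for r in r1] == [(r.id, r.sequence) for r in r2]

    def test_realized_identity_bands(self):
        p = GroupSeqSimParams(seed=4)
        recs, truth = simulate_16s_groups(p)
        intra = [
            pairwise_identity(a, b)
            for a, b in itertools.combinations(recs, 2)
            if truth[a.id] == truth[b.id]
        ]
        inter = [
            pairwise_identity(a, b)
            for a, b in itertools.combinations(recs, 2)
            if truth[a.id] != truth[b.id]
        ]
        assert abs(np.mean(intra) - p.intra_identity) < 0.01
        assert abs(np.mean(inter) - p.inter_identity) < 0.02

    def test_lengths_exercise_the_length_filter(self):
        recs, _ = simulate_16s_groups(GroupSeqSimParams(n_groups=4, seqs_per_group=15, seed=0))
        lengths = [r.length for r in recs]
        assert min(lengths) < 700 <= max(lengths)

    def test_infeasible_targets_error(self):
        with pytest.raises(ValueError):
            GroupSeqSimParams(intra_identity=0.90, inter_identity=0.95)
        with pytest.raises(ValueError):
            GroupSeqSimParams(intra_identity=0.95, inter_identity=0.95)


class TestReadCounts:
    def test_single_genome_takes_all_reads(self):
        t = simulate_read_counts({"g1": 1.0}, {"g1": 2_000_000}, {"s1": 1000}, seed=0)
        assert t.counts.at["s1", "g1"] == 1000

    def test_equal_split_within_3se(self):
        n = 10**6
        t = simulate_read_counts(
            {"g1": 0.5, "g2": 0.5}, {"g1": 10**6, "g2": 10**6}, {"s1": n}, seed=1
        )
        se = math.sqrt(n * 0.25)
        assert abs(t.counts.at["s1", "g1"] - n / 2) < 3 * se

    def test_deterministic(self):
        args = ({"a": 0.3, "b": 0.7}, {"a": 10**6, "b": 2 * 10**6}, {"s1": 5000, "s2": 5000})
        t1 = simulate_read_counts(*args, seed=9)
        t2 = simulate_read_counts(*args, seed=9)
        assert t1.counts.equals(t2.counts)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_read_counts({"a": 0.5, "b": 0.4}, {"a": 1, "b": 1}, {"s": 10})


class TestAnnotationTable:
    def _genome(self, completeness):
        return GenomeRecord("g1", group="G", completeness=completeness, length_bp=10)

    def test_full_completeness_keeps_signature(self):
        m = simulate_annotation_table(
            [self._genome(100.0)], {"G": {"x", "y", "z"}}, completeness_dropout=True, seed=0
        )
        assert m.loc["g1"].sum() == 3

    def test_dropout_rate_matches_completeness(self):
        genes = {f"gene{i}" for i in range(10_000)}
        m = simulate_annotation_table(
            [self._genome(88.71)], {"G": genes}, completeness_dropout=True, seed=0
        )
        rate = m.loc["g1"].mean()
        se = math.sqrt(0.8871 * (1 - 0.8871) / 10_000)
        assert abs(rate - 0.8871) < 3 * se

    def test_dropout_off_reproduces_signatures(self):
        genomes = [
            GenomeRecord("a", group="G1", completeness=50.0, length_bp=10),
            GenomeRecord("b", group="G2", completeness=50.0, length_bp=10),
        ]
        m = simulate_annotation_table(genomes, {"G1": {"x"}, "G2": {"y"}}, seed=0)
        assert m.at["a", "x"] == 1 and m.at["a", "y"] == 0
        assert m.at["b", "y"] == 1 and m.at["b", "x"] == 0

    def test_unknown_group_errors(self):
        with pytest.raises(KeyError, match="unknown group"):
            simulate_annotation_table([self._genome(90.0)], {"other": {"x"}})
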