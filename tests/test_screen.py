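"""Marker screen: eligibility boundaries, filters, trimming, concatenation."""

import numpy as np
import pytest

from clademark import parse_newick
from clademark.alignment import Alignment
from clademark.records import GeneFamily, GenomeRecord
from clademark.screen import (
    R_CONTAMINATION,
    R_MULTI_COPY,
    R_NON_MONOPHYLETIC,
    R_OCCUPANCY,
    ScreenConfig,
    concatenate,
    contamination_screen,
    eligible_genomes,
    load_families,
    monophyly_screen,
    read_genomes_tsv,
    run_marker_screen,
    single_copy_families,
    trim_alignment,
    write_families,
    write_genomes_tsv,
)
from clademark.simulate import (
    SpeciesTreeSimParams,
    simulate_marker_families,
    simulate_species_tree,
)


def _genome(gid, completeness, phylum="Kor"):
    return GenomeRecord(gid, phylum=phylum, completeness=completeness, length_bp=10)


class TestEligibility:
    def test_threshold_is_strict(self):
        gs = [_genome("a", 85.0), _genome("b", 85.01), _genome("c", 88.71)]
        assert eligible_genomes(gs, 85.0) == {"b", "c"}

    def test_empty_input(self):
        assert eligible_genomes([], 85.0) == set()


class TestSingleCopyOccupancy:
    def test_two_copies_anywhere_discards(self):
        fam = GeneFamily("f1", copy_counts={"a": 2, "b": 1})
        assert single_copy_families([fam], {"a", "b"}, occupancy_min=0.0) == []

    def test_multicopy_outside_eligible_set_is_ignored(self):
        fam = GeneFamily("f1", copy_counts={"a": 2, "b": 1})
        assert single_copy_families([fam], {"b"}, occupancy_min=0.5) == ["f1"]

    def test_full_occupancy_kept(self):
        fam = GeneFamily("f1", copy_counts={"a": 1, "b": 1, "c": 1})
        assert single_copy_families([fam], {"a", "b", "c"}, 1.0) == ["f1"]

    def test_below_half_occupancy_discarded(self):
        counts = {f"g{i}": 1 for i in range(4)} | {f"g{i}": 0 for i in range(4, 10)}
        fam = GeneFamily("f1", copy_counts=counts)
        assert single_copy_families([fam], set(counts), 0.5) == []
        assert single_copy_families([fam], set(counts), 0.4) == ["f1"]

    def test_empty_eligible_errors(self):
        with pytest.raises(ValueError):
            single_copy_families([GeneFamily("f")], set())


def _fam_with_tree(fid, newick, counts):
    t = parse_newick(newick)
    return GeneFamily(fid, copy_counts=counts, members={l: None for l in t.leaf_labels}, tree=t)


CLADES = {"K1": "Kor", "K2": "Kor", "K3": "Kor", "E1": "Eury", "E2": "Eury", "D1": "DPANN"}


class TestMonophylyScreen:
    def test_clean_clade_kept(self):
        fam = _fam_with_tree(
            "f", "(((K1|1,K2|1),K3|1),(E1|1,E2|1));",
            {"K1": 1, "K2": 1, "K3": 1, "E1": 1, "E2": 1},
        )
        assert monophyly_screen([fam], CLADES, "Kor") == ["f"]

    def test_intruding_leaf_discards(self):
        fam = _fam_with_tree(
            "f", "(((K1|1,E1|1),K2|1),(K3|1,E2|1));",
            {"K1": 1, "K2": 1, "K3": 1, "E1": 1, "E2": 1},
        )
        assert monophyly_screen([fam], CLADES, "Kor") == []

    def test_single_focal_leaf_passes_vacuously(self):
        fam = _fam_with_tree("f", "((K1|1,E1|1),(E2|1,D1|1));",
                             {"K1": 1, "E1": 1, "E2": 1, "D1": 1})
        assert monophyly_screen([fam], CLADES, "Kor") == ["f"]

    def test_missing_tree_errors(self):
        with pytest.raises(ValueError, match="f9"):
            monophyly_screen([GeneFamily("f9", copy_counts={"K1": 1})], CLADES, "Kor")


class TestContaminationScreen:
    def test_clean_spanning_side_kept(self):
        fam = _fam_with_tree(
            "f", "(((K1|1,K2|1),K3|1),(E1|1,D1|1));",
            {"K1": 1, "K2": 1, "K3": 1, "E1": 1, "D1": 1},
        )
        assert contamination_screen([fam], CLADES, "Kor", {"Eury", "DPANN"}) == ["f"]

    def test_excluded_leaf_inside_side_discards(self):
        # minimal side spanning {K1,K2,K3} necessarily includes E1
        fam = _fam_with_tree(
            "f", "(((K1|1,E1|1),(K2|1,K3|1)),(E2|1,D1|1));",
            {"K1": 1, "K2": 1, "K3": 1, "E1": 1, "E2": 1, "D1": 1},
        )
        assert contamination_screen([fam], CLADES, "Kor", {"Eury", "DPANN"}) == []

    def test_non_excluded_intruder_tolerated(self):
        fam = _fam_with_tree(
            "f", "(((K1|1,E1|1),(K2|1,K3|1)),(E2|1,D1|1));",
            {"K1": 1, "K2": 1, "K3": 1, "E1": 1, "E2": 1, "D1": 1},
        )
        # the intruder E1 is only contaminating when its clade is excluded
        assert contamination_screen([fam], CLADES, "Kor", {"DPANN"}) == ["f"]
        clades = dict(CLADES, E1="TACK")
        assert contamination_screen([fam], clades, "Kor", {"Eury", "DPANN"}) == ["f"]


class TestTrim:
    def test_ten_percent_gap_column_removed(self):
        rows = ["A-"] + ["AA"] * 9  # col 1 has 1 gap in 10 rows = 10%
        aln = Alignment([f"s{i}" for i in range(10)], rows)
        trimmed, kept = trim_alignment(aln, 0.05)
        assert kept == [0]
        assert trimmed.n_cols == 1

    def test_exactly_five_percent_kept(self):
        rows = ["A-"] + ["AA"] * 19  # 1 gap in 20 rows = exactly 5%
        aln = Alignment([f"s{i}" for i in range(20)], rows)
        _, kept = trim_alignment(aln, 0.05)
        assert kept == [0, 1]

    def test_gapless_unchanged(self):
        aln = Alignment(["a", "b"], ["ACGT", "ACGT"])
        trimmed, kept = trim_alignment(aln, 0.05)
        assert kept == [0, 1, 2, 3]
        assert trimmed.rows == aln.rows

    def test_all_columns_removed_warns(self, caplog):
        aln = Alignment(["a", "b"], ["A-", "-A"])
        with caplog.at_level("WARNING"):
            trimmed, kept = trim_alignment(aln, 0.05)
        assert kept == [] and trimmed.n_cols == 0
        assert "gap threshold" in caplog.text


class TestConcatenate:
    def test_partition_intervals(self):
        a1 = Alignment(["g1", "g2"], ["A" * 10, "C" * 10])
        a2 = Alignment(["g1", "g2"], ["G" * 15, "T" * 15])
        sup, parts = concatenate({"f1": a1, "f2": a2}, ["g1", "g2"])
        assert sup.n_cols == 25
        assert parts == [("f1", 0, 10), ("f2", 10, 25)]

    def test_missing_genome_gets_gap_filler(self):
        a1 = Alignment(["g1", "g2"], ["AAAA", "CCCC"])
        a2 = Alignment(["g1"], ["GGG"])
        sup, _ = concatenate({"f1": a1, "f2": a2}, ["g1", "g2"])
        assert sup["g2"] == "CCCC---"

    def test_roundtrip_decomposition(self, rng):
        fams = {}
        genomes = [f"g{i}" for i in range(4)]
        for k in range(3):
            width = int(rng.integers(3, 9))
            present = [g for g in genomes if rng.random() > 0.3] or [genomes[0]]
            fams[f"f{k}"] = Alignment(
                present,
                ["".join(rng.choice(list("ACGT"), size=width)) for _ in present],
            )
        sup, parts = concatenate(fams, genomes)
        for fam_id, s, e in parts:
            block = fams[fam_id]
            for g in genomes:
                got = sup[g][s:e]
                assert got == (block[g] if g in block else "-" * (e - s))

    def test_duplicate_genome_errors(self):
        bad = Alignment(["g1", "g1b"], ["AA", "CC"])
        bad.labels = ["g1", "g1"]  # simulate a single-copy violation
        with pytest.raises(ValueError, match="duplicate"):
            concatenate({"f1": bad}, ["g1"])


@pytest.fixture(scope="module")
def planted():
    tree, cmap = simulate_species_tree(
        SpeciesTreeSimParams(clades={"Kor": 6, "Eury": 4, "DPANN": 3}, seed=21)
    )
    genomes = [
        GenomeRecord(l, phylum=c, group=c, completeness=95.0, length_bp=10)
        for l, c in cmap.items()
    ]
    return tree, cmap, genomes


class TestRunMarkerScreen:
    def test_clean_dataset_all_pass(self, planted):
        tree, cmap, genomes = planted
        fams, vertical = simulate_marker_families(
            tree, cmap, "Kor", n_vertical=6, n_disrupted=0, seq_length=40, seed=1
        )
        cfg = ScreenConfig(focal="Kor", excluded={"Eury", "DPANN"})
        report = run_marker_screen(fams, genomes, cfg)
        assert report.verdicts["kept"].all()
        assert report.supermatrix.n_seqs == len(genomes)
        assert report.supermatrix.n_cols == 6 * 40

    def test_planted_recovery(self, planted):
        tree, cmap, genomes = planted
        fams, vertical = simulate_marker_families(
            tree, cmap, "Kor", n_vertical=12, n_disrupted=8, seq_length=0, seed=5
        )
        cfg = ScreenConfig(focal="Kor", excluded={"Eury", "DPANN"})
        report = run_marker_screen(fams, genomes, cfg)
        kept = set(report.kept_families)
        tp = len(kept & vertical)
        assert tp / len(kept) >= 0.9       # precision
        assert tp / len(vertical) >= 0.9   # recall

    def test_first_failure_reasons_and_idempotence(self, planted):
        tree, cmap, genomes = planted
        fams, _ = simulate_marker_families(
            tree, cmap, "Kor", n_vertical=4, n_disrupted=4, seq_length=0, seed=3
        )
        cfg = ScreenConfig(focal="Kor", excluded={"Eury", "DPANN"})
        r1 = run_marker_screen(fams, genomes, cfg)
        r2 = run_marker_screen(fams, genomes, cfg)
        assert r1.verdicts.equals(r2.verdicts)
        valid = {"kept", R_MULTI_COPY, R_OCCUPANCY, R_NON_MONOPHYLETIC, R_CONTAMINATION}
        assert set(r1.verdicts["reason"]) <= valid

    def test_empty_family_list(self, planted, caplog):
        _, _, genomes = planted
        cfg = ScreenConfig(focal="Kor")
        with caplog.at_level("WARNING"):
            report = run_marker_screen([], genomes, cfg)
        assert report.verdicts.empty and report.supermatrix is None


class TestIO:
    def test_genomes_tsv_roundtrip(self, tmp_path):
        gs = [_genome("a", 90.0), _genome("b", 86.5, phylum="Eury")]
        write_genomes_tsv(tmp_path / "g.tsv", gs)
        back = read_genomes_tsv(tmp_path / "g.tsv")
        assert [(g.id, g.phylum, g.completeness) for g in back] == [
            ("a", "Kor", 90.0), ("b", "Eury", 86.5)
        ]

    def test_families_roundtrip(self, tmp_path, planted):
        tree, cmap, genomes = planted
        fams, _ = simulate_marker_families(
            tree, cmap, "Kor", n_vertical=2, n_disrupted=1, seq_length=30, seed=7
        )
        write_families(tmp_path, fams, [g.id for g in genomes])
        back = load_families(tmp_path, counts_tsv=tmp_path / "copy_counts.tsv")
        assert {f.id for f in back} == {f.id for f in fams}
        orig = {f.id: f for f in fams}
        for f in back:
            assert f.copy_counts == {
                g: c for g, c in orig[f.id].copy_counts.items()
            }
            assert f.tree is not None
            assert f.tree.leaf_labels == orig[f.id].tree.leaf_labels
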