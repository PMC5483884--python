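"""Orthogroup parsing, classification, annotation transfer and summaries."""

import pytest

from radmarker.synthetic import fixture_path, gen_orthogroup_corpus, worked_example
from radmarker.transfer import (
    IdMap,
    OrthoGroup,
    classify_groups,
    find_counterpart_orthologs,
    load_idmap,
    load_orthogroups,
    round_pct,
    summarize,
    transfer,
    write_orthogroups,
)

from conftest import transfer_oracle


class TestLoadOrthogroups:
    def test_minimal_line(self, tmp_path):
        p = tmp_path / "g.txt"
        p.write_text("OG1: hsa|P1 ath|Q1\n")
        groups = load_orthogroups(p)
        assert len(groups) == 1
        assert groups[0].members == {("hsa", "P1"), ("ath", "Q1")}

    def test_empty_file(self, tmp_path):
        p = tmp_path / "g.txt"
        p.write_text("")
        assert load_orthogroups(p) == []

    def test_malformed_member_reports_line(self, tmp_path):
        p = tmp_path / "g.txt"
        p.write_text("OG1: hsa|P1\nOG2: nodelimiter\n")
        with pytest.raises(ValueError, match=":2"):
            load_orthogroups(p)

    def test_duplicate_group_id_rejected(self, tmp_path):
        p = tmp_path / "g.txt"
        p.write_text("OG1: hsa|P1\nOG1: ath|Q1\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_orthogroups(p)

    def test_extra_taxa_are_kept(self, tmp_path):
        p = tmp_path / "g.txt"
        p.write_text("OG1: hsa|P1 ath|Q1 osa|R1\n")
        (group,) = load_orthogroups(p)
        assert ("osa", "R1") in group.members

    def test_round_trip(self, tmp_path):
        groups, *_ = worked_example()
        out = tmp_path / "rt.txt"
        write_orthogroups(groups, out)
        assert load_orthogroups(out) == sorted(groups, key=lambda g: g.group_id)


class TestClassifyGroups:
    def test_worked_example_composition(self):
        """Groups A-C hold both taxa, D-E only plant genes, F only human."""
        groups, *_ = worked_example()
        cls = classify_groups(groups, "hsa", "ath")
        assert cls == {
            "A": "both", "B": "both", "C": "both",
            "D": "B_only", "E": "B_only", "F": "A_only",
        }

    def test_group_with_neither_taxon(self):
        g = OrthoGroup("OGX", frozenset({("osa", "R1")}))
        assert classify_groups([g], "hsa", "ath")["OGX"] == "neither"

    def test_identical_taxa_rejected(self):
        with pytest.raises(ValueError):
            classify_groups([], "hsa", "hsa")

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_membership_oracle(self, seed):
        groups, _a, _b, _t = gen_orthogroup_corpus(100, 40, 10, seed=seed)
        cls = classify_groups(groups, "hsa", "ath")
        for group in groups:
            has_a = any(t == "hsa" for t, _ in group.members)
            has_b = any(t == "ath" for t, _ in group.members)
            expected = (
                "both" if has_a and has_b else
                "A_only" if has_a else
                "B_only" if has_b else "neither"
            )
            assert cls[group.group_id] == expected


class TestTransfer:
    def test_worked_example_relations_depth1(self):
        groups, ann_a, ann_b, exp = worked_example()
        res = transfer(ann_a, ann_b, groups, "hsa", "ath", expansion_depth=1)
        assert exp["pairs"] <= res.pairs
        assert exp["new_A"] <= res.new_A
        assert exp["new_B"] <= res.new_B
        assert exp["expansion_new"] <= res.expansion_new
        assert exp["excluded_groups"] <= res.excluded_groups

    def test_second_hop_gene_requires_depth1(self):
        """Gene iv sits in a plant-only group reachable only via annotated ii,
        so it appears at depth 1 and not at depth 0."""
        groups, ann_a, ann_b, _ = worked_example()
        d0 = transfer(ann_a, ann_b, groups, "hsa", "ath", expansion_depth=0)
        d1 = transfer(ann_a, ann_b, groups, "hsa", "ath", expansion_depth=1)
        assert ("ath", "iv") not in d0.expansion_new
        assert ("ath", "iv") in d1.expansion_new

    def test_depth0_subset_of_depth1(self):
        groups, ann_a, ann_b, _ = worked_example()
        d0 = transfer(ann_a, ann_b, groups, "hsa", "ath", 0)
        d1 = transfer(ann_a, ann_b, groups, "hsa", "ath", 1)
        assert d0.pairs <= d1.pairs and d0.new_A <= d1.new_A
        assert d0.new_B <= d1.new_B and d0.expansion_new <= d1.expansion_new

    def test_symmetry_under_taxon_swap(self):
        groups, ann_a, ann_b, _ = worked_example()
        fwd = transfer(ann_a, ann_b, groups, "hsa", "ath", 1)
        rev = transfer(ann_b, ann_a, groups, "ath", "hsa", 1)
        assert rev.pairs == {(b, a) for a, b in fwd.pairs}
        assert rev.new_A == fwd.new_B and rev.new_B == fwd.new_A
        assert rev.expansion_new == fwd.expansion_new
        assert rev.excluded_groups == fwd.excluded_groups

    def test_empty_annotations_inert(self):
        groups, *_ = worked_example()
        res = transfer(set(), set(), groups, "hsa", "ath", 1)
        assert not res.pairs and not res.new_A and not res.new_B
        assert not res.expansion_new and not res.excluded_groups

    def test_annotating_a_new_gene_moves_it_to_pairs(self):
        """Adding the annotation for a gene listed as new removes it from
        new_B and can only add pairs."""
        groups, ann_a, ann_b, _ = worked_example()
        base = transfer(ann_a, ann_b, groups, "hsa", "ath", 0)
        assert "i" in base.new_B
        richer = transfer(ann_a, ann_b | {"i"}, groups, "hsa", "ath", 0)
        assert "i" not in richer.new_B
        assert base.pairs <= richer.pairs
        assert ("a", "i") in richer.pairs

    def test_invalid_depth(self):
        with pytest.raises(ValueError):
            transfer(set(), set(), [], "hsa", "ath", expansion_depth=2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_triple_scan_oracle(self, seed):
        groups, ann_a, ann_b, _ = gen_orthogroup_corpus(30, 50, 8, seed=seed)
        res = transfer(ann_a, ann_b, groups, "hsa", "ath", 0)
        pairs, new_a, new_b, excluded = transfer_oracle(
            ann_a, ann_b, groups, "hsa", "ath"
        )
        assert res.pairs == pairs
        assert res.new_A == new_a and res.new_B == new_b
        assert res.excluded_groups == excluded


class TestCounterpartLookup:
    @pytest.fixture()
    def lookup(self):
        groups = load_orthogroups(fixture_path("counterpart_groups.txt"))
        qmap = load_idmap(fixture_path("ath_idmap.tsv"), "ath")
        tmap = load_idmap(fixture_path("hsa_idmap.tsv"), "hsa")
        def run(genes):
            return find_counterpart_orthologs(genes, groups, qmap, tmap, "hsa")
        return run

    def test_rad54_resolves_to_both_human_paralogs(self, lookup):
        row = lookup({"RAD54"}).iloc[0]
        assert row.query_protein == "NP_188552"
        assert row.group_id == "OG5_127098"
        assert set(row.target_genes.split(";")) == {"RAD54B", "RAD54L"}

    def test_mc7_has_no_group_and_no_targets(self, lookup):
        row = lookup({"MC7"}).iloc[0]
        assert row.group_id == "none" and row.status == "no_group"
        assert row.target_genes == ""

    def test_msh5_isoforms_collapse_to_one_gene(self, lookup):
        row = lookup({"MSH5"}).iloc[0]
        assert len(row.target_proteins.split(";")) == 7
        assert row.target_genes == "MSH5"

    def test_plant_only_group_yields_no_targets(self, lookup):
        row = lookup({"TED4"}).iloc[0]
        assert row.group_id == "OG5_140322"
        assert row.target_genes == ""

    def test_unresolved_query_flagged(self, lookup):
        row = lookup({"NOSUCHGENE"}).iloc[0]
        assert row.status == "unresolved"


class TestSummarize:
    def _result(self, mech, pairs):
        from radmarker.transfer import TransferResult

        return TransferResult(mechanism=mech, pairs=set(pairs))

    def test_published_percentage_arithmetic(self):
        """507 annotated human genes, 259 with orthologues -> 51.1%."""
        res = self._result("DNA repair", {(f"h{i}", f"a{i % 185}") for i in range(259)})
        df = summarize([res], {"DNA repair": (507, 300)})
        row = df.iloc[0]
        assert row.pct_A == 51.1
        assert row.pct_B == 61.7

    def test_full_coverage_is_100(self):
        res = self._result("m", {(f"h{i}", "a0") for i in range(5)})
        df = summarize([res], {"m": (5, 1)})
        assert df.iloc[0].pct_A == 100.0 and df.iloc[0].pct_B == 100.0

    def test_nhej_low_coverage(self):
        res = self._result("NHEJ", {(f"h{i}", f"a{i % 4}") for i in range(9)})
        df = summarize([res], {"NHEJ": (73, 7)})
        assert df.iloc[0].pct_A == 12.3 and df.iloc[0].pct_B == 57.1

    def test_inconsistent_counts_rejected(self):
        res = self._result("m", {(f"h{i}", "a0") for i in range(10)})
        with pytest.raises(ValueError, match="exceed"):
            summarize([res], {"m": (5, 1)})

    def test_group_rule_counts_shared_group_members(self):
        from radmarker.transfer import TransferResult

        res = TransferResult(
            mechanism="m",
            in_shared_group_A={"h1", "h2", "h3"},
            in_shared_group_B={"a1"},
        )
        df = summarize([res], {"m": (4, 2)}, orth_count_rule="group")
        assert df.iloc[0].n_A_with_orth == 3
        assert df.iloc[0].pct_A == 75.0

    @pytest.mark.parametrize(
        "num,den,expected",
        [(259, 507, 51.1), (185, 300, 61.7), (32, 52, 61.5), (12, 29, 41.4),
         (59, 124, 47.6), (21, 30, 70.0), (14, 43, 32.6), (12, 17, 70.6),
         (76, 162, 46.9), (37, 50, 74.0), (9, 73, 12.3), (4, 7, 57.1)],
    )
    def test_half_up_rounding_reproduces_every_printed_percentage(
        self, num, den, expected
    ):
        assert round_pct(num, den) == expected

    def test_round_half_up_at_boundary(self):
        assert round_pct(1, 16) == 6.3  # 6.25 rounds up, not to even
        assert round_pct(0, 0) == 0.0
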