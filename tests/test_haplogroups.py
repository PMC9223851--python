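"""Haplogroup tree loading, parsimony assignment and the rapid panel."""

import pytest

from mitocommon.haplogroups import (
    HaplogroupTree,
    PanelError,
    TreeError,
    assign_haplogroup,
    evaluate_panel,
    first_level_summary,
    load_tree,
    rapid_panel_classify,
)
from mitocommon.nomenclature import make_haplotype
from mitocommon.stats import as_percent
from mitocommon.fixtures import panel_dataset

MINI_TREE = """\
H\t\t263G 750G
H1\tH\t3010A
H1q\tH1\t16037G
H1q3x\tH1q\t@16037 11266T
H23\tH\t10211T
"""


class TestTreeLoading:
    def test_bundled_tree_structure(self, tree):
        assert tree.root == "H"
        assert "H1e1a2" in tree and "H59a" in tree
        assert tree.nodes["H1e1a2"].parent == "H1e1a"
        assert tree.first_level("H1e1a2") == "H1"
        assert tree.first_level("H") == "H*"
        assert len(tree.children("H1")) >= 10

    def test_unknown_parent_rejected(self):
        with pytest.raises(TreeError, match="unknown parent"):
            load_tree("H\t\t263G\nH1\tHX\t3010A\n")

    def test_duplicate_name_rejected(self):
        with pytest.raises(TreeError, match="duplicate"):
            load_tree("H\t\t263G\nH1\tH\t\nH1\tH\t\n")

    def test_empty_input_rejected(self):
        with pytest.raises(TreeError):
            load_tree("")

    def test_two_roots_rejected(self):
        with pytest.raises(TreeError, match="root"):
            load_tree("H\t\t\nL\t\t\n")


class TestExpectedVariants:
    def test_accumulates_along_root_path(self, tree):
        exp = {f"{v.position}{v.observed}" for v in tree.expected_variants("H1")}
        assert "3010A" in exp
        assert {"263G", "750G", "16519C"} <= exp

    def test_root_is_its_own_signature(self):
        t = load_tree(MINI_TREE)
        exp = {f"{v.position}{v.observed}" for v in t.expected_variants("H")}
        assert exp == {"263G", "750G"}

    def test_back_mutation_cancels_ancestral_variant(self):
        t = load_tree(MINI_TREE)
        exp = {f"{v.position}{v.observed}" for v in t.expected_variants("H1q3x")}
        assert "16037G" not in exp
        assert "11266T" in exp

    def test_back_mutation_without_target_rejected(self):
        with pytest.raises(TreeError, match="reverts nothing"):
            load_tree("H\t\t263G\nHx\tH\t@5000\n").expected_variants("Hx")


class TestMrca:
    def test_siblings(self, tree):
        assert tree.mrca(["H1", "H23"]) == "H"
        assert tree.mrca(["H3ap", "H3ag"]) == "H3"

    def test_single_node(self, tree):
        assert tree.mrca(["H1e1a2"]) == "H1e1a2"

    def test_node_with_its_ancestor(self, tree):
        assert tree.mrca(["H1e1a2", "H1e"]) == "H1e"

    def test_commutative(self, tree):
        assert tree.mrca(["H7b1", "H13a2a"]) == tree.mrca(["H13a2a", "H7b1"])

    def test_empty_rejected(self, tree):
        with pytest.raises(TreeError):
            tree.mrca([])


class TestAssignment:
    def test_exact_h_representative(self, tree, mk):
        r = assign_haplogroup(mk("x"), tree)
        assert r.call == "H"
        assert r.best_cost == 0.0
        assert not r.mrca_applied

    def test_exact_terminal_placement(self, tree, reference):
        exp = tree.expected_variants("H1e1a2")
        h = make_haplotype(
            "x", " ".join(sorted(
                f"{v.position}.{v.insertion_index}{v.observed}"
                if v.insertion_index else f"{v.position}{v.observed}"
                for v in exp
            ))
        )
        r = assign_haplogroup(h, tree)
        assert r.call == "H1e1a2"
        assert r.best_cost == 0.0

    def test_mrca_fallback_on_tied_candidates(self, tree, mk):
        """3010A + 10211T costs one on both H1 and H23 -> paragroup H."""
        r = assign_haplogroup(mk("x", "3010A 10211T"), tree)
        assert r.mrca_applied
        assert r.call == "H"
        tied = {c.name for c in r.candidates if c.cost == r.best_cost}
        assert tied == {"H1", "H23"}

    def test_private_variant_does_not_change_call(self, tree, mk):
        base_call = assign_haplogroup(mk("x", "3010A"), tree)
        with_private = assign_haplogroup(mk("x", "3010A 14000C"), tree)
        assert base_call.call == with_private.call == "H1"
        assert with_private.best_cost == base_call.best_cost + 1.0

    def test_php_at_signature_np_counts_as_carried(self, tree, mk):
        r = assign_haplogroup(mk("x", "3010R"), tree)
        assert r.call == "H1"
        assert r.best_cost == 0.0

    def test_noise_free_signature_haplotypes_assign_exactly(self, tree, reference):
        for name in tree.nodes:
            exp = tree.expected_variants(name)
            tokens = " ".join(
                f"{v.position}.{v.insertion_index}{v.observed}"
                if v.insertion_index else f"{v.position}{v.observed}"
                for v in sorted(exp)
            )
            r = assign_haplogroup(make_haplotype(name, tokens), tree)
            assert r.call == name
            assert r.best_cost == 0.0


class TestRapidPanel:
    def test_marker_classification(self, mk):
        assert rapid_panel_classify(mk("x", "3010A")).label == "H1"
        assert rapid_panel_classify(mk("x", "6776C")).label == "H3"
        assert rapid_panel_classify(mk("x", "4793G")).label == "H7"
        assert rapid_panel_classify(mk("x")).label == "other"

    def test_php_at_marker_counts_as_derived(self, mk):
        assert rapid_panel_classify(mk("x", "3010R")).label == "H1"

    def test_conflicting_markers_flagged(self, mk):
        assert rapid_panel_classify(mk("x", "3010A 6776C")).conflict

    def test_missing_coverage_rejected(self):
        h = make_haplotype("x", "263G", range_start=16024, range_end=576)
        with pytest.raises(PanelError):
            rapid_panel_classify(h)

    def test_printed_class_sizes_reproduce_statistics(self):
        fp = evaluate_panel(panel_dataset())
        assert sorted(fp.group_sizes, reverse=True) == [98, 72, 30, 16]
        assert as_percent(fp.RMP) == 34.2
        assert as_percent(fp.HD) == 66.1
        assert round(fp.DC, 3) == 0.019

    def test_four_equal_classes(self, mk):
        hs = (
            [mk(f"a{i}", "3010A") for i in range(4)]
            + [mk(f"b{i}", "6776C") for i in range(4)]
            + [mk(f"c{i}", "4793G") for i in range(4)]
            + [mk(f"d{i}") for i in range(4)]
        )
        fp = evaluate_panel(hs)
        assert fp.RMP == pytest.approx(0.25)


class TestFirstLevelSummary:
    def test_study_inventory_percentages(self, tree):
        """Table-level counts aggregate to H1 44.0%, H3 13.9%, H7 7.4%."""
        from mitocommon.simulate import TABLE_FIRST_LEVEL_COUNTS

        calls = {}
        i = 0
        for level, n in TABLE_FIRST_LEVEL_COUNTS.items():
            name = "H" if level == "H*" else level
            for _ in range(n):
                calls[f"s{i}"] = name
                i += 1
        df = first_level_summary(calls, tree).set_index("first_level")
        assert df.loc["H1", "percent"] == 44.0
        assert df.loc["H3", "percent"] == 13.9
        assert df.loc["H7", "percent"] == 7.4
        assert df.loc["H*", "percent"] == 13.9
        assert df.loc["H13", "percent"] == 2.3
        assert df["n"].sum() == 216

    def test_terminal_calls_aggregate_to_first_level(self, tree):
        df = first_level_summary(
            {"a": "H1e1a2", "b": "H1c2", "c": "H"}, tree
        ).set_index("first_level")
        assert df.loc["H1", "n"] == 2
        assert df.loc["H*", "n"] == 1
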