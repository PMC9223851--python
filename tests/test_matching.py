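"""MCH screening, heteroplasmy-aware matching and identity partitions."""

import pytest

from mitocommon.matching import (
    DEFAULT_RULES,
    RangeError,
    Scenario,
    build_identity_partition,
    comparable_variants,
    haplotypes_match,
    is_mch,
    shared_variant_clusters,
)
from mitocommon.nomenclature import make_haplotype, serialize_variant
from mitocommon.fixtures import paper_partition_dataset


def tokens(h, rules=DEFAULT_RULES):
    return [serialize_variant(v) for v in comparable_variants(h, rules)]


class TestComparableVariants:
    def test_strips_c_stretch_but_keeps_motif_insertion(self):
        h = make_haplotype("x", "263G 309.1C 315.1C 16519C")
        assert tokens(h) == ["263G", "315.1C", "16519C"]

    def test_strips_heteroplasmic_dinucleotide_insertion(self):
        h = make_haplotype("x", "263G 315.1C 524.1a 524.2c 16519C")
        assert tokens(h) == ["263G", "315.1C", "16519C"]

    def test_strips_dinucleotide_deletions(self):
        h = make_haplotype("x", "523DEL 524DEL")
        assert tokens(h) == []

    def test_strips_extra_315_insertions_only(self):
        h = make_haplotype("x", "315.1C 315.2C 573.1C 16193.1C")
        assert tokens(h) == ["315.1C"]

    def test_empty(self):
        assert tokens(make_haplotype("x", "")) == []

    def test_retains_phps_and_ordinary_variants(self):
        h = make_haplotype("x", "263G 6253Y 8251R")
        assert tokens(h) == ["263G", "6253Y", "8251R"]


class TestIsMch:
    def test_exact_motif(self):
        assert is_mch(make_haplotype("x", "263G 315.1C 16519C"))

    def test_codr_variants_do_not_matter(self):
        assert is_mch(make_haplotype("x", "263G 315.1C 3010A 6253C 16519C"))

    def test_php_not_preclusive(self):
        assert is_mch(make_haplotype("x", "146Y 263G 315.1C 16519C"))

    def test_length_variants_not_preclusive(self):
        assert is_mch(
            make_haplotype("x", "263G 309.1C 315.1C 524.1a 524.2c 16519C")
        )

    def test_extra_fixed_cr_variant_precludes(self):
        assert not is_mch(make_haplotype("x", "263G 315.1C 16311C 16519C"))

    def test_missing_motif_member_precludes(self):
        assert not is_mch(make_haplotype("x", "263G 315.1C"))

    def test_motif_member_as_php_still_mch(self):
        # 263R contains the motif base G and 16519Y contains C
        assert is_mch(make_haplotype("x", "263R 315.1C 16519Y"))

    def test_cr_php_excluding_reference_precludes(self):
        # 146S = {C,G} excludes both motif bases and the reference T
        assert not is_mch(make_haplotype("x", "146S 263G 315.1C 16519C"))

    def test_range_must_cover_cr(self):
        h = make_haplotype("x", "263G 315.1C", range_start=1, range_end=600)
        with pytest.raises(RangeError):
            is_mch(h)


class TestHaplotypesMatch:
    def test_php_matches_reference_carrier(self):
        h1 = make_haplotype("a", "263G 6253Y")
        h2 = make_haplotype("b", "263G")
        assert haplotypes_match(h1, h2)
        assert haplotypes_match(h2, h1)

    def test_php_matches_fixed_alternative(self):
        h1 = make_haplotype("a", "263G 6253Y")
        h2 = make_haplotype("b", "263G 6253C")
        assert haplotypes_match(h1, h2)

    def test_fixed_difference_precludes(self):
        h1 = make_haplotype("a", "263G 6253C")
        h2 = make_haplotype("b", "263G")
        assert not haplotypes_match(h1, h2)

    def test_reflexive_and_symmetric(self):
        h1 = make_haplotype("a", "263G 315.1C 3010A")
        h2 = make_haplotype("b", "263G 315.1C 3010A 309.1C")
        assert haplotypes_match(h1, h1)
        assert haplotypes_match(h1, h2) == haplotypes_match(h2, h1) is True

    def test_incomparable_ranges_error(self):
        h1 = make_haplotype("a", "263G")
        h2 = make_haplotype("b", "263G", range_start=16024, range_end=576)
        with pytest.raises(RangeError):
            haplotypes_match(h1, h2)


class TestIdentityPartition:
    def test_all_distinct_gives_singletons(self):
        hs = [make_haplotype(f"s{i}", f"{5000 + i}A") for i in range(5)]
        p = build_identity_partition(hs)
        assert sorted(p.group_sizes) == [1] * 5
        assert p.total_membership == p.N == 5

    def test_identical_copies_group(self):
        hs = [make_haplotype(f"s{i}", "263G 3010A") for i in range(4)]
        p = build_identity_partition(hs)
        assert p.group_sizes == [4]

    def test_double_match_structure(self):
        """A PHP carrier bridging a sextet and a 6253C singleton yields a
        septet and a pair sharing that sample, total membership N+1."""
        hs = [make_haplotype(f"s{i}", "3010A") for i in range(6)]
        hs.append(make_haplotype("het", "3010A 6253Y"))
        hs.append(make_haplotype("alt", "3010A 6253C"))
        p = build_identity_partition(hs, scenario=Scenario.DOUBLE_MATCH)
        assert sorted(p.group_sizes) == [2, 7]
        assert p.N == 8
        assert p.total_membership == 9
        members = [set(g) for g in p.groups]
        assert all("het" in g for g in members)

    def test_inflate_total_same_groups_larger_n(self):
        hs = [make_haplotype(f"s{i}", "3010A") for i in range(6)]
        hs.append(make_haplotype("het", "3010A 6253Y"))
        hs.append(make_haplotype("alt", "3010A 6253C"))
        p2 = build_identity_partition(hs, scenario=Scenario.INFLATE_TOTAL)
        assert sorted(p2.group_sizes) == [2, 7]
        assert p2.N == 9

    @pytest.mark.parametrize(
        "scenario, expected_sizes",
        [
            (Scenario.ASSIGN_TO_MAJOR, [1, 7]),
            (Scenario.ASSIGN_TO_MINOR, [2, 6]),
        ],
    )
    def test_assign_scenarios(self, scenario, expected_sizes):
        hs = [make_haplotype(f"s{i}", "3010A") for i in range(6)]
        hs.append(make_haplotype("het", "3010A 6253Y"))
        hs.append(make_haplotype("alt", "3010A 6253C"))
        p = build_identity_partition(hs, scenario=scenario)
        assert sorted(p.group_sizes) == expected_sizes
        assert p.N == p.total_membership == 8

    def test_php_free_data_is_true_partition(self):
        hs = [
            make_haplotype(f"s{i}", f"{5000 + i % 3}A 263G") for i in range(9)
        ]
        for scenario in Scenario:
            p = build_identity_partition(hs, scenario=scenario)
            assert p.total_membership == p.N == 9
            assert sorted(p.group_sizes) == [3, 3, 3]

    def test_unmatched_php_carriers_group_together(self):
        hs = [
            make_haplotype("a", "3010A 9180R"),
            make_haplotype("b", "3010A 9180R"),
            make_haplotype("c", "5000A"),
        ]
        p = build_identity_partition(hs)
        assert sorted(p.group_sizes) == [1, 2]

    def test_paper_dataset_reproduces_printed_structure(self):
        """216 reconstructed mitogenomes give the printed partition: one
        septet and a pair sharing the heteroplasmic sample, two quintets,
        two quartets, seven triplets, 20 pairs, 131 singletons."""
        hs = paper_partition_dataset()
        p = build_identity_partition(hs)
        sizes = sorted(p.group_sizes, reverse=True)
        assert sizes[:5] == [7, 5, 5, 4, 4]
        assert sizes.count(3) == 7
        assert sizes.count(2) == 20
        assert sizes.count(1) == 131
        assert p.N == 216
        assert p.total_membership == 217
        in_two = [
            sid
            for sid in {m for g in p.groups for m in g}
            if sum(sid in g for g in p.groups) == 2
        ]
        assert in_two == ["UniPV_046"]


class TestSharedVariantClusters:
    def _expected(self, hs, call="H", expected_set=frozenset()):
        return {h.sample_id: (call, expected_set) for h in hs}

    def test_shared_triple_pattern(self, tree):
        exp = tree.expected_variants("H")
        hs = [
            make_haplotype(f"s{i}", "263G 315.1C 750G 1438G 4769G 8860G "
                                    "15326G 16519C 930A 3531A 4703C")
            for i in range(3)
        ]
        clusters = shared_variant_clusters(
            hs, {h.sample_id: ("H", exp) for h in hs}, min_shared=3
        )
        assert len(clusters) == 1
        assert clusters[0].label == "H-930A-3531A-4703C"
        assert len(clusters[0].members) == 3

    def test_single_shared_variant(self, tree):
        exp = tree.expected_variants("H1")
        base = "263G 315.1C 750G 1438G 4769G 8860G 15326G 16519C 3010A"
        hs = [
            make_haplotype(f"s{i}", f"{base} 15217A" + (f" {6000+i}A" if i else ""))
            for i in range(7)
        ]
        clusters = shared_variant_clusters(
            hs, {h.sample_id: ("H1", exp) for h in hs}, min_shared=1
        )
        labels = [c.label for c in clusters]
        assert "H1-15217A" in labels
        big = next(c for c in clusters if c.label == "H1-15217A")
        assert len(big.members) == 7

    def test_no_shared_extras_no_clusters(self, tree):
        exp = tree.expected_variants("H")
        hs = [
            make_haplotype("a", "263G 315.1C 750G 1438G 4769G 8860G 15326G "
                                "16519C 6000A"),
            make_haplotype("b", "263G 315.1C 750G 1438G 4769G 8860G 15326G "
                                "16519C 7000A"),
        ]
        assert shared_variant_clusters(
            hs, {h.sample_id: ("H", exp) for h in hs}
        ) == []
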