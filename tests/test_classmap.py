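"""Domain-classification reconciliation: overlaps, consensus, tiers."""

from __future__ import annotations

import numpy as np
import pytest

from modelsup.classmap import (ClassifiedDomain, ConsensusTier, Segment,
                               SuperfamilyPairStats, aggregate_pairs,
                               assign_tier, classify, consensus_pairs,
                               domain_overlap, read_classification_tsv,
                               write_classification_tsv)

from oracles import brute_force_tiers, random_classifications


def dom(did, sf, *segs):
    return ClassifiedDomain(did, sf, tuple(Segment(*s) for s in segs))


class TestDomainOverlap:
    def test_identical_segments(self):
        d1 = dom("a", "sf1", ("1abc", "A", 1, 100))
        d2 = dom("b", "sf2", ("1abc", "A", 1, 100))
        assert domain_overlap(d1, d2) == 100

    def test_partial_interval_intersection(self):
        d1 = dom("a", "sf1", ("1abc", "A", 1, 50))
        d2 = dom("b", "sf2", ("1abc", "A", 41, 90))
        assert domain_overlap(d1, d2) == 10

    def test_different_chain_or_structure_is_zero(self):
        d1 = dom("a", "sf1", ("1abc", "A", 1, 50))
        assert domain_overlap(d1, dom("b", "sf2", ("1abc", "B", 1, 50))) == 0
        assert domain_overlap(d1, dom("c", "sf2", ("2xyz", "A", 1, 50))) == 0

    def test_multi_segment_matches_set_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b = random_classifications(rng, max_sf=1, max_dom=1)
            d1, d2 = a[0], b[0]
            s1 = {(s.structure_id, s.chain_id, p)
                  for s in d1.segments for p in range(s.start, s.end + 1)}
            s2 = {(s.structure_id, s.chain_id, p)
                  for s in d2.segments for p in range(s.start, s.end + 1)}
            assert domain_overlap(d1, d2) == len(s1 & s2)

    def test_overlapping_segments_within_domain_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            dom("a", "sf", ("1abc", "A", 1, 50), ("1abc", "A", 40, 80))


class TestAggregatePairs:
    def test_single_overlapping_pair(self):
        a = [dom("a1", "sfA", ("s1", "A", 1, 100))]
        b = [dom("b1", "sfB", ("s1", "A", 1, 100))]
        stats = aggregate_pairs(a, b)
        assert len(stats) == 1
        s = stats[0]
        assert (s.sf_a, s.sf_b) == ("sfA", "sfB")
        assert s.shared_residues == 100
        assert s.mapped_domains_a == s.mapped_domains_b == 1
        assert s.classifiable_domains_a == s.classifiable_domains_b == 1
        assert s.overlap_fracs_a == (1.0,)

    def test_domain_on_foreign_structure_not_classifiable(self):
        a = [dom("a1", "sfA", ("s1", "A", 1, 100)),
             dom("a2", "sfA", ("s9", "A", 1, 100))]  # s9 absent from B
        b = [dom("b1", "sfB", ("s1", "A", 1, 100))]
        stats = aggregate_pairs(a, b)
        assert stats[0].classifiable_domains_a == 1
        assert stats[0].mapped_domains_a == 1

    def test_duplicate_domain_ids_rejected(self):
        a = [dom("a1", "sfA", ("s1", "A", 1, 10)),
             dom("a1", "sfA", ("s2", "A", 1, 10))]
        with pytest.raises(ValueError, match="duplicate"):
            aggregate_pairs(a, [])


class TestConsensusPairs:
    def test_two_disjoint_perfect_pairs(self):
        a = [dom("a1", "sfA1", ("s1", "A", 1, 50)),
             dom("a2", "sfA2", ("s2", "A", 1, 50))]
        b = [dom("b1", "sfB1", ("s1", "A", 1, 50)),
             dom("b2", "sfB2", ("s2", "A", 1, 50))]
        stats = aggregate_pairs(a, b)
        assert consensus_pairs(stats) == {("sfA1", "sfB1"), ("sfA2", "sfB2")}

    def test_non_mutual_best_excluded(self):
        # sfB's best is sfA2 (60 residues); sfA1's best is sfB but not mutual
        a = [dom("a1", "sfA1", ("s1", "A", 1, 30)),
             dom("a2", "sfA2", ("s1", "A", 31, 90))]
        b = [dom("b1", "sfB", ("s1", "A", 1, 90))]
        stats = aggregate_pairs(a, b)
        assert consensus_pairs(stats) == {("sfA2", "sfB")}

    def test_exact_tie_is_ambiguous(self):
        a = [dom("a1", "sfA", ("s1", "A", 1, 90))]
        b = [dom("b1", "sfB1", ("s1", "A", 1, 30)),
             dom("b2", "sfB2", ("s1", "A", 61, 90))]
        stats = aggregate_pairs(a, b)
        assert consensus_pairs(stats) == set()


class TestAssignTier:
    def _stats(self, fracs_a, fracs_b, mapped_a=None, mapped_b=None,
               cls_a=None, cls_b=None):
        mapped_a = len(fracs_a) if mapped_a is None else mapped_a
        mapped_b = len(fracs_b) if mapped_b is None else mapped_b
        return SuperfamilyPairStats(
            sf_a="a", sf_b="b", shared_residues=100,
            mapped_domains_a=mapped_a, mapped_domains_b=mapped_b,
            classifiable_domains_a=cls_a or mapped_a,
            classifiable_domains_b=cls_b or mapped_b,
            overlap_fracs_a=tuple(fracs_a), overlap_fracs_b=tuple(fracs_b))

    def test_not_consensus_is_none(self):
        s = self._stats([1.0], [1.0])
        assert assign_tier(s, False) is ConsensusTier.NONE

    def test_all_perfect_is_gold(self):
        s = self._stats([1.0] * 5, [1.0] * 5)
        assert assign_tier(s, True) is ConsensusTier.GOLD

    def test_low_minimum_caps_at_silver(self):
        s = self._stats([1.0, 1.0, 1.0, 1.0, 0.5], [1.0] * 5)
        assert assign_tier(s, True) is ConsensusTier.SILVER

    def test_exact_080_boundary_is_inclusive(self):
        s = self._stats([0.8, 0.8, 0.8], [0.8, 0.8, 0.8])
        assert assign_tier(s, True) is ConsensusTier.GOLD
        # domain-mapping fraction exactly 0.8 as well
        s2 = self._stats([0.8] * 4, [0.8] * 4, cls_a=5, cls_b=5)
        assert assign_tier(s2, True) is ConsensusTier.GOLD

    def test_low_domain_mapping_caps_at_bronze(self):
        s = self._stats([1.0] * 3, [1.0] * 3, cls_a=5)
        assert assign_tier(s, True) is ConsensusTier.BRONZE

    def test_low_mean_caps_at_bronze(self):
        s = self._stats([1.0, 0.5, 0.5, 0.5], [1.0] * 4)
        assert assign_tier(s, True) is ConsensusTier.BRONZE

    def test_zero_classifiable_fails_silver(self):
        s = self._stats([1.0], [1.0], cls_a=0)
        s = SuperfamilyPairStats(**{**s.__dict__, "classifiable_domains_a": 0})
        assert assign_tier(s, True) is ConsensusTier.BRONZE


class TestPipelineProperties:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            a, b = random_classifications(rng)
            graded = classify(a, b)
            got = {(s.sf_a, s.sf_b): tier.name for s, tier in graded}
            assert got == brute_force_tiers(a, b)

    def test_tier_nesting(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            a, b = random_classifications(rng)
            for s, tier in classify(a, b):
                if tier >= ConsensusTier.SILVER:
                    assert assign_tier(s, True) >= ConsensusTier.SILVER
                if tier is ConsensusTier.GOLD:
                    assert min(s.overlap_fracs_a) >= 0.8
                    assert min(s.overlap_fracs_b) >= 0.8

    def test_swap_symmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            a, b = random_classifications(rng)
            fwd = {(s.sf_a, s.sf_b): t for s, t in classify(a, b)}
            rev = {(s.sf_b, s.sf_a): t for s, t in classify(b, a)}
            assert fwd == rev

    def test_raising_one_fraction_never_lowers_tier(self):
        base = [0.7, 0.8, 0.85]
        sb = (1.0, 1.0, 1.0)
        tiers = []
        for bump in (0.0, 0.1, 0.2, 0.3):
            fr = tuple(min(1.0, f + bump) for f in base)
            s = SuperfamilyPairStats(
                sf_a="a", sf_b="b", shared_residues=10,
                mapped_domains_a=3, mapped_domains_b=3,
                classifiable_domains_a=3, classifiable_domains_b=3,
                overlap_fracs_a=fr, overlap_fracs_b=sb)
            tiers.append(assign_tier(s, True))
        assert all(t1 <= t2 for t1, t2 in zip(tiers, tiers[1:]))


class TestTsvIO:
    def test_round_trip(self, tmp_path):
        doms = [dom("d1", "sf1", ("s1", "A", 1, 50), ("s1", "A", 60, 80)),
                dom("d2", "sf2", ("s2", "B", 5, 25))]
        p = tmp_path / "cls.tsv"
        write_classification_tsv(doms, p)
        back = read_classification_tsv(p)
        assert back == doms

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("d1\tsf1\ts1\tA\t1\t50\nd2\tsf2\ts1\n")
        with pytest.raises(ValueError, match=r"bad\.tsv:2"):
            read_classification_tsv(p)

    def test_non_integer_bounds_reports_line(self, tmp_path):
        p = tmp_path / "bad2.tsv"
        p.write_text("d1\tsf1\ts1\tA\tx\t50\n")
        with pytest.raises(ValueError, match=r"bad2\.tsv:1"):
            read_classification_tsv(p)

    def test_domain_under_two_superfamilies_rejected(self, tmp_path):
        p = tmp_path / "bad3.tsv"
        p.write_text("d1\tsf1\ts1\tA\t1\t50\nd1\tsf2\ts1\tA\t60\t70\n")
        with pytest.raises(ValueError, match="two superfamilies"):
            read_classification_tsv(p)
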