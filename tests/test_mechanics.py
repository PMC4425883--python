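"""Hybrid construction, gene conversion, hypothetical genomes, enumeration."""

import numpy as np
import pytest

from nahrcall.catalog import build_catalog
from nahrcall.config import CallerConfig
from nahrcall.mechanics import (
    EventAssignment,
    Hypothesis,
    apply_hypothesis,
    enumerate_hypotheses,
    gene_conversion_sequence,
    hybrid_sequence,
    null_hypothesis,
)

from conftest import make_reference, random_snp_pair


@pytest.fixture(scope="module")
def toy():
    # A = AAcAAgAA, B = AAtAAtAA: SNP VPs at alignment columns 2 and 5
    reference, event = make_reference("AACAAGAA", "AATAATAA", z="GGTTGGTTGG")
    return reference, event


class TestHybridSequence:
    def test_identical_repeats_hybrid_equals_either(self):
        _, event = make_reference("ACGTACGTAC", "ACGTACGTAC")
        assert hybrid_sequence(event, "AB", 0) == "ACGTACGTAC"

    def test_toy_hybrid_by_hand(self, toy):
        """A's prefix through the first VP joined to B's suffix."""
        _, event = toy
        assert hybrid_sequence(event, "AB", 0) == "AACAATAA"
        assert hybrid_sequence(event, "BA", 0) == "AATAAGAA"
        assert hybrid_sequence(event, "AB", 1) == "AACAAGAA"

    def test_out_of_range_breakpoint(self, toy):
        _, event = toy
        with pytest.raises(IndexError):
            hybrid_sequence(event, "AB", 5)

    def test_vp_pattern_switch_every_k(self):
        """For every breakpoint index the deletion hybrid carries the first
        repeat's alleles through k and the second's after."""
        rng = np.random.default_rng(21)
        for _ in range(5):
            a, b, pos = random_snp_pair(rng, length=50, n_vps=5)
            _, event = make_reference(a, b)
            for k in range(5):
                hyb = hybrid_sequence(event, "AB", k)
                assert len(hyb) == 50
                for j, p in enumerate(pos):
                    assert hyb[p] == (a[p] if j <= k else b[p])

    def test_complementary_hybrids_cover_all_alleles(self):
        """A->B and B->A hybrids at the same k carry every VP allele of A and
        B exactly once between them."""
        rng = np.random.default_rng(22)
        a, b, pos = random_snp_pair(rng, length=40, n_vps=4)
        _, event = make_reference(a, b)
        for k in range(4):
            ab = hybrid_sequence(event, "AB", k)
            ba = hybrid_sequence(event, "BA", k)
            for p in pos:
                assert {ab[p], ba[p]} == {a[p], b[p]}


class TestGeneConversion:
    def test_minimal_tract(self, toy):
        """Tract (k1, k1+1] converts a single VP."""
        _, event = toy
        # B donates into A, tract covering only VP 1 (column 5)
        assert gene_conversion_sequence(event, "b", 0, 1) == "AACAATAA"
        # A donates into B
        assert gene_conversion_sequence(event, "a", 0, 1) == "AATAAGAA"

    def test_bad_tract_rejected(self, toy):
        _, event = toy
        with pytest.raises(ValueError):
            gene_conversion_sequence(event, "b", 1, 1)

    def test_full_tract_mimics_deletion_hybrid(self):
        """A tract covering every VP except the first reproduces the deletion
        hybrid A->B at k=0: the two are indistinguishable by sequence."""
        rng = np.random.default_rng(4)
        a, b, _ = random_snp_pair(rng, length=40, n_vps=4)
        _, event = make_reference(a, b)
        conv = gene_conversion_sequence(event, "b", 0, 3)
        assert conv == hybrid_sequence(event, "AB", 0)


class TestApplyHypothesis:
    def test_null_hypothesis_is_reference(self, toy):
        reference, event = toy
        cat = build_catalog([event])
        group = cat.groups[0]
        hg = apply_hypothesis(reference, group, null_hypothesis(group), pad=10)
        chrom = group.span()[0]
        expected = reference[chrom][hg.locus_start:hg.locus_end]
        for hap in hg.haplotypes:
            assert hap.sequence == expected
            assert hap.map_to_reference(0) == (chrom, hg.locus_start, "ref")

    def test_deletion_collapses_locus(self, toy):
        reference, event = toy
        cat = build_catalog([event])
        group = cat.groups[0]
        h = Hypothesis((EventAssignment("E1", "deletion", 1, 0),))
        hg = apply_hypothesis(reference, group, h, pad=0)
        removed = len(event.seq_a) + 10  # one repeat-equivalent + intervening
        assert len(hg.haplotypes[0].sequence) == len(hg.haplotypes[1].sequence) - removed
        assert hg.haplotypes[0].sequence == hybrid_sequence(event, "AB", 0)
        # class copies: intact homolog 2 + hybrid 1
        assert hg.class_copies[cat.classes[0].id] == 3

    def test_duplication_adds_tandem_copy(self, toy):
        reference, event = toy
        cat = build_catalog([event])
        group = cat.groups[0]
        h = Hypothesis((EventAssignment("E1", "duplication", 1, 1),))
        hg = apply_hypothesis(reference, group, h, pad=0)
        z = reference[event.chrom][event.lcr_a.end:event.lcr_b.start]
        expected = event.seq_a + z + hybrid_sequence(event, "BA", 1) + z + event.seq_b
        assert hg.haplotypes[0].sequence == expected
        assert hg.class_copies[cat.classes[0].id] == 5

    def test_two_copy_affects_both_homologs(self, toy):
        reference, event = toy
        cat = build_catalog([event])
        group = cat.groups[0]
        h = Hypothesis((EventAssignment("E1", "deletion", 2, 0),))
        hg = apply_hypothesis(reference, group, h, pad=0)
        assert hg.haplotypes[0].sequence == hg.haplotypes[1].sequence
        assert hg.class_copies[cat.classes[0].id] == 2

    def test_length_bookkeeping_random_pairs(self):
        """Deletion shrinks the locus by (inter-repeat distance + one repeat
        length); duplication grows it by the same amount."""
        rng = np.random.default_rng(9)
        for _ in range(4):
            a, b, _ = random_snp_pair(rng, length=30, n_vps=3)
            reference, event = make_reference(a, b)
            cat = build_catalog([event])
            group = cat.groups[0]
            z_len = event.lcr_b.start - event.lcr_a.end
            delta = z_len + 30
            for k in range(3):
                hd = apply_hypothesis(reference, group,
                                      Hypothesis((EventAssignment("E1", "deletion", 1, k),)))
                hu = apply_hypothesis(reference, group,
                                      Hypothesis((EventAssignment("E1", "duplication", 1, k),)))
                ref_len = len(hd.haplotypes[1].sequence)
                assert len(hd.haplotypes[0].sequence) == ref_len - delta
                assert len(hu.haplotypes[0].sequence) == ref_len + delta

    def test_coordinate_map_total_and_unique_sources(self, toy):
        """Every hypothetical base maps to exactly one reference source."""
        reference, event = toy
        cat = build_catalog([event])
        group = cat.groups[0]
        h = Hypothesis((EventAssignment("E1", "deletion", 1, 0),))
        hg = apply_hypothesis(reference, group, h, pad=5)
        hap = hg.haplotypes[0]
        chrom = group.span()[0]
        for pos in range(len(hap.sequence)):
            c, src, _ = hap.map_to_reference(pos)
            assert hap.sequence[pos] == reference[c][src]

    def test_exclusivity_violation_rejected(self):
        from nahrcall.catalog import EventGroup

        rng = np.random.default_rng(2)
        a1, b1, _ = random_snp_pair(rng, length=30, n_vps=2)
        ref1, e1 = make_reference(a1, b1)
        e2 = type(e1)("E2", e1.lcr_a, e1.lcr_b, "positive", 0.95)
        e2.seq_a, e2.seq_b, e2.aln_a, e2.aln_b = e1.seq_a, e1.seq_b, e1.aln_a, e1.aln_b
        e2.vps, e2.allowed_outcomes = e1.vps, e1.allowed_outcomes
        group = EventGroup("G", [e1, e2],
                           exclusivity_pairs=frozenset({frozenset({"E1", "E2"})}))
        h = Hypothesis((EventAssignment("E1", "deletion", 1, 0),
                        EventAssignment("E2", "deletion", 1, 0)))
        with pytest.raises(ValueError, match="exclusive"):
            apply_hypothesis(ref1, group, h)


class TestEnumeration:
    def test_closed_form_count_without_gene_conversion(self):
        """1 event, 3 VPs: 1 + del(2x3) + dup(2x3) = 13 hypotheses."""
        rng = np.random.default_rng(6)
        a, b, _ = random_snp_pair(rng, length=30, n_vps=3)
        _, event = make_reference(a, b)
        cat = build_catalog([event])
        cfg = CallerConfig(gene_conversion=False)
        hyps = enumerate_hypotheses(cat.groups[0], cfg)
        assert len(hyps) == 13

    def test_gene_conversion_adds_two_per_tract(self):
        """max_gc_pairs=1 on a 5-VP event adds one tract per donor direction."""
        rng = np.random.default_rng(6)
        a, b, _ = random_snp_pair(rng, length=40, n_vps=5)
        _, event = make_reference(a, b)
        cat = build_catalog([event])
        base = enumerate_hypotheses(cat.groups[0], CallerConfig(gene_conversion=False))
        with_gc = enumerate_hypotheses(cat.groups[0],
                                       CallerConfig(gene_conversion=True, max_gc_pairs=1))
        assert len(with_gc) == len(base) + 2
        gc = [h for h in with_gc if h.assignments[0].outcome == "gene_conversion"]
        assert {a0.assignments[0].breakpoint for a0 in gc} == {(0, 4)}  # widest tract

    def test_exclusive_pair_never_jointly_non_null(self):
        from nahrcall.catalog import EventGroup

        rng = np.random.default_rng(8)
        a, b, _ = random_snp_pair(rng, length=30, n_vps=2)
        _, e1 = make_reference(a, b)
        e2 = type(e1)("E2", e1.lcr_a, e1.lcr_b, "positive", 0.95)
        e2.seq_a, e2.seq_b, e2.aln_a, e2.aln_b = e1.seq_a, e1.seq_b, e1.aln_a, e1.aln_b
        e2.vps, e2.allowed_outcomes = e1.vps, e1.allowed_outcomes
        group = EventGroup("G", [e1, e2],
                           exclusivity_pairs=frozenset({frozenset({"E1", "E2"})}))
        hyps = enumerate_hypotheses(group, CallerConfig(gene_conversion=False))
        for h in hyps:
            assert h["E1"].is_null or h["E2"].is_null

    def test_oversized_group_rejected(self):
        from nahrcall.catalog import EventGroup

        rng = np.random.default_rng(8)
        a, b, _ = random_snp_pair(rng, length=30, n_vps=2)
        _, e1 = make_reference(a, b)
        group = EventGroup("G", [e1] * 4)
        with pytest.raises(ValueError, match="complexity"):
            enumerate_hypotheses(group, CallerConfig())
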