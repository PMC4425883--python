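"""Repeat catalog: table parsing, VP calling, classes, groups, ranking."""

import numpy as np
import pytest

from nahrcall.catalog import (
    LCRInterval,
    PotentialEvent,
    build_catalog,
    build_homology_classes,
    call_variational_positions,
    classify_outcomes,
    group_events,
    load_segdup_table,
    rank_by_complexity,
)
from nahrcall.config import CallerConfig

from conftest import random_snp_pair


def _write_table(path, rows):
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


class TestLoadSegdupTable:
    def test_case_study_row_lengths(self, tmp_path):
        """1-based inclusive convention: the printed pair yields repeats of
        10,583 and 12,491 bp."""
        p = tmp_path / "t.tsv"
        _write_table(p, [("chr1", 155180173, 155190755, "chr1", 155200767, 155213257,
                          "+", 0.992)])
        events = load_segdup_table(p, reference=None, annotate=False)
        assert len(events) == 1
        assert events[0].lcr_a.length == 10583
        assert events[0].lcr_b.length == 12491

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("")
        assert load_segdup_table(p, None, annotate=False) == []

    def test_low_identity_dropped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "t.tsv"
        _write_table(p, [("chr1", 1000, 3000, "chr1", 10000, 12000, "+", 0.85)])
        with caplog.at_level("WARNING"):
            events = load_segdup_table(p, None, annotate=False)
        assert events == []
        assert "identity" in caplog.text

    def test_short_interval_dropped(self, tmp_path):
        p = tmp_path / "t.tsv"
        _write_table(p, [("chr1", 1000, 1500, "chr1", 10000, 10500, "+", 0.99)])
        assert load_segdup_table(p, None, annotate=False) == []

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "t.tsv"
        _write_table(p, [("chr1", "x", 3000, "chr1", 10000, 12000, "+", 0.95)])
        with pytest.raises(ValueError, match=":1"):
            load_segdup_table(p, None, annotate=False)

    def test_interval_outside_reference(self, tmp_path):
        p = tmp_path / "t.tsv"
        _write_table(p, [("c", 1, 2000, "c", 3001, 5000, "+", 0.95)])
        with pytest.raises(ValueError, match="outside"):
            load_segdup_table(p, {"c": "A" * 3000}, annotate=False)

    def test_locus_span_filter(self, tmp_path):
        p = tmp_path / "t.tsv"
        _write_table(p, [("c", 1, 2000, "c", 300001, 302000, "+", 0.95)])
        cfg = CallerConfig(max_locus_span=250_000)
        assert load_segdup_table(p, None, cfg, annotate=False) == []


class TestVariationalPositions:
    def test_identical_sequences_no_vps(self):
        assert call_variational_positions("ACGTACGT", "ACGTACGT") == []

    def test_single_snp(self):
        vps = call_variational_positions("ACGTACGT", "ACGAACGT")
        assert len(vps) == 1
        assert (vps[0].column, vps[0].allele_a, vps[0].allele_b, vps[0].kind) == \
            (3, "T", "A", "snp")

    def test_single_indel_merged(self):
        vps = call_variational_positions("ACGTTACG", "ACGTACG")
        assert len(vps) == 1
        assert vps[0].kind == "indel"
        assert (vps[0].allele_a, vps[0].allele_b) == ("T", "")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            call_variational_positions("", "ACGT")

    def test_symmetric_up_to_allele_swap(self):
        rng = np.random.default_rng(11)
        a, b, _ = random_snp_pair(rng, length=70, n_vps=5)
        fw = call_variational_positions(a, b)
        bw = call_variational_positions(b, a)
        assert [(v.column, v.allele_a, v.allele_b) for v in fw] == \
            [(v.column, v.allele_b, v.allele_a) for v in bw]

    def test_columns_strictly_increasing(self):
        rng = np.random.default_rng(13)
        a, b, _ = random_snp_pair(rng, length=90, n_vps=6)
        vps = call_variational_positions(a, b)
        cols = [v.column for v in vps]
        assert cols == sorted(cols) and len(set(cols)) == len(cols)


def _iv(chrom, start, end, name):
    return LCRInterval(chrom, start, end, name)


def _event(eid, a, b, orientation="positive"):
    ev = PotentialEvent(eid, a, b, orientation, 0.95)
    ev.allowed_outcomes = classify_outcomes(ev)
    return ev


class TestClassesAndGroups:
    def test_disjoint_pairs_two_classes(self):
        e1 = _event("E1", _iv("c", 0, 100, "A"), _iv("c", 200, 300, "B"))
        e2 = _event("E2", _iv("c", 1000, 1100, "C"), _iv("c", 1200, 1300, "D"))
        classes = build_homology_classes([e1, e2])
        assert sorted(len(c.members) for c in classes) == [2, 2]

    def test_shared_member_single_class(self):
        """(A,B) and (B,C) chain into one class {A,B,C} by transitivity."""
        e1 = _event("E1", _iv("c", 0, 100, "A"), _iv("c", 200, 300, "B"))
        e2 = _event("E2", _iv("c", 200, 300, "B"), _iv("c", 400, 500, "C"))
        classes = build_homology_classes([e1, e2])
        assert len(classes) == 1 and len(classes[0].members) == 3
        assert classes[0].copy_number_null == 3

    def test_classes_partition_members(self):
        """Every repeat interval lands in exactly one class."""
        rng = np.random.default_rng(3)
        events = []
        pos = 0
        for i in range(6):
            a = _iv("c", pos, pos + 100, f"A{i}")
            b = _iv("c", pos + 200, pos + 300, f"B{i}")
            events.append(_event(f"E{i}", a, b))
            pos += 1000
        classes = build_homology_classes(events)
        seen = []
        for c in classes:
            seen.extend((m.chrom, m.start, m.end) for m in c.members)
        assert len(seen) == len(set(seen)) == 12

    def test_homologous_mediators_grouped(self):
        """Two events whose mediating repeats are all homologous are one group."""
        e1 = _event("E1", _iv("c", 0, 100, "A"), _iv("c", 1000, 1100, "B"))
        e2 = _event("E2", _iv("c", 5000, 5100, "C"), _iv("c", 1000, 1100, "B"))
        classes = build_homology_classes([e1, e2])
        groups = group_events([e1, e2], classes)
        assert len(groups) == 1

    def test_unrelated_events_separate_groups(self):
        e1 = _event("E1", _iv("c", 0, 100, "A"), _iv("c", 200, 300, "B"))
        e2 = _event("E2", _iv("c", 5000, 5100, "C"), _iv("c", 5200, 5300, "D"))
        classes = build_homology_classes([e1, e2])
        groups = group_events([e1, e2], classes)
        assert len(groups) == 2
        assert all(not g.exclusivity_pairs for g in groups)

    def test_nested_shared_repeat_is_exclusive(self):
        """Events sharing a mediating repeat cannot both occur."""
        e1 = _event("E1", _iv("c", 0, 100, "A"), _iv("c", 200, 300, "B"))
        e2 = _event("E2", _iv("c", 200, 300, "B"), _iv("c", 400, 500, "C"))
        classes = build_homology_classes([e1, e2])
        groups = group_events([e1, e2], classes)
        assert len(groups) == 1
        assert frozenset({"E1", "E2"}) in groups[0].exclusivity_pairs

    def test_contained_mediator_is_exclusive(self):
        """A deletion spanning another event's repeat forbids that event."""
        e1 = _event("E1", _iv("c", 0, 100, "A"), _iv("c", 900, 1000, "B"))
        e2 = _event("E2", _iv("c", 300, 400, "C"), _iv("c", 500, 600, "D"))
        classes = build_homology_classes([e1, e2])
        groups = group_events([e1, e2], classes)
        assert len(groups) == 1
        assert frozenset({"E1", "E2"}) in groups[0].exclusivity_pairs

    def test_grouping_matches_bruteforce_components(self):
        """Group membership equals connected components of the pairwise
        relation computed by brute force."""
        rng = np.random.default_rng(23)
        events = []
        for i in range(12):
            s = int(rng.integers(0, 20000))
            ln = int(rng.integers(50, 200))
            gap = int(rng.integers(100, 3000))
            events.append(_event(f"E{i}", _iv("c", s, s + ln, f"A{i}"),
                                 _iv("c", s + ln + gap, s + 2 * ln + gap, f"B{i}")))
        classes = build_homology_classes(events)
        groups = group_events(events, classes)
        # brute-force relation: shared class or intersecting spans, closed transitively
        def related(x, y):
            kx = {(m.chrom, m.start, m.end) for c in classes for m in c.members
                  if any(m.overlaps(l) for l in (x.lcr_a, x.lcr_b))}
            ky = {(m.chrom, m.start, m.end) for c in classes for m in c.members
                  if any(m.overlaps(l) for l in (y.lcr_a, y.lcr_b))}
            if kx & ky:
                return True
            sx, sy = x.locus_span(), y.locus_span()
            return sx[0] < sy[1] and sy[0] < sx[1]
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(e.id for e in events)
        for i, x in enumerate(events):
            for y in events[i + 1:]:
                if related(x, y):
                    g.add_edge(x.id, y.id)
        expected = {frozenset(c) for c in nx.connected_components(g)}
        got = {frozenset(e.id for e in grp.events) for grp in groups}
        assert got == expected


class TestOutcomesAndRanking:
    def test_positive_same_chrom(self):
        e = _event("E", _iv("c", 0, 100, "A"), _iv("c", 200, 300, "B"))
        assert {"deletion", "duplication", "gene_conversion"} == set(e.allowed_outcomes)

    def test_negative_orientation_call_disabled(self):
        e = _event("E", _iv("c", 0, 100, "A"), _iv("c", 200, 300, "B"), "negative")
        assert e.allowed_outcomes == frozenset({"inversion", "gene_conversion"})
        assert "call_disabled" in e.flags

    def test_interchromosomal_translocation_out_of_scope(self):
        e = _event("E", _iv("c1", 0, 100, "A"), _iv("c2", 200, 300, "B"))
        assert e.allowed_outcomes == frozenset({"translocation"})
        assert "out_of_scope" in e.flags

    def test_rank_by_complexity(self):
        events = []
        # one chained trio (group of 3) + two singletons
        events.append(_event("E1", _iv("c", 0, 100, "A"), _iv("c", 200, 300, "B")))
        events.append(_event("E2", _iv("c", 200, 300, "B"), _iv("c", 400, 500, "C")))
        events.append(_event("E3", _iv("c", 400, 500, "C"), _iv("c", 600, 700, "D")))
        events.append(_event("E5", _iv("c", 9000, 9100, "G"), _iv("c", 9200, 9300, "H")))
        events.append(_event("E4", _iv("c", 5000, 5100, "E"), _iv("c", 5200, 5300, "F")))
        cat = build_catalog(events)
        top2 = rank_by_complexity(cat.groups, 2)
        assert [e.id for e in top2] == ["E4", "E5"]  # singletons, genome order
        assert rank_by_complexity(cat.groups, 0) == []
        allofthem = rank_by_complexity(cat.groups, 99)
        assert len(allofthem) == 5


def test_catalog_round_trip(tmp_path, toy_catalog):
    """Serializing the catalog and reloading the pair table reproduces
    identical events, VPs, and classes."""
    import pandas as pd

    from nahrcall.io import save_catalog, write_segdup_table

    reference, cat = toy_catalog
    prefix = tmp_path / "cat"
    save_catalog(cat, prefix)
    ev = pd.read_csv(f"{prefix}.events.tsv", sep="\t")
    vp = pd.read_csv(f"{prefix}.vps.tsv", sep="\t")
    assert len(ev) == len(cat.events)
    assert len(vp) == sum(e.n_vps for e in cat.events)
    # round-trip through the pair-table writer/loader
    e = cat.events[0]
    rows = [(e.chrom, e.lcr_a.start, e.lcr_a.end, e.lcr_b.chrom,
             e.lcr_b.start, e.lcr_b.end, "+", e.identity)]
    tbl = tmp_path / "pairs.tsv"
    write_segdup_table(rows, tbl)
    cfg = CallerConfig(min_lcr_length=10)
    reloaded = load_segdup_table(tbl, reference, cfg)
    assert len(reloaded) == 1
    r = reloaded[0]
    assert (r.lcr_a.start, r.lcr_a.end, r.lcr_b.start, r.lcr_b.end) == \
        (e.lcr_a.start, e.lcr_a.end, e.lcr_b.start, e.lcr_b.end)
    assert [(v.column, v.allele_a, v.allele_b) for v in r.vps] == \
        [(v.column, v.allele_a, v.allele_b) for v in e.vps]
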