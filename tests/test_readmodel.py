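"""Read-pair scoring: per-VP simplification, pair likelihood, averaging,
recruitment."""

import math

import numpy as np
import pytest

from nahrcall.readmodel import (
    CandidateLocation,
    ErrorModel,
    FragmentModel,
    ReadPair,
    average_location_likelihood,
    logmeanexp,
    pair_likelihood,
    per_vp_likelihood,
    read_likelihood,
    recruit_reads,
)


class TestPerVPSimplification:
    def test_mediating_repeat_one_agree_one_disagree(self):
        """A hybrid-spanning read against a mediating repeat agrees at one VP
        and disagrees at the other: 0.98 x 0.02."""
        assert per_vp_likelihood([True, False]) == pytest.approx(0.0196, abs=1e-12)

    def test_hybrid_both_agree(self):
        assert per_vp_likelihood([True, True]) == pytest.approx(0.9604, abs=1e-12)

    def test_no_vps_overlapped(self):
        assert per_vp_likelihood([]) == 1.0


class TestModels:
    def test_error_model_validation(self):
        with pytest.raises(ValueError):
            ErrorModel(base_error=1.5)

    def test_quality_floor(self):
        em = ErrorModel(base_error=0.02)
        e = em.per_position_error(3, qualities=[40, 10, 2])
        assert e[0] == pytest.approx(0.02)      # floor dominates Q40
        assert e[1] == pytest.approx(0.1)       # Q10 above the floor
        assert e[2] < 0.5

    def test_fragment_model_validation(self):
        with pytest.raises(ValueError):
            FragmentModel(mean=150.0, sd=10.0, read_length=100)
        with pytest.raises(ValueError):
            FragmentModel(mean=400.0, sd=0.0)

    def test_read_pair_validation(self):
        with pytest.raises(ValueError):
            ReadPair("r", "", "ACGT")
        with pytest.raises(ValueError):
            ReadPair("r", "ACGT", "ACGT", qual1=np.ones(3))


def _perfect_pair(segment, o1, o2, rl=20):
    return ReadPair("p", segment[o1:o1 + rl], segment[o2:o2 + rl])


class TestPairLikelihood:
    segment = "".join(np.random.default_rng(1).choice(list("ACGT"), 700))
    em = ErrorModel(homopolymer_multiplier=1.0)
    fm = FragmentModel(400.0, 40.0, 20)

    def test_modal_fragment_maximal_over_shifts(self):
        """With both mates perfect, the modal insert dominates shifted ones."""
        vals = []
        for o2 in (330, 360, 380, 420):
            loc = CandidateLocation(self.segment, 10, mate2_offset=o2)
            pair = _perfect_pair(self.segment, 10, o2)
            vals.append(pair_likelihood(pair, loc, self.em, self.fm))
        assert np.argmax(vals) == 2  # insert = 390+20 = 410 ~ closest to 400

    def test_location_too_short_for_fragment(self):
        loc = CandidateLocation(self.segment[:50], 10, mate2_offset=380)
        pair = _perfect_pair(self.segment, 10, 380)
        assert pair_likelihood(pair, loc, self.em, self.fm) == -np.inf

    def test_single_candidate_equals_pair_likelihood(self):
        loc = CandidateLocation(self.segment, 10, mate2_offset=380)
        pair = _perfect_pair(self.segment, 10, 380)
        single = pair_likelihood(pair, loc, self.em, self.fm)
        avg = average_location_likelihood(pair, [loc], self.em, self.fm)
        assert avg == pytest.approx(single)

    def test_equal_candidates_average_unchanged(self):
        loc = CandidateLocation(self.segment, 10, mate2_offset=380)
        pair = _perfect_pair(self.segment, 10, 380)
        single = pair_likelihood(pair, loc, self.em, self.fm)
        avg = average_location_likelihood(pair, [loc, loc], self.em, self.fm)
        assert avg == pytest.approx(single)

    def test_empty_candidate_set_rejected(self):
        pair = _perfect_pair(self.segment, 10, 380)
        with pytest.raises(ValueError, match="candidate"):
            average_location_likelihood(pair, [], self.em, self.fm)

    def test_average_bounded_by_extremes(self):
        """The average over locations never exceeds the best location and
        never falls below best/n."""
        pair = _perfect_pair(self.segment, 10, 380)
        locs = [CandidateLocation(self.segment, 10, mate2_offset=380),
                CandidateLocation(self.segment, 40, mate2_offset=410),
                CandidateLocation(self.segment, 100, mate2_offset=470)]
        vals = [pair_likelihood(pair, l, self.em, self.fm) for l in locs]
        avg = average_location_likelihood(pair, locs, self.em, self.fm)
        assert avg <= max(vals) + 1e-12
        assert avg >= max(vals) - math.log(len(locs)) - 1e-12

    def test_figure_style_average_from_per_vp_values(self):
        """Null-genome average over the two mediating repeats stays 0.0196;
        a duplication adds the hybrid: mean over {A, B, hybrid}."""
        null_mean = (0.0196 + 0.0196) / 2
        dup_mean = (0.0196 + 0.0196 + 0.9604) / 3
        got_null = logmeanexp(np.log([0.0196, 0.0196]))
        got_dup = logmeanexp(np.log([0.0196, 0.0196, 0.9604]))
        assert math.exp(got_null) == pytest.approx(null_mean, rel=1e-12)
        assert math.exp(got_dup) == pytest.approx(dup_mean, rel=1e-12)


class TestRecruitment:
    def _make_bam(self, tmp_path, records, ref_len=2000):
        import pysam

        from nahrcall.io import sam_to_indexed_bam

        sam = tmp_path / "t.sam"
        with open(sam, "w") as fh:
            fh.write("@HD\tVN:1.6\n@SQ\tSN:c\tLN:%d\n" % ref_len)
            for r in records:
                fh.write(r + "\n")
        return sam_to_indexed_bam(sam)

    def _group(self):
        from nahrcall.catalog import build_catalog

        from conftest import make_reference, random_snp_pair

        rng = np.random.default_rng(2)
        a, b, _ = random_snp_pair(rng, length=200, n_vps=3)
        reference, event = make_reference(a, b, z="A" * 300, flank="C" * 500, chrom="c")
        return reference, build_catalog([event]).groups[0]

    def test_no_reads_in_region(self, tmp_path):
        _, group = self._group()
        bam = self._make_bam(tmp_path, [])
        assert recruit_reads(bam, group, flank=50) == []

    def test_mapq_zero_recruited_duplicates_excluded(self, tmp_path):
        _, group = self._group()
        seq = "A" * 30
        q = "I" * 30
        rec = [
            f"r1\t99\tc\t600\t0\t30M\t=\t900\t330\t{seq}\t{q}",
            f"r1\t147\tc\t900\t0\t30M\t=\t600\t-330\t{seq}\t{q}",
            f"r2\t1123\tc\t610\t60\t30M\t=\t910\t330\t{seq}\t{q}",   # duplicate flag
            f"r2\t1171\tc\t910\t60\t30M\t=\t610\t-330\t{seq}\t{q}",
        ]
        bam = self._make_bam(tmp_path, rec)
        pairs = recruit_reads(bam, group, flank=100)
        assert [p.name for p in pairs] == ["r1"]
        assert pairs[0].mapq1 == 0  # mapping quality 0 is kept, not discarded

    def test_missing_index_rejected(self, tmp_path):
        import pysam

        _, group = self._group()
        sam = tmp_path / "x.sam"
        sam.write_text("@HD\tVN:1.6\n@SQ\tSN:c\tLN:2000\n")
        with pysam.AlignmentFile(sam) as fh:
            with pytest.raises(ValueError, match="index"):
                recruit_reads(fh, group, flank=10)


class TestCandidateLocations:
    def _setup(self, n_events=1):
        from nahrcall.catalog import build_catalog
        from nahrcall.mechanics import (
            EventAssignment,
            Hypothesis,
            apply_hypothesis,
            null_hypothesis,
        )

        from conftest import make_reference, random_snp_pair

        rng = np.random.default_rng(17)
        a, b, _ = random_snp_pair(rng, length=60, n_vps=3)
        reference, event = make_reference(a, b)
        cat = build_catalog([event])
        return reference, cat, event

    def test_unique_read_single_location_per_haplotype(self):
        from nahrcall.mechanics import apply_hypothesis, null_hypothesis
        from nahrcall.readmodel import candidate_locations

        reference, cat, event = self._setup()
        group = cat.groups[0]
        hg = apply_hypothesis(reference, group, null_hypothesis(group), pad=20)
        # read in the unique flank upstream of the first repeat
        pair = ReadPair("u", "A" * 10, "A" * 10, pos1=hg.locus_start + 2,
                        pos2=hg.locus_start + 30)
        locs = candidate_locations(pair, hg, cat.classes)
        assert len(locs) == 2  # one per homolog
        assert not any(l.is_hybrid for l in locs)

    def test_class_members_all_offered_under_null(self):
        from nahrcall.mechanics import apply_hypothesis, null_hypothesis
        from nahrcall.readmodel import candidate_locations

        reference, cat, event = self._setup()
        group = cat.groups[0]
        hg = apply_hypothesis(reference, group, null_hypothesis(group), pad=20)
        pair = ReadPair("m", "A" * 10, "A" * 10, pos1=event.lcr_a.start + 5,
                        pos2=event.lcr_a.start + 35)
        locs = candidate_locations(pair, hg, cat.classes, cat.events)
        assert len(locs) == 4  # A and B on each homolog

    def test_duplication_adds_hybrid_junction(self):
        from nahrcall.mechanics import EventAssignment, Hypothesis, apply_hypothesis
        from nahrcall.readmodel import candidate_locations

        reference, cat, event = self._setup()
        group = cat.groups[0]
        h = Hypothesis((EventAssignment("E1", "duplication", 1, 1),))
        hg = apply_hypothesis(reference, group, h, pad=20)
        pair = ReadPair("m", "A" * 10, "A" * 10, pos1=event.lcr_a.start + 5,
                        pos2=event.lcr_a.start + 35)
        locs = candidate_locations(pair, hg, cat.classes, cat.events)
        assert sum(l.is_hybrid for l in locs) == 1
        assert len(locs) == 5  # 2xA, 2xB, hybrid
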