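"""Read-pair likelihoods against candidate generating locations.

No read mapping is taken as given: existing alignments serve only to
*recruit* reads to a locus.  Every recruited read is scored against every
location in the hypothetical genome that could have generated it
concordantly — all paralogs of its homology class plus any hybrid junction
segments the hypothesis creates — and the model averages the likelihood
uniformly across those locations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from nahrcall import pairhmm


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

@dataclass
class ErrorModel:
    """Context-sensitive error model of the read aligner.

    The per-base substitution rate is the conservative 2% floor, raised by
    base quality when available, and multiplied (like the gap rates) by the
    homopolymer factor inside segment homopolymer runs; all rates capped
    below 0.5.
    """

    base_error: float = 0.02
    gap_open: float = 0.01
    gap_extend: float = 0.02
    homopolymer_multiplier: float = 5.0
    homopolymer_min_run: int = 4
    use_quality: bool = True

    def __post_init__(self):
        for p in (self.base_error, self.gap_open, self.gap_extend):
            if not 0.0 <= p < 1.0:
                raise ValueError("error-model probabilities must lie in [0, 1)")

    def per_position_error(self, n: int, qualities=None) -> np.ndarray:
        e = np.full(n, self.base_error)
        if qualities is not None and self.use_quality:
            q = np.asarray(qualities, dtype=float)
            e = np.maximum(e, 10.0 ** (-q / 10.0))
        return np.minimum(e, 0.49)

    def segment_multipliers(self, seg_codes: np.ndarray) -> np.ndarray:
        mult = np.ones(len(seg_codes))
        if self.homopolymer_multiplier != 1.0:
            mask = pairhmm.homopolymer_mask(seg_codes, self.homopolymer_min_run)
            mult[mask] = self.homopolymer_multiplier
        return mult

    @classmethod
    def from_config(cls, config) -> "ErrorModel":
        return cls(
            base_error=config.read_error,
            gap_open=config.gap_open,
            gap_extend=config.gap_extend,
            homopolymer_multiplier=config.homopolymer_multiplier,
            homopolymer_min_run=config.homopolymer_min_run,
            use_quality=config.use_quality,
        )


@dataclass
class FragmentModel:
    """Normal fragment-length model used to join mates and set flanks."""

    mean: float = 400.0
    sd: float = 40.0
    read_length: int = 100

    def __post_init__(self):
        if self.mean <= 2 * self.read_length:
            raise ValueError("fragment mean must exceed twice the read length")
        if self.sd <= 0:
            raise ValueError("fragment sd must be positive")

    def log_density(self, insert: float) -> float:
        if insert < self.read_length or insert > self.mean + 8 * self.sd:
            return -np.inf
        return float(norm.logpdf(insert, self.mean, self.sd))

    def flank(self, quantile: float = 0.975) -> int:
        return int(round(norm.ppf(quantile, self.mean, self.sd)))

    @classmethod
    def from_config(cls, config) -> "FragmentModel":
        return cls(config.fragment_mean, config.fragment_sd, config.read_length)


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class ReadPair:
    """A paired-end read with its recruitment coordinates (mapping positions
    are used only to gather and anchor reads, never as evidence).

    Mate sequences are stored reference-stranded (the reverse mate already
    reverse-complemented), so both score directly against forward-strand
    segments; :func:`pair_from_fastq` converts from sequencer orientation.
    """

    name: str
    seq1: str
    seq2: str
    qual1: np.ndarray | None = None
    qual2: np.ndarray | None = None
    chrom: str = ""
    pos1: int = -1  # 0-based leftmost mapped position of each mate
    pos2: int = -1
    reverse1: bool = False
    reverse2: bool = True
    mapq1: int = 0
    mapq2: int = 0
    is_proper: bool = True
    is_duplicate: bool = False

    def __post_init__(self):
        if not self.seq1 or not self.seq2:
            raise ValueError("both mates must be non-empty")
        for s, q in ((self.seq1, self.qual1), (self.seq2, self.qual2)):
            if q is not None and len(q) != len(s):
                raise ValueError("quality length must match sequence length")

    @property
    def leftmost(self) -> int:
        return min(p for p in (self.pos1, self.pos2) if p >= 0)


@dataclass(frozen=True)
class CandidateLocation:
    """One candidate generating location in a hypothetical genome."""

    segment: str          # sequence context containing the fragment window
    offset: int           # anchor offset of mate 1 within the segment
    mate2_offset: int = -1
    strand: str = "+"
    is_hybrid: bool = False
    copies: int = 1       # identical placements across haplotypes
    label: str = ""


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------

def per_vp_likelihood(agreements, error: float = 0.02) -> float:
    """The per-VP simplification of the read likelihood: the product, over
    the variational positions a read overlaps, of (1-e) where the read agrees
    with the target's allele and e where it disagrees.

    With e = 0.02, a hybrid-spanning read that agrees at one VP of a
    mediating repeat and disagrees at the other scores 0.98 x 0.02 = 0.0196,
    and 0.98^2 = 0.9604 against the hybrid where both agree.
    """
    p = 1.0
    for agree in agreements:
        p *= (1.0 - error) if agree else error
    return p


def read_likelihood(read: str, segment: str, error_model: ErrorModel | None = None,
                    qualities=None) -> float:
    """Log forward probability of the read given the segment (pair-HMM),
    summing over all alignments with free segment offset at both ends."""
    if not read:
        raise ValueError("empty read")
    if len(segment) < len(read):
        raise ValueError("segment shorter than read")
    error_model = error_model or ErrorModel()
    r = pairhmm.encode(read)
    s = pairhmm.encode(segment)
    e = error_model.per_position_error(len(read), qualities)
    mult = error_model.segment_multipliers(s)
    return float(pairhmm.forward_log(r, s, e, mult,
                                     error_model.gap_open, error_model.gap_extend, 0.25))


def windowed_likelihood(read: str, context: str, anchor: int, band: int,
                        error_model: ErrorModel, qualities=None) -> float:
    """Banded scoring: run the forward algorithm on the window
    context[anchor-band : anchor+len(read)+band]."""
    lo = max(0, anchor - band)
    hi = min(len(context), anchor + len(read) + band)
    window = context[lo:hi]
    if len(window) < len(read):
        return -np.inf
    return read_likelihood(read, window, error_model, qualities)


def pair_likelihood(read_pair: ReadPair, location: CandidateLocation,
                    error_model: ErrorModel, fragment_model: FragmentModel) -> float:
    """Log joint likelihood of both mates at one candidate location: the
    product of the mates' likelihoods (mate 2 reverse-complemented) and the
    fragment-length density at the implied insert size."""
    seg = location.segment
    rl1, rl2 = len(read_pair.seq1), len(read_pair.seq2)
    o1 = location.offset
    o2 = location.mate2_offset
    if o2 < 0:
        o2 = o1 + int(round(fragment_model.mean)) - rl2
    insert = max(o1 + rl1, o2 + rl2) - min(o1, o2)
    logf = fragment_model.log_density(insert)
    if not np.isfinite(logf):
        return -np.inf
    if min(o1, o2) < 0 or max(o1 + rl1, o2 + rl2) > len(seg):
        return -np.inf
    l1 = read_likelihood(read_pair.seq1, seg[o1:o1 + rl1], error_model, read_pair.qual1)
    l2 = read_likelihood(read_pair.seq2, seg[o2:o2 + rl2], error_model, read_pair.qual2)
    return l1 + l2 + logf


def average_location_likelihood(read_pair: ReadPair, locations,
                                error_model: ErrorModel,
                                fragment_model: FragmentModel) -> float:
    """Log of the arithmetic mean of the pair likelihood over candidate
    locations (uniform location prior, copy-weighted), log-sum-exp stabilized."""
    locations = list(locations)
    if not locations:
        raise ValueError("empty candidate-location set (recruitment failure)")
    logs = []
    weights = []
    for loc in locations:
        logs.append(pair_likelihood(read_pair, loc, error_model, fragment_model))
        weights.append(loc.copies)
    return logmeanexp(np.array(logs), np.array(weights, dtype=float))


def logmeanexp(logs: np.ndarray, weights: np.ndarray | None = None) -> float:
    if weights is None:
        weights = np.ones_like(logs)
    total = weights.sum()
    mx = np.max(logs)
    if not np.isfinite(mx):
        return -np.inf
    return float(mx + np.log(np.sum(weights * np.exp(logs - mx)) / total))


# ---------------------------------------------------------------------------
# recruitment
# ---------------------------------------------------------------------------

def recruit_reads(bam, group, catalog=None, flank: int = 500,
                  max_reads: int | None = None) -> list[ReadPair]:
    """Gather every read pair with a reported mapping (any quality, primary or
    secondary; duplicates excluded) overlapping a class-member interval or the
    inter-repeat region of the group, +/- flank.

    ``bam`` is a pysam.AlignmentFile (coordinate-sorted, indexed) or a path.
    """
    import pysam

    own = False
    if isinstance(bam, (str, bytes)) or hasattr(bam, "__fspath__"):
        bam = pysam.AlignmentFile(str(bam))
        own = True
    try:
        if not bam.has_index():
            raise ValueError("recruitment requires a coordinate-sorted, indexed BAM")
        chrom, start, end = group.span()
        start = max(0, start - flank)
        end = end + flank
        mates: dict[str, dict[int, object]] = {}
        for aln in bam.fetch(chrom, start, end):
            if aln.is_unmapped or aln.is_duplicate or aln.is_supplementary:
                continue
            which = 2 if aln.is_read2 else 1
            slot = mates.setdefault(aln.query_name, {})
            if which not in slot:  # keep the primary-most record per mate
                slot[which] = aln
        pairs = []
        for name, slot in sorted(mates.items()):
            if 1 not in slot or 2 not in slot:
                # mate outside the flanked window: the fragment cannot
                # overlap the variational positions of interest; skip
                continue
            a1, a2 = slot[1], slot[2]
            seq1 = a1.query_sequence  # reference-stranded, as aligned
            seq2 = a2.query_sequence
            if not seq1 or not seq2:
                continue
            q1 = np.array(a1.query_qualities) if a1.query_qualities is not None else None
            q2 = np.array(a2.query_qualities) if a2.query_qualities is not None else None
            pairs.append(ReadPair(
                name=name, seq1=seq1, seq2=seq2, qual1=q1, qual2=q2,
                chrom=chrom, pos1=a1.reference_start, pos2=a2.reference_start,
                reverse1=a1.is_reverse, reverse2=a2.is_reverse,
                mapq1=a1.mapping_quality, mapq2=a2.mapping_quality,
                is_proper=a1.is_proper_pair,
            ))
            if max_reads is not None and len(pairs) >= max_reads:
                break
        return pairs
    finally:
        if own:
            bam.close()


def pair_from_fastq(name: str, seq1: str, seq2: str, **kw) -> ReadPair:
    """Build a ReadPair from sequencer-orientation mates (mate 2 is
    reverse-complemented into reference orientation)."""
    return ReadPair(name=name, seq1=seq1, seq2=revcomp(seq2), **kw)


def candidate_locations(read_pair: ReadPair, hypothesis_genome, classes,
                        events=()) -> list[CandidateLocation]:
    """All locations in a hypothetical genome that could have concordantly
    generated the pair: every copy of its homology class's members plus any
    hybrid junction segment sourcing from them (both haplotypes).

    ``classes``: HomologyClass objects; ``events``: optional PotentialEvents
    used to project offsets between members through their alignment (members
    of equal length project by identical offset otherwise).
    """
    pos = read_pair.leftmost
    rl = len(read_pair.seq1)
    member = cls = None
    for c in classes:
        for m in c.members:
            if pos + rl > m.start and pos < m.end:
                member, cls = m, c
                break
        if member:
            break
    if member is None:
        positions = [pos]
    else:
        positions = {pos}
        offset = pos - member.start
        for e in events:
            for side, lcr, other in (("a", e.lcr_a, e.lcr_b), ("b", e.lcr_b, e.lcr_a)):
                if lcr.overlaps(member):
                    clipped = min(max(offset, 0), lcr.length - 1)
                    proj = e.project_offset(side, clipped) + (offset - clipped)
                    positions.add(other.start + proj)
        if len(positions) == 1 and cls is not None:
            positions.update(m.start + offset for m in cls.members)
        positions = sorted(positions)
    out = []
    seen = set()
    for hi, hap in enumerate(hypothesis_genome.haplotypes):
        for b in hap.blocks:
            for p in positions:
                if b.src_start <= p < b.src_end:
                    q = b.hyp_start + (p - b.src_start)
                    if (hi, q) in seen:
                        continue
                    seen.add((hi, q))
                    out.append(CandidateLocation(
                        segment=hap.sequence, offset=q,
                        is_hybrid=b.label.startswith("hybrid:"), label=b.label))
    return out
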