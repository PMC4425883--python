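"""Repeat catalog: segmental-duplication pairs, variational positions,
homology equivalence classes, and joint event groups.

Every pair of homologous LCRs in the input table is a *potential NAHR event*.
The SNPs and short indels distinguishing the two repeats in their pairwise
alignment are the *variational positions* (VPs); they are the discrete
breakpoint space, because every crossover between two consecutive VPs yields
the same hybrid repeat.  Homologous intervals are merged into equivalence
classes (for repeat read depth), and events that can influence each other —
shared homology or intersecting affected intervals — are grouped so their
hypotheses are enumerated jointly.

Coordinates are 0-based half-open internally; external tables use 1-based
inclusive coordinates, converted only at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
from Bio import Align
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

OUTCOMES = ("deletion", "duplication", "inversion", "translocation", "gene_conversion")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LCRInterval:
    """A low-copy-repeat interval on the reference (0-based half-open)."""

    chrom: str
    start: int
    end: int
    id: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"interval {self.id}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "LCRInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def to_1based(self) -> tuple[str, int, int]:
        """(chrom, start, end) in the 1-based inclusive convention of the tables."""
        return (self.chrom, self.start + 1, self.end)


@dataclass(frozen=True)
class VariationalPosition:
    """A SNP or short indel distinguishing the two repeats of a pair.

    ``column`` / ``column_end`` delimit the (inclusive) alignment columns the
    VP occupies; adjacent gap columns are merged into a single indel VP.
    ``offset_a`` / ``offset_b`` are 0-based offsets of the first differing
    base within each oriented LCR sequence (for a pure insertion on one side,
    the offset of the insertion point).
    """

    column: int
    column_end: int
    offset_a: int
    offset_b: int
    allele_a: str
    allele_b: str
    kind: str  # "snp" | "indel"

    def __post_init__(self):
        if self.allele_a == self.allele_b:
            raise ValueError("VP alleles must differ")
        if self.kind not in ("snp", "indel"):
            raise ValueError(f"unknown VP kind {self.kind!r}")

    def swapped(self) -> "VariationalPosition":
        return replace(
            self,
            offset_a=self.offset_b,
            offset_b=self.offset_a,
            allele_a=self.allele_b,
            allele_b=self.allele_a,
        )


@dataclass
class PotentialEvent:
    """A pair of homologous LCRs that could mediate an NAHR rearrangement.

    ``seq_a``/``seq_b`` are the oriented sequences (``seq_b`` is
    reverse-complemented for negative orientation so alignment columns are
    well defined); ``aln_a``/``aln_b`` the gapped rows of their global
    alignment, and ``vps`` the variational positions in column order.
    """

    id: str
    lcr_a: LCRInterval
    lcr_b: LCRInterval
    orientation: str  # "positive" | "negative"
    identity: float
    seq_a: str = ""
    seq_b: str = ""
    aln_a: str = ""
    aln_b: str = ""
    vps: list[VariationalPosition] = field(default_factory=list)
    allowed_outcomes: frozenset = frozenset()
    flags: tuple = ()

    def __post_init__(self):
        if self.orientation not in ("positive", "negative"):
            raise ValueError(f"bad orientation {self.orientation!r}")

    @property
    def n_vps(self) -> int:
        return len(self.vps)

    @property
    def chrom(self) -> str:
        return self.lcr_a.chrom

    def locus_span(self) -> tuple[int, int]:
        """Reference span of the potential NAHR locus (start of A to end of B)."""
        return (self.lcr_a.start, self.lcr_b.end)

    def inter_lcr(self) -> tuple[int, int]:
        """The unique interval between the two repeats."""
        return (self.lcr_a.end, self.lcr_b.start)

    # offset <-> alignment-column maps, built lazily from the gapped rows
    def _col_maps(self):
        if not hasattr(self, "_cmaps"):
            col_a, col_b = [], []
            off_a, off_b = [], []
            ia = ib = 0
            for c, (ca, cb) in enumerate(zip(self.aln_a, self.aln_b)):
                if ca != "-":
                    col_a.append(c)
                    ia += 1
                if cb != "-":
                    col_b.append(c)
                    ib += 1
                off_a.append(ia)  # A bases consumed through column c
                off_b.append(ib)
            self._cmaps = (col_a, col_b, off_a, off_b)
        return self._cmaps

    def column_of_offset(self, side: str, offset: int) -> int:
        col_a, col_b, _, _ = self._col_maps()
        cols = col_a if side == "a" else col_b
        return cols[min(offset, len(cols) - 1)]

    def offset_of_column(self, side: str, column: int) -> int:
        """Number of bases of ``side`` consumed through ``column`` (inclusive)."""
        _, _, off_a, off_b = self._col_maps()
        offs = off_a if side == "a" else off_b
        return offs[min(column, len(offs) - 1)]

    def project_offset(self, from_side: str, offset: int) -> int:
        """Map an offset in one repeat to the homologous offset in the other."""
        to_side = "b" if from_side == "a" else "a"
        col = self.column_of_offset(from_side, offset)
        off = self.offset_of_column(to_side, col)
        return max(0, off - 1)

    def vp_ref_positions(self, k: int) -> tuple[int, int]:
        """Reference coordinates (0-based) of VP ``k`` on each LCR.

        For negative orientation the B offset is in the oriented frame and is
        mapped back through the reverse complement.
        """
        vp = self.vps[k]
        pos_a = self.lcr_a.start + vp.offset_a
        if self.orientation == "positive":
            pos_b = self.lcr_b.start + vp.offset_b
        else:
            pos_b = self.lcr_b.end - 1 - vp.offset_b
        return pos_a, pos_b


@dataclass
class HomologyClass:
    """An equivalence class of mutually homologous intervals (transitive closure)."""

    id: str
    members: tuple[LCRInterval, ...]
    copy_number_null: int = 0

    def __post_init__(self):
        if not self.copy_number_null:
            self.copy_number_null = len(self.members)


@dataclass
class EventGroup:
    """Events whose hypotheses must be enumerated jointly."""

    id: str
    events: list[PotentialEvent]
    exclusivity_pairs: frozenset = frozenset()  # frozenset of frozenset({id1, id2})
    classes: tuple[HomologyClass, ...] = ()

    @property
    def size(self) -> int:
        return len(self.events)

    def span(self) -> tuple[str, int, int]:
        chroms = {e.chrom for e in self.events} | {e.lcr_b.chrom for e in self.events}
        if len(chroms) > 1:
            raise ValueError(f"group {self.id} spans chromosomes {sorted(chroms)}")
        start = min(e.lcr_a.start for e in self.events)
        end = max(e.lcr_b.end for e in self.events)
        return (next(iter(chroms)), start, end)


@dataclass
class RepeatCatalog:
    events: list[PotentialEvent]
    classes: list[HomologyClass]
    groups: list[EventGroup]

    def event(self, event_id: str) -> PotentialEvent:
        for e in self.events:
            if e.id == event_id:
                return e
        raise KeyError(event_id)

    def class_of(self, lcr: LCRInterval) -> HomologyClass:
        for c in self.classes:
            if any(m.overlaps(lcr) or m == lcr for m in c.members):
                return c
        raise KeyError(f"no class contains {lcr}")


# ---------------------------------------------------------------------------
# sequence access helper
# ---------------------------------------------------------------------------

def fetch_sequence(reference, chrom: str, start: int, end: int) -> str:
    """Extract reference sequence; accepts a dict of strings, a pyfaidx.Fasta,
    or any object with a ``fetch(chrom, start, end)`` method (pysam)."""
    start = max(0, start)
    if end <= start:
        return ""
    if isinstance(reference, dict):
        seq = reference[chrom][start:end]
    elif hasattr(reference, "fetch"):
        seq = reference.fetch(chrom, start, end)
    else:  # pyfaidx-style
        seq = str(reference[chrom][start:end])
    return str(seq).upper()


def reference_length(reference, chrom: str) -> int:
    if isinstance(reference, dict):
        return len(reference[chrom])
    if hasattr(reference, "get_reference_length"):
        return reference.get_reference_length(chrom)
    return len(reference[chrom])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def classify_outcomes(event: PotentialEvent) -> frozenset:
    """Rules of NAHR: positively oriented intra-chromosomal pairs can delete or
    duplicate (and gene-convert); negatively oriented pairs invert
    (call-disabled); inter-chromosomal pairs translocate (out of scope)."""
    same_chrom = event.lcr_a.chrom == event.lcr_b.chrom
    if not same_chrom:
        event.flags = tuple(set(event.flags) | {"out_of_scope"})
        return frozenset({"translocation"})
    if event.orientation == "positive":
        return frozenset({"deletion", "duplication", "gene_conversion"})
    event.flags = tuple(set(event.flags) | {"call_disabled"})
    return frozenset({"inversion", "gene_conversion"})


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


def align_pair(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Deterministic global alignment (affine gaps) of the two repeats."""
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    aln = _make_aligner().align(seq_a, seq_b)[0]
    return str(aln[0]), str(aln[1])


def vps_from_alignment(aln_a: str, aln_b: str) -> list[VariationalPosition]:
    """Extract VPs from the gapped alignment rows: mismatch columns become SNP
    VPs; maximal runs of gap-bearing columns merge into single indel VPs."""
    vps: list[VariationalPosition] = []
    n = len(aln_a)
    ia = ib = 0  # bases consumed before current column
    c = 0
    while c < n:
        ca, cb = aln_a[c], aln_b[c]
        if ca == "-" or cb == "-":
            c0, a0, b0 = c, ia, ib
            al, bl = [], []
            while c < n and (aln_a[c] == "-" or aln_b[c] == "-"):
                if aln_a[c] != "-":
                    al.append(aln_a[c])
                    ia += 1
                if aln_b[c] != "-":
                    bl.append(aln_b[c])
                    ib += 1
                c += 1
            vps.append(
                VariationalPosition(
                    column=c0, column_end=c - 1, offset_a=a0, offset_b=b0,
                    allele_a="".join(al), allele_b="".join(bl), kind="indel",
                )
            )
            continue
        if ca != cb:
            vps.append(
                VariationalPosition(
                    column=c, column_end=c, offset_a=ia, offset_b=ib,
                    allele_a=ca, allele_b=cb, kind="snp",
                )
            )
        ia += 1
        ib += 1
        c += 1
    return vps


def call_variational_positions(seq_a: str, seq_b: str) -> list[VariationalPosition]:
    """VPs of a repeat pair: the mismatch and (merged) gap columns of their
    global pairwise alignment.  Identical sequences have no VPs."""
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    if seq_a == seq_b:
        return []
    return vps_from_alignment(*align_pair(seq_a, seq_b))


def annotate_event(event: PotentialEvent, reference) -> PotentialEvent:
    """Attach oriented sequences, alignment, and VPs to an event."""
    event.seq_a = fetch_sequence(reference, event.lcr_a.chrom, event.lcr_a.start, event.lcr_a.end)
    seq_b = fetch_sequence(reference, event.lcr_b.chrom, event.lcr_b.start, event.lcr_b.end)
    if event.orientation == "negative":
        seq_b = str(Seq(seq_b).reverse_complement())
    event.seq_b = seq_b
    if event.seq_a == event.seq_b:
        event.aln_a, event.aln_b = event.seq_a, event.seq_b
        event.vps = []
    else:
        event.aln_a, event.aln_b = align_pair(event.seq_a, event.seq_b)
        event.vps = vps_from_alignment(event.aln_a, event.aln_b)
    event.allowed_outcomes = classify_outcomes(event)
    return event


def load_segdup_table(path, reference, config=None, annotate: bool = True) -> list[PotentialEvent]:
    """Parse an HSDD-style tab-separated pair table into potential events.

    Columns per row: chromA, startA, endA, chromB, startB, endB,
    strand (+/-), identity.  Coordinates are 1-based inclusive.  Rows below
    90% identity or with an interval under 1 kb are dropped with a warning.
    """
    from nahrcall.config import CallerConfig

    config = config or CallerConfig()
    events: list[PotentialEvent] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise ValueError(f"{path}:{lineno}: expected >=8 tab-separated fields, got {len(parts)}")
            try:
                chrom_a, start_a, end_a = parts[0], int(parts[1]), int(parts[2])
                chrom_b, start_b, end_b = parts[3], int(parts[4]), int(parts[5])
                strand, identity = parts[6], float(parts[7])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from None
            a = LCRInterval(chrom_a, start_a - 1, end_a, id=f"E{lineno}.A")
            b = LCRInterval(chrom_b, start_b - 1, end_b, id=f"E{lineno}.B")
            # canonical order: lcr_a precedes lcr_b in genome order
            if (b.chrom, b.start) < (a.chrom, a.start):
                a, b = (
                    LCRInterval(b.chrom, b.start, b.end, id=a.id),
                    LCRInterval(a.chrom, a.start, a.end, id=b.id),
                )
            for iv in (a, b):
                if reference is not None:
                    if iv.end > reference_length(reference, iv.chrom):
                        raise ValueError(f"{path}:{lineno}: interval {iv} outside reference")
            if identity < config.min_identity:
                logger.warning("%s:%d: dropped pair with identity %.3f < %.2f",
                               path, lineno, identity, config.min_identity)
                continue
            if a.length < config.min_lcr_length or b.length < config.min_lcr_length:
                logger.warning("%s:%d: dropped pair with interval < %d bp",
                               path, lineno, config.min_lcr_length)
                continue
            if a.chrom == b.chrom and b.end - a.start > config.max_locus_span:
                logger.warning("%s:%d: dropped pair spanning %d bp > %d",
                               path, lineno, b.end - a.start, config.max_locus_span)
                continue
            event = PotentialEvent(
                id=f"E{lineno}",
                lcr_a=a,
                lcr_b=b,
                orientation="positive" if strand == "+" else "negative",
                identity=identity,
            )
            if annotate and reference is not None:
                annotate_event(event, reference)
            else:
                event.allowed_outcomes = classify_outcomes(event)
            events.append(event)
    return events


def build_homology_classes(events: list[PotentialEvent]) -> list[HomologyClass]:
    """Connected components of the homology graph: the two repeats of every
    pair are homologous, and overlapping intervals are the same repeat copy."""
    g = nx.Graph()
    lcrs: list[LCRInterval] = []
    for e in events:
        lcrs.extend((e.lcr_a, e.lcr_b))
        g.add_edge(_key(e.lcr_a), _key(e.lcr_b))
    # merge positionally overlapping intervals (same copy seen by two rows)
    by_chrom: dict[str, list[LCRInterval]] = {}
    for iv in lcrs:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for ivs in by_chrom.values():
        ivs.sort(key=lambda x: x.start)
        for i in range(len(ivs) - 1):
            if ivs[i + 1].start < ivs[i].end:
                g.add_edge(_key(ivs[i]), _key(ivs[i + 1]))
    key_to_iv = {_key(iv): iv for iv in lcrs}
    classes = []
    for i, comp in enumerate(sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])):
        members = tuple(sorted((key_to_iv[k] for k in comp), key=lambda x: (x.chrom, x.start)))
        classes.append(HomologyClass(id=f"H{i + 1}", members=members))
    return classes


def _key(iv: LCRInterval) -> tuple:
    return (iv.chrom, iv.start, iv.end)


def _class_index(classes: list[HomologyClass]) -> dict[tuple, str]:
    idx = {}
    for c in classes:
        for m in c.members:
            idx[_key(m)] = c.id
    return idx


def group_events(events: list[PotentialEvent], classes: list[HomologyClass]) -> list[EventGroup]:
    """Group events that must be considered simultaneously: sharing a homology
    class, or intersecting potentially affected intervals (LCRs plus the
    intervening sequence).  Within each group, mark as exclusive every pair
    where one event's deletion would remove the other's mediating repeat."""
    idx = _class_index(classes)
    g = nx.Graph()
    g.add_nodes_from(e.id for e in events)
    for i, e1 in enumerate(events):
        for e2 in events[i + 1:]:
            share_class = {idx[_key(e1.lcr_a)], idx[_key(e1.lcr_b)]} & {
                idx[_key(e2.lcr_a)], idx[_key(e2.lcr_b)]}
            s1, s2 = e1.locus_span(), e2.locus_span()
            same_chrom = e1.chrom == e2.chrom and e1.lcr_b.chrom == e2.lcr_b.chrom
            span_intersect = same_chrom and s1[0] < s2[1] and s2[0] < s1[1]
            if share_class or span_intersect:
                g.add_edge(e1.id, e2.id)
    by_id = {e.id: e for e in events}
    groups = []
    comps = sorted(nx.connected_components(g),
                   key=lambda c: min((by_id[i].chrom, by_id[i].lcr_a.start) for i in c))
    for gi, comp in enumerate(comps):
        evs = sorted((by_id[i] for i in comp), key=lambda e: (e.chrom, e.lcr_a.start))
        excl = set()
        for i, e1 in enumerate(evs):
            for e2 in evs[i + 1:]:
                if _deletion_removes_mediator(e1, e2) or _deletion_removes_mediator(e2, e1):
                    excl.add(frozenset({e1.id, e2.id}))
        touched = sorted({idx[_key(e.lcr_a)] for e in evs} | {idx[_key(e.lcr_b)] for e in evs})
        cls = tuple(c for c in classes if c.id in touched)
        groups.append(EventGroup(id=f"G{gi + 1}", events=evs,
                                 exclusivity_pairs=frozenset(excl), classes=cls))
    return groups


def _deletion_removes_mediator(e1: PotentialEvent, e2: PotentialEvent) -> bool:
    """Would a deletion at e1 remove a mediating LCR of e2?

    Only deletions can remove a repeat (duplications preserve both), so the
    exclusivity test considers deletion outcomes only.  A mediator is removed
    if it is shared with e1 (hybridized away) or lies inside e1's locus span.
    """
    if "deletion" not in e1.allowed_outcomes:
        return False
    if e1.chrom != e1.lcr_b.chrom:
        return False
    s, t = e1.locus_span()
    for m in (e2.lcr_a, e2.lcr_b):
        if m.overlaps(e1.lcr_a) or m.overlaps(e1.lcr_b):
            return True
        if m.chrom == e1.chrom and m.start >= s and m.end <= t:
            return True
    return False


def rank_by_complexity(groups: list[EventGroup], n: int) -> list[PotentialEvent]:
    """The n events of smallest computational complexity: ascending group size,
    ties broken by genomic coordinate of the first repeat."""
    flat = []
    for grp in groups:
        for e in grp.events:
            flat.append((grp.size, e.chrom, e.lcr_a.start, e))
    flat.sort(key=lambda t: t[:3])
    if n > len(flat):
        logger.warning("requested %d events but only %d available", n, len(flat))
        n = len(flat)
    return [t[3] for t in flat[:n]]


def build_catalog(events: list[PotentialEvent]) -> RepeatCatalog:
    classes = build_homology_classes(events)
    groups = group_events(events, classes)
    return RepeatCatalog(events=events, classes=classes, groups=groups)
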