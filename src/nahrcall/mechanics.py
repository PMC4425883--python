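"""Rules of NAHR: hybrid repeats and fully specified hypothetical genomes.

A crossover between paralogs A and B anywhere in the interval (v_k, v_{k+1}]
of consecutive variational positions yields one and the same hybrid repeat:
A's alleles at VPs up to index k, B's after (pattern A→B; B→A symmetric).
A deletion collapses the locus A…Z…B to the single hybrid A→B, removing the
intervening sequence Z; a duplication preserves A and B and inserts a tandem
copy, A…Z…(B→A)…Z…B.  Gene conversion replaces a VP tract of the recipient
with the donor's alleles without changing copy number — sequence-wise, a
tract covering every VP is indistinguishable from the deletion hybrid, which
is why gene conversion must compete as a hypothesis.

Multiplicity is interpreted on a diploid: m=1 rearranges one homolog, m=2
both (with a shared breakpoint).  Duplicated copies are modeled as tandem.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from nahrcall.catalog import (
    EventGroup,
    HomologyClass,
    PotentialEvent,
    fetch_sequence,
)

CALLABLE_OUTCOMES = ("deletion", "duplication")


# ---------------------------------------------------------------------------
# hypotheses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EventAssignment:
    """One event's slot in a joint hypothesis."""

    event_id: str
    outcome: str = "none"  # none | deletion | duplication | gene_conversion
    multiplicity: int = 0  # 0 iff none; 1 = one homolog, 2 = both
    breakpoint: int | tuple[int, int] | None = None  # VP index k, or (k1, k2) tract
    donor: str | None = None  # gene conversion only: "a" or "b" donates

    def __post_init__(self):
        if (self.outcome == "none") != (self.multiplicity == 0):
            raise ValueError("multiplicity must be 0 iff outcome is none")
        if self.outcome == "gene_conversion":
            k1, k2 = self.breakpoint
            if k1 >= k2:
                raise ValueError("gene conversion tract requires k1 < k2")
            if self.donor not in ("a", "b"):
                raise ValueError("gene conversion needs a donor side")

    @property
    def is_null(self) -> bool:
        return self.outcome == "none"


@dataclass(frozen=True)
class Hypothesis:
    """A joint assignment of (outcome, multiplicity, breakpoint) per event."""

    assignments: tuple[EventAssignment, ...]

    def __getitem__(self, event_id: str) -> EventAssignment:
        for a in self.assignments:
            if a.event_id == event_id:
                return a
        raise KeyError(event_id)

    @property
    def is_null(self) -> bool:
        return all(a.is_null for a in self.assignments)

    def non_null(self) -> list[EventAssignment]:
        return [a for a in self.assignments if not a.is_null]


def null_hypothesis(group: EventGroup) -> Hypothesis:
    return Hypothesis(tuple(EventAssignment(e.id) for e in group.events))


# ---------------------------------------------------------------------------
# hybrid sequences
# ---------------------------------------------------------------------------

def _split_offsets(event: PotentialEvent, k: int) -> tuple[int, int]:
    """Ungapped lengths of each repeat consumed through VP k's last column."""
    if not 0 <= k < event.n_vps:
        raise IndexError(f"breakpoint index {k} out of range for {event.n_vps} VPs")
    col_end = event.vps[k].column_end
    return (event.offset_of_column("a", col_end), event.offset_of_column("b", col_end))


def hybrid_sequence(event: PotentialEvent, pattern: str, k: int) -> str:
    """The hybrid repeat for a crossover in (v_k, v_{k+1}].

    ``pattern`` "AB" (A→B: A's prefix through VP k, B's suffix after) or
    "BA".  The result carries allele_a at VPs ≤ k and allele_b above (for
    A→B; mirrored for B→A).  With no VPs the repeats are identical and the
    hybrid equals either.
    """
    if event.n_vps == 0:
        if pattern not in ("AB", "BA"):
            raise ValueError(f"bad pattern {pattern!r}")
        return event.seq_a
    cut_a, cut_b = _split_offsets(event, k)
    if pattern == "AB":
        return event.seq_a[:cut_a] + event.seq_b[cut_b:]
    if pattern == "BA":
        return event.seq_b[:cut_b] + event.seq_a[cut_a:]
    raise ValueError(f"bad pattern {pattern!r}")


def gene_conversion_sequence(event: PotentialEvent, donor: str, k1: int, k2: int) -> str:
    """Recipient repeat with the VP alleles in (k1, k2] replaced by the
    donor's (pattern A→B→A when B donates into A)."""
    if k1 >= k2:
        raise ValueError("gene conversion tract requires k1 < k2")
    if donor not in ("a", "b"):
        raise ValueError("donor must be 'a' or 'b'")
    recipient, other = ("b", "a") if donor == "a" else ("a", "b")
    aln_r = event.aln_a if recipient == "a" else event.aln_b
    aln_d = event.aln_b if recipient == "a" else event.aln_a
    out = []
    tract_cols = set()
    for k in range(k1 + 1, k2 + 1):
        vp = event.vps[k]
        tract_cols.update(range(vp.column, vp.column_end + 1))
    for c, (cr, cd) in enumerate(zip(aln_r, aln_d)):
        ch = cd if c in tract_cols else cr
        if ch != "-":
            out.append(ch)
    return "".join(out)


# ---------------------------------------------------------------------------
# hypothetical genomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Block:
    """A run of hypothetical sequence with a single reference source."""

    hyp_start: int
    hyp_end: int
    chrom: str
    src_start: int
    src_end: int
    label: str = "ref"  # "ref" or "hybrid:<event>:<pattern>:<k>" etc.

    @property
    def length(self) -> int:
        return self.hyp_end - self.hyp_start


@dataclass
class Haplotype:
    sequence: str
    blocks: list[Block]

    def map_to_reference(self, pos: int) -> tuple[str, int, str]:
        """Reference source of a hypothetical position (total over the locus)."""
        for b in self.blocks:
            if b.hyp_start <= pos < b.hyp_end:
                return (b.chrom, b.src_start + (pos - b.hyp_start), b.label)
        raise IndexError(pos)


@dataclass
class HypotheticalGenome:
    """The rearranged locus of a group under one joint hypothesis, restricted
    to [locus_start, locus_end) on the group's chromosome, as a diploid pair
    of haplotypes with total coordinate maps back to the reference."""

    chrom: str
    locus_start: int
    locus_end: int
    haplotypes: list[Haplotype]
    class_copies: dict[str, int]  # homologous-segment copies over both haplotypes
    hypothesis: Hypothesis | None = None


def _apply_to_sequence(reference, chrom: str, locus_start: int, locus_end: int,
                       assignments: list[tuple[PotentialEvent, EventAssignment]]) -> Haplotype:
    """Apply non-overlapping assignments left-to-right across the locus."""
    assignments = sorted(assignments, key=lambda t: t[0].lcr_a.start)
    for (e1, _), (e2, _) in itertools.pairwise(assignments):
        if e2.lcr_a.start < e1.lcr_b.end:
            raise ValueError(
                f"cannot apply overlapping non-null events {e1.id} and {e2.id} jointly")
    seq_parts: list[str] = []
    blocks: list[Block] = []
    cursor = locus_start  # reference cursor
    hyp = 0

    def emit(seq: str, src_start: int, src_end: int, label: str = "ref"):
        nonlocal hyp
        if not seq:
            return
        blocks.append(Block(hyp, hyp + len(seq), chrom, src_start, src_end, label))
        seq_parts.append(seq)
        hyp += len(seq)

    for event, a in assignments:
        s, t = event.locus_span()
        emit(fetch_sequence(reference, chrom, cursor, s), cursor, s)
        lena, lenb = event.lcr_a.length, event.lcr_b.length
        z_start, z_end = event.inter_lcr()
        z_seq = fetch_sequence(reference, chrom, z_start, z_end)
        if a.outcome == "deletion":
            k = a.breakpoint
            cut_a, cut_b = _split_offsets(event, k) if event.n_vps else (lena, 0)
            hseq = hybrid_sequence(event, "AB", k) if event.n_vps else event.seq_a
            label = f"hybrid:{event.id}:AB:{k}"
            emit(hseq[:cut_a], event.lcr_a.start, event.lcr_a.start + cut_a, label)
            emit(hseq[cut_a:], event.lcr_b.start + cut_b, event.lcr_b.end, label)
        elif a.outcome == "duplication":
            k = a.breakpoint
            cut_a, cut_b = _split_offsets(event, k) if event.n_vps else (0, lenb)
            hseq = hybrid_sequence(event, "BA", k) if event.n_vps else event.seq_a
            label = f"hybrid:{event.id}:BA:{k}"
            emit(event.seq_a, event.lcr_a.start, event.lcr_a.end)
            emit(z_seq, z_start, z_end)
            emit(hseq[:cut_b], event.lcr_b.start, event.lcr_b.start + cut_b, label)
            emit(hseq[cut_b:], event.lcr_a.start + cut_a, event.lcr_a.end, label)
            emit(z_seq, z_start, z_end, "dup_copy")
            emit(event.seq_b, event.lcr_b.start, event.lcr_b.end)
        elif a.outcome == "gene_conversion":
            k1, k2 = a.breakpoint
            conv = gene_conversion_sequence(event, a.donor, k1, k2)
            label = f"gc:{event.id}:{a.donor}:{k1}-{k2}"
            if a.donor == "b":  # A is the recipient
                emit(conv, event.lcr_a.start, event.lcr_a.end, label)
                emit(z_seq, z_start, z_end)
                emit(event.seq_b, event.lcr_b.start, event.lcr_b.end)
            else:
                emit(event.seq_a, event.lcr_a.start, event.lcr_a.end)
                emit(z_seq, z_start, z_end)
                emit(conv, event.lcr_b.start, event.lcr_b.end, label)
        else:
            raise ValueError(f"cannot apply outcome {a.outcome!r}")
        cursor = t
    emit(fetch_sequence(reference, chrom, cursor, locus_end), cursor, locus_end)
    return Haplotype("".join(seq_parts), blocks)


def apply_hypothesis(reference, group: EventGroup, hypothesis: Hypothesis,
                     pad: int = 0, locus: tuple[int, int] | None = None) -> HypotheticalGenome:
    """Build the diploid hypothetical genome for a joint hypothesis.

    The all-none hypothesis reproduces the reference locus with an identity
    coordinate map.  Exclusivity violations are rejected.  ``locus``
    overrides the padded group span (e.g. a whole chromosome).
    """
    for pair in group.exclusivity_pairs:
        i1, i2 = tuple(pair)
        if not hypothesis[i1].is_null and not hypothesis[i2].is_null:
            raise ValueError(f"exclusive events {i1} and {i2} both non-null")
    chrom, start, end = group.span()
    if locus is not None:
        start, end = locus
    else:
        start = max(0, start - pad)
        end = end + pad
    by_id = {e.id: e for e in group.events}
    hap_assignments: list[list] = [[], []]
    for a in hypothesis.non_null():
        ev = by_id[a.event_id]
        hap_assignments[0].append((ev, a))
        if a.multiplicity == 2:
            hap_assignments[1].append((ev, a))
    haplotypes = [
        _apply_to_sequence(reference, chrom, start, end, hap_assignments[0]),
        _apply_to_sequence(reference, chrom, start, end, hap_assignments[1]),
    ]
    class_copies = _count_class_copies(group, haplotypes)
    return HypotheticalGenome(chrom, start, end, haplotypes, class_copies, hypothesis)


def _count_class_copies(group: EventGroup, haplotypes: list[Haplotype]) -> dict[str, int]:
    """Count homologous-segment copies per class across both haplotypes.

    A hybrid counts as one copy of its class; each intact member counts one.
    Counting walks the coordinate map: a maximal run of blocks sourcing from
    class members (one hybrid's two pieces form one run) is one copy.
    """
    copies: dict[str, int] = {}
    for c in group.classes:
        frac = 0.0
        for hap in haplotypes:
            for b in hap.blocks:
                for m in c.members:
                    if b.chrom != m.chrom:
                        continue
                    lo = max(b.src_start, m.start)
                    hi = min(b.src_end, m.end)
                    if hi > lo:
                        frac += (hi - lo) / m.length
        copies[c.id] = int(round(frac))
    return copies


# ---------------------------------------------------------------------------
# hypothesis enumeration
# ---------------------------------------------------------------------------

def _event_assignments(event: PotentialEvent, config) -> list[EventAssignment]:
    out = [EventAssignment(event.id)]
    nv = event.n_vps
    if nv == 0:
        return out
    for outcome in CALLABLE_OUTCOMES:
        if outcome not in event.allowed_outcomes:
            continue
        for m in (1, 2):
            for k in range(nv):
                out.append(EventAssignment(event.id, outcome, m, k))
    if config.gene_conversion and "gene_conversion" in event.allowed_outcomes and nv >= 2:
        pairs = sorted(
            itertools.combinations(range(nv), 2),
            key=lambda p: (-(p[1] - p[0]), p),
        )[: config.max_gc_pairs]
        for k1, k2 in pairs:
            for donor in ("a", "b"):
                out.append(EventAssignment(event.id, "gene_conversion", 1, (k1, k2), donor))
    return out


def enumerate_hypotheses(group: EventGroup, config) -> list[Hypothesis]:
    """Deterministic bounded enumeration of the joint hypothesis space:
    Cartesian product of per-event assignment spaces pruned by exclusivity."""
    if group.size > config.max_joint_events:
        raise ValueError(
            f"group {group.id} has {group.size} events > max_joint_events="
            f"{config.max_joint_events}; re-rank loci by complexity and restrict"
        )
    spaces = [_event_assignments(e, config) for e in group.events]
    excl = group.exclusivity_pairs
    hyps = []
    for combo in itertools.product(*spaces):
        ok = True
        for pair in excl:
            i1, i2 = tuple(pair)
            a1 = next(a for a in combo if a.event_id == i1)
            a2 = next(a for a in combo if a.event_id == i2)
            if not a1.is_null and not a2.is_null:
                ok = False
                break
        if ok:
            hyps.append(Hypothesis(tuple(combo)))
    return hyps
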