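"""End-to-end calling: recruit reads per event group, enumerate joint
hypotheses, score each fully specified hypothetical genome (read alignments
+ repeat read depth + priors), normalize posteriors, and emit filtered calls
with gamma / local fdr / breakpoint log-odds / support counts.

Two algebraic properties keep the exact model tractable at scale:

* a read pair in which neither mate overlaps a variational position scores
  the same at every candidate location under every hypothesis (its window
  sequence is identical in all paralogs and hybrids), so its factor cancels
  in the posterior and only VP-overlapping pairs are scored — copy-number
  evidence from all fragments is carried by the depth term;
* read depth is pooled over whole homology classes (repeat read depth), so
  no within-class mapping assignment is ever needed or used.

Single-event groups whose repeats differ only by SNP variational positions
take a vectorized path that shares pair-HMM window scores across the
breakpoint dimension; general groups (indel VPs, joint events) take the
block-map path.  Both compute the same model.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pysam

from nahrcall.catalog import EventGroup, PotentialEvent, RepeatCatalog, fetch_sequence
from nahrcall.config import CallerConfig
from nahrcall.depth import GCCurve, count_fragment_starts, gamma_statistic
from nahrcall.inference import (
    EventCall,
    PosteriorTable,
    Priors,
    call_group,
    joint_log_prob,
)
from nahrcall.mechanics import (
    EventAssignment,
    Hypothesis,
    HypotheticalGenome,
    apply_hypothesis,
    enumerate_hypotheses,
    hybrid_sequence,
)
from nahrcall.readmodel import (
    ErrorModel,
    FragmentModel,
    ReadPair,
    logmeanexp,
    read_likelihood,
    recruit_reads,
)
from nahrcall.stats import breakpoint_log_odds as _bp_log_odds_from_logs
from nahrcall.stats import local_fdr

logger = logging.getLogger(__name__)

_FLOOR = -700.0  # log-likelihood floor for a read with no candidate location


@dataclass
class Placement:
    haplotype: int
    q1: int            # anchor-mate offset in the haplotype sequence
    q2: int | None     # other-mate offset (None: no concordant coupling)
    label: str         # source block label ("ref", "hybrid:...", ...)


@dataclass
class GroupResult:
    group: EventGroup
    table: PosteriorTable
    gamma: dict[str, float]
    observed: dict[str, float]
    expected_null: dict[str, float]
    n_informative: int
    n_discordant: int
    log_odds: dict[str, float] = field(default_factory=dict)
    n_hybrid: dict[str, int] = field(default_factory=dict)


@dataclass
class CallResult:
    calls: list[EventCall]
    group_results: list[GroupResult]
    fdr_fit: object = None

    def gamma_table(self):
        import pandas as pd

        rows = []
        for gr in self.group_results:
            for eid, g in gr.gamma.items():
                rows.append({"event_id": eid, "gamma": g})
        return pd.DataFrame(rows)


class _LikelihoodCache:
    """Memoized pair-HMM window scores keyed by (mate sequence, window)."""

    def __init__(self, error_model: ErrorModel, band: int):
        self.error_model = error_model
        self.band = band
        self._store: dict[tuple[str, str], float] = {}

    def score(self, mate_seq: str, context: str, anchor: int) -> float:
        lo = max(0, anchor - self.band)
        hi = min(len(context), anchor + len(mate_seq) + self.band)
        window = context[lo:hi]
        if len(window) < len(mate_seq):
            return _FLOOR
        key = (mate_seq, window)
        val = self._store.get(key)
        if val is None:
            val = read_likelihood(mate_seq, window, self.error_model)
            self._store[key] = val
        return val


def _lme_stack(arrays, weights) -> np.ndarray:
    """Elementwise log of the weighted mean of exponentials of broadcast
    arrays (the uniform-location-prior average in log space)."""
    stack = np.broadcast_arrays(*[np.atleast_1d(np.asarray(a, dtype=float)) for a in arrays])
    stack = np.stack(stack)
    w = np.asarray(weights, dtype=float)[:, None]
    m = stack.max(axis=0)
    safe = np.where(np.isfinite(m), m, 0.0)
    out = safe + np.log(np.sum(w * np.exp(stack - safe), axis=0) / w.sum())
    out = np.where(np.isfinite(m), out, -np.inf)
    return float(out[0]) if out.size == 1 else out


# ---------------------------------------------------------------------------
# group scoring engine
# ---------------------------------------------------------------------------

class GroupScorer:
    """Scores one event group against one sample's alignments."""

    def __init__(self, group: EventGroup, catalog: RepeatCatalog, reference,
                 bam: pysam.AlignmentFile, config: CallerConfig,
                 total_fragments: float, genome_size: float,
                 gc_curve: GCCurve | None = None):
        self.group = group
        self.catalog = catalog
        self.reference = reference
        self.bam = bam
        self.config = config
        self.N = total_fragments
        self.G = genome_size
        self.gc_curve = gc_curve or GCCurve.uniform(config.gc_bins)
        self.error_model = ErrorModel.from_config(config)
        self.fragment_model = FragmentModel.from_config(config)
        self.flank = config.flank()
        self.frag_cap = int(self.fragment_model.mean + 8 * self.fragment_model.sd)
        self.pad = self.flank + self.frag_cap + config.band
        self.cache = _LikelihoodCache(self.error_model, config.band)
        self._members = self._collect_members()
        self._vp_positions = self._collect_vp_positions()
        self._parts = self._build_partition()

    # --- geometry ---------------------------------------------------------

    def _collect_members(self):
        members = []
        for cls in self.group.classes:
            for m in cls.members:
                members.append((m, cls.id))
        members.sort(key=lambda t: t[0].start)
        return members

    def _collect_vp_positions(self) -> np.ndarray:
        pos = []
        for e in self.group.events:
            for k in range(e.n_vps):
                pa, pb = e.vp_ref_positions(k)
                pos.extend((pa, pb))
        return np.array(sorted(pos))

    def _build_partition(self):
        """Parts covering the group span: one part per homology class (all
        member intervals pooled — repeat read depth) and the unique gaps."""
        chrom, g_start, g_end = self.group.span()
        by_class: dict[str, list[tuple[int, int]]] = {}
        for m, cls_id in self._members:
            by_class.setdefault(cls_id, []).append((m.start, m.end))
        parts = []
        for cls_id, ivs in sorted(by_class.items()):
            parts.append((cls_id, sorted(ivs), "class"))
        covered = sorted(iv for ivs in by_class.values() for iv in ivs)
        cursor = g_start
        uniques = []
        for s, t in covered:
            if s > cursor:
                uniques.append((cursor, s))
            cursor = max(cursor, t)
        if cursor < g_end:
            uniques.append((cursor, g_end))
        for s, t in uniques:
            parts.append((f"U:{s}-{t}", [(s, t)], "unique"))
        return parts

    def member_of(self, pos: int):
        for m, cls_id in self._members:
            if m.start <= pos < m.end:
                return m, cls_id
        return None, None

    # --- depth ------------------------------------------------------------

    def observed_counts(self) -> dict[str, float]:
        chrom, _, _ = self.group.span()
        return {pid: count_fragment_starts(self.bam, [(chrom, s, t) for s, t in ivs])
                for pid, ivs, kind in self._parts}

    def expected_counts(self, hg: HypotheticalGenome) -> dict[str, float]:
        """mu per part: every haplotype block piece sourcing from the part
        contributes (N / 2G) fragments per (GC-weighted) base."""
        exp = {p[0]: 0.0 for p in self._parts}
        rate = self.N / (2.0 * self.G)
        for hap in hg.haplotypes:
            for b in hap.blocks:
                for pid, ivs, kind in self._parts:
                    for s, t in ivs:
                        lo, hi = max(b.src_start, s), min(b.src_end, t)
                        if hi > lo:
                            exp[pid] += rate * self._gc_weight(hg.chrom, lo, hi)
        floor = self.config.copy_factor_floor * self.N / self.G
        for pid, ivs, kind in self._parts:
            exp[pid] = max(exp[pid], floor * sum(t - s for s, t in ivs))
        return exp

    def _gc_weight(self, chrom: str, start: int, end: int) -> float:
        if self.gc_curve.is_uniform:
            return float(end - start)
        from nahrcall.depth import region_gc_weight

        return region_gc_weight(self.reference, [(chrom, start, end)], self.gc_curve,
                                int(self.fragment_model.mean))

    def depth_terms(self, observed, expected) -> list[tuple[float, float]]:
        return [(observed[pid], expected[pid]) for pid, *_ in self._parts]

    def event_gamma(self, observed, expected_null) -> dict[str, float]:
        """gamma per event over its unique inter-LCR span."""
        gamma = {}
        for e in self.group.events:
            z_start, z_end = e.inter_lcr()
            obs = exp = 0.0
            for pid, ivs, kind in self._parts:
                if kind == "unique" and all(s >= z_start and t <= z_end for s, t in ivs):
                    obs += observed[pid]
                    exp += expected_null[pid]
            gamma[e.id] = gamma_statistic(obs, exp) if exp > 0 else float("nan")
        return gamma

    # --- read recruitment -------------------------------------------------

    def informative_pairs(self, pairs: list[ReadPair]) -> list[ReadPair]:
        vp = self._vp_positions
        if len(vp) == 0:
            return []
        out = []
        for p in pairs:
            for pos, seq in ((p.pos1, p.seq1), (p.pos2, p.seq2)):
                i = np.searchsorted(vp, pos)
                if i < len(vp) and vp[i] < pos + len(seq):
                    out.append(p)
                    break
        return out

    # --- generic (block-map) path ----------------------------------------

    def _event_of_member(self, member):
        out = []
        for e in self.group.events:
            if e.lcr_a.overlaps(member):
                out.append((e, "a"))
            if e.lcr_b.overlaps(member):
                out.append((e, "b"))
        return out

    def member_overlapping(self, pos: int, rl: int):
        """The class member whose interval the read window [pos, pos+rl)
        overlaps (reads may start slightly upstream of the repeat)."""
        for m, cls_id in self._members:
            if pos + rl > m.start and pos < m.end:
                return m, cls_id
        return None, None

    def _homologous_positions(self, pos: int, rl: int = 1) -> list[int]:
        """Reference positions homologous to ``pos`` across its class."""
        member, cls_id = self.member_overlapping(pos, rl)
        if member is None:
            return [pos]
        positions = {pos}
        for event, side in self._event_of_member(member):
            lcr = event.lcr_a if side == "a" else event.lcr_b
            other = event.lcr_b if side == "a" else event.lcr_a
            offset = pos - lcr.start
            clipped = min(max(offset, 0), lcr.length - 1)
            proj = event.project_offset(side, clipped) + (offset - clipped)
            positions.add(other.start + proj)
        return sorted(positions)

    def _anchor_is_1(self, pair: ReadPair) -> bool:
        return not (self.member_overlapping(pair.pos1, len(pair.seq1))[0] is None
                    and self.member_overlapping(pair.pos2, len(pair.seq2))[0] is not None)

    def _block_positions(self, hap, ppos_list):
        out = []
        for ppos in ppos_list:
            for b in hap.blocks:
                if b.src_start <= ppos < b.src_end:
                    out.append((b.hyp_start + (ppos - b.src_start), b.label))
        return out

    def placements(self, pair: ReadPair, hg: HypotheticalGenome) -> list[Placement]:
        """Candidate placements of a pair in a hypothetical genome: the
        anchor mate at every block copy of its homologous positions, the
        other mate projected independently and coupled on the same haplotype
        at the candidate closest to the modal fragment length."""
        anchor_is_1 = self._anchor_is_1(pair)
        anchor_pos = pair.pos1 if anchor_is_1 else pair.pos2
        other_pos = pair.pos2 if anchor_is_1 else pair.pos1
        rl_anchor = len(pair.seq1 if anchor_is_1 else pair.seq2)
        rl_other = len(pair.seq2 if anchor_is_1 else pair.seq1)
        homologs = self._homologous_positions(anchor_pos, rl_anchor)
        other_homologs = self._homologous_positions(other_pos, rl_other)
        out: list[Placement] = []
        seen = set()
        for hi, hap in enumerate(hg.haplotypes):
            anchors = self._block_positions(hap, homologs)
            others = [q for q, _ in self._block_positions(hap, other_homologs)
                      if 0 <= q <= len(hap.sequence) - rl_other]
            for q1, label in anchors:
                if (hi, q1) in seen:
                    continue
                seen.add((hi, q1))
                q2 = None
                if others:
                    q2 = min(others, key=lambda q: abs(abs(q - q1) - self.fragment_model.mean))
                    if abs(q2 - q1) > self.frag_cap:
                        q2 = None
                out.append(Placement(hi, q1, q2, label))
        return out

    def pair_log_lik(self, pair: ReadPair, pl: Placement, hg: HypotheticalGenome,
                     anchor_is_1: bool = True) -> float:
        hap = hg.haplotypes[pl.haplotype]
        s_anchor = pair.seq1 if anchor_is_1 else pair.seq2
        s_other = pair.seq2 if anchor_is_1 else pair.seq1
        val = self.cache.score(s_anchor, hap.sequence, pl.q1)
        if pl.q2 is not None:
            val += self.cache.score(s_other, hap.sequence, pl.q2)
        else:
            # nowhere concordant for the other mate on this haplotype:
            # charge it as a fully mismatched alignment
            val += len(s_other) * math.log(self.error_model.base_error)
        return val

    def read_term(self, pairs, hg: HypotheticalGenome, keep_detail: bool = False):
        total = 0.0
        detail = []
        for pair in pairs:
            a1 = self._anchor_is_1(pair)
            pls = self.placements(pair, hg)
            if not pls:
                total += _FLOOR
                if keep_detail:
                    detail.append((pair, [], np.array([])))
                continue
            logs = np.array([self.pair_log_lik(pair, pl, hg, a1) for pl in pls])
            total += logmeanexp(logs)
            if keep_detail:
                detail.append((pair, pls, logs))
        return (total, detail) if keep_detail else (total, None)

    # --- dispatch ---------------------------------------------------------

    def score(self) -> GroupResult:
        if self._fast_event() is not None:
            return self._score_fast()
        return self._score_generic()

    def _fast_event(self) -> PotentialEvent | None:
        if self.group.size != 1 or len(self.group.classes) != 1:
            return None
        e = self.group.events[0]
        if (e.orientation == "positive" and e.n_vps >= 1
                and "deletion" in e.allowed_outcomes
                and "-" not in e.aln_a and "-" not in e.aln_b
                and len(self.group.classes[0].members) == 2
                and e.lcr_a.length == e.lcr_b.length):
            return e
        return None

    # --- generic scoring --------------------------------------------------

    def _score_generic(self) -> GroupResult:
        cfg = self.config
        group = self.group
        pairs = recruit_reads(self.bam, group, self.catalog, flank=self.flank)
        informative = self.informative_pairs(pairs)
        hypotheses = enumerate_hypotheses(group, cfg)
        observed = self.observed_counts()
        priors = Priors.from_config(cfg)
        log_joints = np.empty(len(hypotheses))
        genomes: list[HypotheticalGenome] = []
        for i, h in enumerate(hypotheses):
            hg = apply_hypothesis(self.reference, group, h, pad=self.pad)
            genomes.append(hg)
            expected = self.expected_counts(hg)
            read_total, _ = self.read_term(informative, hg)
            log_joints[i] = joint_log_prob(group, h, [read_total],
                                           self.depth_terms(observed, expected), priors)
        table = PosteriorTable(group, hypotheses, log_joints)
        null_idx = next(i for i, h in enumerate(hypotheses) if h.is_null)
        exp_null = self.expected_counts(genomes[null_idx])
        gamma = self.event_gamma(observed, exp_null)
        n_disc = sum(1 for p in pairs if not p.is_proper)
        result = GroupResult(group, table, gamma, observed, exp_null,
                             n_informative=len(informative), n_discordant=n_disc)
        map_hyp = table.map_hypothesis()
        if not map_hyp.is_null:
            mi = table.map_index()
            _, detail_map = self.read_term(informative, genomes[mi], keep_detail=True)
            _, detail_null = self.read_term(informative, genomes[null_idx], keep_detail=True)
            by_id = {e.id: e for e in group.events}
            for e in group.events:
                a = map_hyp[e.id]
                if a.is_null or a.outcome == "gene_conversion":
                    continue
                lo, n_hyb = self._breakpoint_stats(by_id[e.id], a, detail_map, detail_null)
                result.log_odds[e.id] = lo
                result.n_hybrid[e.id] = n_hyb
        return result

    def _breakpoint_stats(self, event, assignment, detail_map, detail_null):
        """ln(P_A/P_0) over the reads near the called breakpoint.

        P_0 averages each read over the breakpoint windows of every paralog
        (its null-genome location set); P_A over the location set after the
        rearrangement — the hybrid window included, the pair of windows it
        replaced removed per rearranged homolog (the MAP genome's
        placements).  Reads showing the VP switch gain strongly on the
        hybrid; reads without it pay the location dilution, so only genuine
        breakpoints accumulate positive log odds.
        """
        k = assignment.breakpoint
        pa, pb = event.vp_ref_positions(k)
        w = self.flank
        null_logs, alt_logs = [], []
        n_hybrid = 0
        for (pair, pls_m, logs_m), (_, pls_n, logs_n) in zip(detail_map, detail_null):
            hyb_mask = np.array([pl.label.startswith("hybrid:") for pl in pls_m])
            if len(logs_m) and hyb_mask.any():
                post_hybrid = float(np.exp(
                    logmeanexp(logs_m[hyb_mask]) + np.log(hyb_mask.sum())
                    - logmeanexp(logs_m) - np.log(len(logs_m))))
                if post_hybrid > 0.5:
                    n_hybrid += 1
            near = any(abs(pos - bp) <= w
                       for pos in (pair.pos1, pair.pos2) for bp in (pa, pb))
            if not near or not len(logs_n) or not len(logs_m):
                continue
            null_logs.append(logs_n)
            alt_logs.append(logs_m)
        return _bp_log_odds_from_logs(null_logs, alt_logs), n_hybrid

    # --- fast path: single event, SNP-only VPs ---------------------------

    def _fast_contexts(self, e: PotentialEvent):
        """Sequence contexts shared by every hypothesis of a SNP-only pair:
        the reference around each repeat, the deletion hybrid locus per k,
        the tandem duplication hybrid per k, and gene-conversion variants."""
        chrom = e.chrom
        P = self.pad
        a, b = e.lcr_a, e.lcr_b
        L = a.length
        startA = max(0, a.start - P)
        startB = max(0, b.start - P)
        PA, PB = a.start - startA, b.start - startB
        ctxA = fetch_sequence(self.reference, chrom, startA, a.end + P)
        ctxB = fetch_sequence(self.reference, chrom, startB, b.end + P)
        left = fetch_sequence(self.reference, chrom, startA, a.start)
        right = fetch_sequence(self.reference, chrom, b.end, b.end + P)
        Z = fetch_sequence(self.reference, chrom, a.end, b.start)
        leftZ = Z[-P:] if Z else ""
        ctx_del = [left + hybrid_sequence(e, "AB", k) + right for k in range(e.n_vps)]
        ctx_dup = [leftZ + hybrid_sequence(e, "BA", k) + Z[:P] for k in range(e.n_vps)]
        return {"A": ctxA, "B": ctxB, "del": ctx_del, "dup": ctx_dup,
                "Z_len": len(Z), "L": L, "P": P,
                "PA": PA, "PB": PB, "PU": len(leftZ)}

    def _gc_variants(self, e: PotentialEvent):
        """(donor, k1, k2) -> context with the converted recipient repeat."""
        from nahrcall.mechanics import gene_conversion_sequence

        cfg = self.config
        out = {}
        if not cfg.gene_conversion or e.n_vps < 2:
            return out
        import itertools

        pairs = sorted(itertools.combinations(range(e.n_vps), 2),
                       key=lambda p: (-(p[1] - p[0]), p))[: cfg.max_gc_pairs]
        P = self.pad
        chrom = e.chrom
        leftA = fetch_sequence(self.reference, chrom, max(0, e.lcr_a.start - P), e.lcr_a.start)
        rightA = fetch_sequence(self.reference, chrom, e.lcr_a.end, e.lcr_a.end + P)
        leftB = fetch_sequence(self.reference, chrom, max(0, e.lcr_b.start - P), e.lcr_b.start)
        rightB = fetch_sequence(self.reference, chrom, e.lcr_b.end, e.lcr_b.end + P)
        for k1, k2 in pairs:
            out[("b", k1, k2)] = leftA + gene_conversion_sequence(e, "b", k1, k2) + rightA
            out[("a", k1, k2)] = leftB + gene_conversion_sequence(e, "a", k1, k2) + rightB
        return out

    def _fast_pair_frames(self, e: PotentialEvent, pair: ReadPair):
        """Anchor/other mate frame offsets for the fast path.

        Returns (anchor_seq, u_anchor, other_seq, other_kind, other_val)
        where other_kind is "member" (other_val = frame offset), "unique"
        (reference position), and u_anchor the anchor's offset within its
        repeat frame.
        """
        a, b = e.lcr_a, e.lcr_b

        def frame(pos, rl):
            # window-overlap anchoring (the window may start upstream of the repeat)
            for m in (a, b):
                if pos + rl > m.start and pos < m.end:
                    return pos - m.start
            return None

        u1 = frame(pair.pos1, len(pair.seq1))
        u2 = frame(pair.pos2, len(pair.seq2))
        if u1 is not None:
            anchor = (pair.seq1, u1)
            other = (pair.seq2, "member", u2) if u2 is not None else (pair.seq2, "unique", pair.pos2)
        elif u2 is not None:
            anchor = (pair.seq2, u2)
            other = (pair.seq1, "member", u1) if u1 is not None else (pair.seq1, "unique", pair.pos1)
        else:
            return None
        return anchor, other

    def _fast_pair_values(self, e: PotentialEvent, ctx, gc_ctx, pair: ReadPair):
        """Per-pair log pair-likelihood against every candidate copy type."""
        frames = self._fast_pair_frames(e, pair)
        if frames is None:
            return None
        (s_anchor, u), (s_other, okind, oval) = frames
        L, Z_len = ctx["L"], ctx["Z_len"]
        PA, PB, PU = ctx["PA"], ctx["PB"], ctx["PU"]
        a, b = e.lcr_a, e.lcr_b
        rl_o = len(s_other)
        miss = rl_o * math.log(self.error_model.base_error)

        def value(context, q1, q2):
            v = self.cache.score(s_anchor, context, q1)
            if (q2 is None or q2 < 0 or q2 > len(context) - rl_o
                    or abs(q2 - q1) > self.frag_cap):
                return v + miss  # no concordant coupling here
            return v + self.cache.score(s_other, context, q2)

        # reference copies: unique other mates sit at their reference offset
        if okind == "member":
            q2A, q2B = PA + oval, PB + oval
        else:
            q2A = oval - (a.start - PA)
            q2B = oval - (b.start - PB)
        vA = value(ctx["A"], PA + u, q2A)
        vB = value(ctx["B"], PB + u, q2B)

        # deletion hybrid: flanks of A on the left, of B on the right
        q1D = PA + u
        if okind == "member":
            q2D = PA + oval
        elif oval < a.start:
            q2D = oval - (a.start - PA)
        elif oval >= b.end:
            q2D = PA + L + (oval - b.end)
        else:
            q2D = None  # the intervening sequence does not exist here
        vD = np.array([value(c, q1D, q2D) for c in ctx["del"]])

        # tandem duplication hybrid: intervening sequence on both sides
        q1U = PU + u
        if okind == "member":
            q2U = PU + oval
        elif a.end <= oval < b.start:
            z_off = oval - a.end
            cands = []
            if z_off >= Z_len - PU:
                cands.append(PU - (Z_len - z_off))
            if z_off < PU:
                cands.append(PU + L + z_off)
            q2U = min(cands, key=lambda q: abs(abs(q - q1U) - self.fragment_model.mean)) \
                if cands else None
        else:
            q2U = None
        vU = np.array([value(c, q1U, q2U) for c in ctx["dup"]])

        vGC = {}
        for key, context in gc_ctx.items():
            donor = key[0]
            recipient_lcr, PR = (a, PA) if donor == "b" else (b, PB)
            if okind == "member":
                q2g = PR + oval
            else:
                q2g = oval - (recipient_lcr.start - PR)
            vGC[key] = value(context, PR + u, q2g)
        return vA, vB, vD, vU, vGC

    def _score_fast(self) -> GroupResult:
        cfg = self.config
        group = self.group
        e = group.events[0]
        pairs = recruit_reads(self.bam, group, self.catalog, flank=self.flank)
        informative = self.informative_pairs(pairs)
        hypotheses = enumerate_hypotheses(group, cfg)
        observed = self.observed_counts()
        priors = Priors.from_config(cfg)
        ctx = self._fast_contexts(e)
        gc_ctx = self._gc_variants(e)
        nk = e.n_vps

        # accumulate read terms per hypothesis family
        acc = {"null": 0.0, ("deletion", 1): np.zeros(nk), ("deletion", 2): np.zeros(nk),
               ("duplication", 1): np.zeros(nk), ("duplication", 2): np.zeros(nk)}
        acc_gc = {key: 0.0 for key in gc_ctx}
        per_pair = []
        for pair in informative:
            vals = self._fast_pair_values(e, ctx, gc_ctx, pair)
            if vals is None:
                continue
            vA, vB, vD, vU, vGC = vals
            per_pair.append((pair, vals))
            acc["null"] += _lme_stack([vA, vB], [1, 1])
            acc[("deletion", 1)] += _lme_stack([vA, vB, vD], [1, 1, 1])
            acc[("deletion", 2)] += vD
            acc[("duplication", 1)] += _lme_stack([vA, vB, vU], [2, 2, 1])
            acc[("duplication", 2)] += _lme_stack([vA, vB, vU], [1, 1, 1])
            for key, vg in vGC.items():
                if key[0] == "b":  # A converted; copies: conv, A, B, B
                    acc_gc[key] += _lme_stack([vg, vA, vB], [1, 1, 2])
                else:
                    acc_gc[key] += _lme_stack([vg, vA, vB], [1, 2, 1])

        # depth expectations per hypothesis family (k-independent for SNPs)
        depth_by_family = {}
        genomes_by_family = {}
        for fam in ["null", ("deletion", 1), ("deletion", 2),
                    ("duplication", 1), ("duplication", 2)]:
            if fam == "null":
                assign = EventAssignment(e.id)
            else:
                assign = EventAssignment(e.id, fam[0], fam[1], 0)
            hg = apply_hypothesis(self.reference, group,
                                  Hypothesis((assign,)), pad=self.pad)
            genomes_by_family[fam] = hg
            depth_by_family[fam] = self.expected_counts(hg)
        depth_gc = depth_by_family["null"]  # gene conversion preserves copy number

        log_joints = np.empty(len(hypotheses))
        for i, h in enumerate(hypotheses):
            assignment = h.assignments[0]
            if assignment.is_null:
                read_total = acc["null"]
                expected = depth_by_family["null"]
            elif assignment.outcome == "gene_conversion":
                key = (assignment.donor, *assignment.breakpoint)
                read_total = acc_gc[key]
                expected = depth_gc
            else:
                fam = (assignment.outcome, assignment.multiplicity)
                read_total = acc[fam][assignment.breakpoint]
                expected = depth_by_family[fam]
            log_joints[i] = joint_log_prob(group, h, [read_total],
                                           self.depth_terms(observed, expected), priors)
        table = PosteriorTable(group, hypotheses, log_joints)
        exp_null = depth_by_family["null"]
        gamma = self.event_gamma(observed, exp_null)
        n_disc = sum(1 for p in pairs if not p.is_proper)
        result = GroupResult(group, table, gamma, observed, exp_null,
                             n_informative=len(informative), n_discordant=n_disc)

        map_hyp = table.map_hypothesis()
        a_map = map_hyp.assignments[0]
        if not a_map.is_null and a_map.outcome != "gene_conversion":
            k = a_map.breakpoint
            pa, pb = e.vp_ref_positions(k)
            w = self.flank
            null_logs, alt_logs = [], []
            n_hybrid = 0
            for pair, (vA, vB, vD, vU, vGC) in per_pair:
                if a_map.outcome == "deletion":
                    vH = vD[k]
                    if a_map.multiplicity == 1:
                        alt = np.array([vA, vB, vH])
                        hyb_mask = np.array([False, False, True])
                    else:
                        alt = np.array([vH])
                        hyb_mask = np.array([True])
                else:
                    vH = vU[k]
                    m = a_map.multiplicity
                    alt = np.array([vA, vA, vB, vB] + [vH] * m)
                    hyb_mask = np.array([False] * 4 + [True] * m)
                post_hybrid = float(np.exp(
                    logmeanexp(alt[hyb_mask]) + np.log(hyb_mask.sum())
                    - logmeanexp(alt) - np.log(len(alt))))
                if post_hybrid > 0.5:
                    n_hybrid += 1
                near = any(abs(pos - bp) <= w
                           for pos in (pair.pos1, pair.pos2) for bp in (pa, pb))
                if near:
                    null_logs.append(np.array([vA, vB]))
                    alt_logs.append(alt)
            result.log_odds[e.id] = _bp_log_odds_from_logs(null_logs, alt_logs)
            result.n_hybrid[e.id] = n_hybrid
        return result


# ---------------------------------------------------------------------------
# sample-level driver
# ---------------------------------------------------------------------------

def score_sample(bam_path, catalog: RepeatCatalog, reference,
                 config: CallerConfig | None = None,
                 gc_curve: GCCurve | None = None) -> list[GroupResult]:
    """Score every group of a sample (no fdr pooling yet)."""
    config = config or CallerConfig()
    results: list[GroupResult] = []
    with pysam.AlignmentFile(str(bam_path)) as bam:
        genome_size = float(sum(bam.lengths))
        stats = bam.get_index_statistics()
        total_fragments = sum(s.mapped for s in stats) / 2.0
        for group in catalog.groups:
            scorer = GroupScorer(group, catalog, reference, bam, config,
                                 total_fragments, genome_size, gc_curve)
            results.append(scorer.score())
    return results


def call_sample(bam_path, catalog: RepeatCatalog, reference,
                config: CallerConfig | None = None,
                gc_curve: GCCurve | None = None,
                extra_gammas=None) -> CallResult:
    """Run the caller on one sample: score every group, pool gamma across
    loci for the empirical-null local fdr, and emit filtered calls.

    ``extra_gammas``: optional gamma values from other samples/loci of the
    same run, pooled into the fdr fit (the fit needs >= min_fdr_loci values).
    """
    config = config or CallerConfig()
    results = score_sample(bam_path, catalog, reference, config, gc_curve)
    return finalize_calls(results, config, extra_gammas)


def finalize_calls(results: list[GroupResult], config: CallerConfig,
                   extra_gammas=None) -> CallResult:
    """Pool gamma, fit the local fdr, apply thresholds, emit calls."""
    gammas, owners = [], []
    for gr in results:
        for eid, g in gr.gamma.items():
            if np.isfinite(g):
                gammas.append(g)
                owners.append(eid)
    pooled = list(gammas) + [float(g) for g in (extra_gammas or [])]
    fdr_by_event = {}
    fit = None
    if len(pooled) >= config.min_fdr_loci:
        fdrs, fit = local_fdr(pooled, config, return_fit=True)
        for eid, f in zip(owners, fdrs[: len(owners)]):
            fdr_by_event[eid] = float(f)
    else:
        logger.warning("only %d gamma values; local fdr not fitted (need %d)",
                       len(pooled), config.min_fdr_loci)

    calls: list[EventCall] = []
    for gr in results:
        stats_by_event = {}
        for e in gr.group.events:
            stats_by_event[e.id] = {
                "gamma": gr.gamma.get(e.id, float("nan")),
                "fdr": fdr_by_event.get(e.id, float("nan")),
                "log_odds": gr.log_odds.get(e.id, float("nan")),
                "n_hybrid_reads": gr.n_hybrid.get(e.id, 0),
                "n_discordant_reads": gr.n_discordant,
            }
        calls.extend(call_group(gr.table, config, stats_by_event))
    return CallResult(calls=calls, group_results=results, fdr_fit=fit)


def filtered_calls(result: CallResult) -> list[EventCall]:
    """The conservative call set: fdr <= threshold (pass_fdr)."""
    return [c for c in result.calls if c.pass_fdr]
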