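"""Synthetic study harness: genomes with planted LCR pairs, planted NAHR
events, GC-aware paired-end read simulation, and call scoring.

The generator emulates the study conditions end to end: a random background
genome carrying positively oriented repeat pairs of configured length and
identity (SNP variational positions placed uniformly at random), one-copy
NAHR events planted at a random subset of loci, and 15x paired-end reads
(100 bp, 400 +/- 40 bp fragments) with 2% uniform substitution errors.  The
truth SAM places every read at its generating origin projected through the
hypothetical-genome coordinate map back onto the reference — exactly the
phantom-concordant placement a mapper would produce for hybrid reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from nahrcall import io as nio
from nahrcall.catalog import RepeatCatalog, build_catalog, load_segdup_table
from nahrcall.mechanics import (
    EventAssignment,
    Haplotype,
    Block,
    Hypothesis,
    apply_hypothesis,
)
from nahrcall.readmodel import revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for one synthetic replicate."""

    n_pairs: int = 30
    lcr_length: tuple[int, int] = (1000, 1400)
    identity: float = 0.97
    vp_count: tuple[int, int] | None = None  # overrides identity-derived VP number
    inter_lcr: tuple[int, int] = (4000, 10000)
    spacing: tuple[int, int] = (40000, 60000)
    flank: int = 50000
    coverage: float = 15.0
    fragment_mean: float = 400.0
    fragment_sd: float = 40.0
    read_length: int = 100
    base_error: float = 0.02
    gc_curve: object = None  # optional GCCurve biasing fragment placement
    seed: int = 0
    chrom: str = "chrS"

    def __post_init__(self):
        if not 0.9 <= self.identity < 1.0:
            raise ValueError("identity must lie in [0.9, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def make_genome(cfg: SimConfig, out_prefix=None):
    """Generate a reference with planted positively oriented LCR pairs.

    Returns (reference: dict chrom->sequence, segdup_rows) and, with
    ``out_prefix``, writes the FASTA and the pair table (which round-trips
    through the catalog loader).
    """
    rng = np.random.default_rng(cfg.seed)
    parts: list[np.ndarray] = []
    rows = []
    pos = 0

    def emit(arr: np.ndarray):
        nonlocal pos
        parts.append(arr)
        pos += len(arr)

    emit(_random_seq(rng, cfg.flank))
    for i in range(cfg.n_pairs):
        lcr_len = int(rng.integers(cfg.lcr_length[0], cfg.lcr_length[1] + 1))
        if cfg.vp_count is not None:
            n_vp = int(rng.integers(cfg.vp_count[0], cfg.vp_count[1] + 1))
        else:
            n_vp = max(1, int(round(lcr_len * (1.0 - cfg.identity))))
        if n_vp > lcr_len - 20:
            raise ValueError("infeasible geometry: more VPs than available positions")
        a = _random_seq(rng, lcr_len)
        b = a.copy()
        vp_pos = np.sort(rng.choice(np.arange(10, lcr_len - 10), size=n_vp, replace=False))
        for p in vp_pos:
            alt = _BASES[(np.where(_BASES == b[p])[0][0] + rng.integers(1, 4)) % 4]
            b[p] = alt
        z_len = int(rng.integers(cfg.inter_lcr[0], cfg.inter_lcr[1] + 1))
        start_a = pos
        emit(a)
        emit(_random_seq(rng, z_len))
        start_b = pos
        emit(b)
        ident = 1.0 - n_vp / lcr_len
        rows.append((cfg.chrom, start_a, start_a + lcr_len,
                     cfg.chrom, start_b, start_b + lcr_len, "+", ident))
        emit(_random_seq(rng, int(rng.integers(cfg.spacing[0], cfg.spacing[1] + 1))))
    emit(_random_seq(rng, cfg.flank))
    genome = b"".join(p.tobytes() for p in parts).decode()
    reference = {cfg.chrom: genome}
    if out_prefix is not None:
        nio.write_fasta(reference, f"{out_prefix}.fasta")
        nio.write_segdup_table(rows, f"{out_prefix}.segdups.tsv")
    return reference, rows


def catalog_from_simulation(reference, rows, config=None, tmpdir=None) -> RepeatCatalog:
    """Round-trip the generated pair table through the standard loader."""
    import tempfile

    with tempfile.TemporaryDirectory(dir=tmpdir) as td:
        path = Path(td) / "segdups.tsv"
        nio.write_segdup_table(rows, path)
        events = load_segdup_table(path, reference, config)
    return build_catalog(events)


@dataclass
class TruthSet:
    """Planted events of one replicate."""

    rows: list[dict] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows,
                            columns=["event_id", "outcome", "multiplicity", "vp_index"])

    def write(self, path) -> None:
        self.frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "TruthSet":
        return cls(pd.read_csv(path, sep="\t").to_dict("records"))


def plant_events(reference, catalog: RepeatCatalog, k: int, seed: int = 0,
                 outcomes=("deletion", "duplication"),
                 multiplicity: int = 1):
    """Draw k one-copy NAHR events at random loci (without replacement,
    respecting exclusivity) and rearrange one homolog accordingly.

    Returns (haplotypes, truth): haplotypes is a list of two
    :class:`~nahrcall.mechanics.Haplotype` objects covering the whole
    chromosome — the rearranged homolog and the untouched one.
    """
    rng = np.random.default_rng(seed)
    singles = [g for g in catalog.groups if g.size == 1]
    if k > len(singles):
        raise ValueError(f"cannot plant {k} events at {len(singles)} isolated loci")
    chosen_idx = sorted(rng.choice(len(singles), size=k, replace=False))
    chrom = catalog.events[0].chrom if catalog.events else "chr"
    length = len(reference[chrom])
    assignments = []
    truth = TruthSet()
    for gi in chosen_idx:
        event = singles[gi].events[0]
        outcome = str(rng.choice(list(outcomes)))
        vp = int(rng.integers(0, event.n_vps))
        assignments.append(EventAssignment(event.id, outcome, multiplicity, vp))
        truth.rows.append({"event_id": event.id, "outcome": outcome,
                           "multiplicity": multiplicity, "vp_index": vp})
    all_events = [e for g in catalog.groups for e in g.events]
    from nahrcall.catalog import EventGroup

    group = EventGroup(id="planted", events=sorted(all_events, key=lambda e: e.lcr_a.start))
    planted_ids = {a.event_id for a in assignments}
    hyp = Hypothesis(tuple(
        list(assignments) + [EventAssignment(e.id) for e in group.events
                             if e.id not in planted_ids]))
    hg = apply_hypothesis(reference, group, hyp, locus=(0, length))
    return [hg.haplotypes[0], hg.haplotypes[1]], truth


def reference_haplotypes(reference, chrom: str) -> list[Haplotype]:
    seq = reference[chrom]
    blk = [Block(0, len(seq), chrom, 0, len(seq))]
    return [Haplotype(seq, list(blk)), Haplotype(seq, list(blk))]


def simulate_reads(haplotypes, cfg: SimConfig, out_prefix,
                   repeat_intervals=None, write_truth_sam: bool = True,
                   write_fastq: bool = True,
                   reference_lengths: dict[str, int] | None = None):
    """Simulate GC-aware paired-end reads from a diploid genome.

    Fragments are drawn uniformly (or weighted by the GC curve), mates read
    off both ends, substitution errors applied at ``base_error``.  Writes
    paired FASTQ and, optionally, a truth SAM whose placements are the true
    origins projected back to reference coordinates.  Returns a dict with
    paths and the fragment count.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    rl = cfg.read_length
    hap_lens = np.array([len(h.sequence) for h in haplotypes], dtype=float)
    total_len = hap_lens.sum()
    if cfg.fragment_mean >= hap_lens.min():
        raise ValueError("fragment mean exceeds genome length")
    n_frag = int(round(cfg.coverage * total_len / (2 * rl)))
    n_per_hap = rng.multinomial(n_frag, hap_lens / total_len)

    chrom = haplotypes[0].blocks[0].chrom
    ref_len = (reference_lengths or {}).get(chrom)
    if ref_len is None:
        ref_len = max(b.src_end for h in haplotypes for b in h.blocks)

    rep_iv = sorted(repeat_intervals or [])
    rep_starts = np.array([s for s, _ in rep_iv])
    rep_ends = np.array([e for _, e in rep_iv])

    r1_records, r2_records, sam_records = [], [], []
    qual = "I" * rl
    frag_counter = 0
    for hi, (hap, n_h) in enumerate(zip(haplotypes, n_per_hap)):
        seq = hap.sequence
        L = len(seq)
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        flens = np.clip(rng.normal(cfg.fragment_mean, cfg.fragment_sd, size=n_h).round().astype(int),
                        rl, L - 1)
        starts = (rng.random(n_h) * (L - flens)).astype(int)
        if cfg.gc_curve is not None:
            gc_cum = np.concatenate([[0], np.cumsum((arr == ord("G")) | (arr == ord("C")))])
            gc = (gc_cum[starts + flens] - gc_cum[starts]) / flens
            w = cfg.gc_curve.rate(gc)
            keep = rng.random(n_h) < w / max(w.max(), 1e-9)
            # resample rejected fragments uniformly until the count is met
            while not keep.all():
                n_bad = int((~keep).sum())
                flens[~keep] = np.clip(
                    rng.normal(cfg.fragment_mean, cfg.fragment_sd, n_bad).round().astype(int),
                    rl, L - 1)
                starts[~keep] = (rng.random(n_bad) * (L - flens[~keep])).astype(int)
                gc = (gc_cum[starts + flens] - gc_cum[starts]) / flens
                w = cfg.gc_curve.rate(gc)
                keep |= rng.random(n_h) < w / max(w.max(), 1e-9)
        # mate windows on the haplotype (vectorized extraction + errors)
        p1 = starts
        p2 = starts + flens - rl
        blk_starts = np.array([b.hyp_start for b in hap.blocks])
        blk_src = np.array([b.src_start for b in hap.blocks])
        bi1 = np.searchsorted(blk_starts, p1, side="right") - 1
        bi2 = np.searchsorted(blk_starts, p2, side="right") - 1
        ref1 = blk_src[bi1] + (p1 - blk_starts[bi1])
        ref2 = blk_src[bi2] + (p2 - blk_starts[bi2])
        cols = np.arange(rl)
        code_of = np.zeros(256, dtype=np.uint8)
        for ci, bb in enumerate(_BASES):
            code_of[bb] = ci
        mats = []
        for p in (p1, p2):
            m = arr[p[:, None] + cols[None, :]].copy()
            err = rng.random(m.shape) < cfg.base_error
            if err.any():
                cur = code_of[m[err]]
                shift = rng.integers(1, 4, size=cur.shape).astype(np.uint8)
                m[err] = _BASES[(cur + shift) % 4]
            mats.append(m)
        m1, m2 = mats
        proper_arr = (ref1 <= ref2) & (ref2 + rl - ref1 >= rl) \
            & (ref2 + rl - ref1 <= cfg.fragment_mean + 4 * cfg.fragment_sd)
        for j in range(n_h):
            name = f"frag{frag_counter + j}_h{hi}"
            fwd1 = m1[j].tobytes().decode()
            fwd2 = m2[j].tobytes().decode()
            if write_fastq:
                r1_records.append((name, fwd1, qual))
                r2_records.append((name, revcomp(fwd2), qual))
            if write_truth_sam:
                rp1, rp2 = int(ref1[j]), int(ref2[j])
                tlen = (rp2 + rl) - rp1
                proper = bool(proper_arr[j])
                flag1 = 0x1 | 0x2 * proper | 0x20 | 0x40
                flag2 = 0x1 | 0x2 * proper | 0x10 | 0x80
                mq1 = 0 if _in_repeat(rp1, rl, rep_starts, rep_ends) else 60
                mq2 = 0 if _in_repeat(rp2, rl, rep_starts, rep_ends) else 60
                sam_records.append(
                    f"{name}\t{flag1}\t{chrom}\t{rp1 + 1}\t{mq1}\t{rl}M\t=\t{rp2 + 1}\t{tlen}\t{fwd1}\t{qual}")
                sam_records.append(
                    f"{name}\t{flag2}\t{chrom}\t{rp2 + 1}\t{mq2}\t{rl}M\t=\t{rp1 + 1}\t{-tlen}\t{fwd2}\t{qual}")
        frag_counter += int(n_h)

    out_prefix = str(out_prefix)
    result = {"n_fragments": frag_counter, "seed": cfg.seed}
    if write_fastq:
        fq1, fq2 = f"{out_prefix}_R1.fastq", f"{out_prefix}_R2.fastq"
        nio.write_fastq(r1_records, fq1)
        nio.write_fastq(r2_records, fq2)
        result.update(fastq1=fq1, fastq2=fq2)
    if write_truth_sam:
        sam = f"{out_prefix}.truth.sam"
        with open(sam, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            fh.write(f"@SQ\tSN:{chrom}\tLN:{ref_len}\n")
            fh.write(f"@RG\tID:sim\tSM:sim\n")
            fh.write("\n".join(sam_records))
            fh.write("\n")
        result["truth_sam"] = sam
    return result


def _in_repeat(pos: int, rl: int, starts: np.ndarray, ends: np.ndarray) -> bool:
    if len(starts) == 0:
        return False
    i = int(np.searchsorted(ends, pos, side="right"))
    return i < len(starts) and starts[i] < pos + rl


def evaluate_calls(truth: TruthSet, calls, universe) -> dict:
    """Score calls against the planted truth.

    sensitivity: planted events recovered with the correct outcome /
    planted; specificity: non-planted loci without a call / non-planted
    loci; breakpoint_accuracy: true-positive calls whose breakpoint region
    (v_k, v_{k+1}] contains the planted crossover, i.e. matches the planted
    VP index.
    """
    truth_by_id = {r["event_id"]: r for r in truth.rows}
    universe = list(universe)
    if not set(truth_by_id) <= set(universe):
        raise ValueError("truth events missing from the tested universe")
    calls_by_id = {}
    for c in calls:
        calls_by_id.setdefault(c.event_id, []).append(c)
    unknown = set(calls_by_id) - set(universe)
    if unknown:
        raise ValueError(f"calls outside the tested universe: {sorted(unknown)}")
    tp = bp_ok = 0
    for eid, row in truth_by_id.items():
        matched = [c for c in calls_by_id.get(eid, []) if c.outcome == row["outcome"]]
        if matched:
            tp += 1
            if any(c.breakpoint_index == row["vp_index"] for c in matched):
                bp_ok += 1
    nulls = [u for u in universe if u not in truth_by_id]
    fp = sum(1 for u in nulls if calls_by_id.get(u))
    sensitivity = tp / len(truth_by_id) if truth_by_id else float("nan")
    specificity = (len(nulls) - fp) / len(nulls) if nulls else float("nan")
    bp_acc = bp_ok / tp if tp else float("nan")
    return {"sensitivity": sensitivity, "specificity": specificity,
            "breakpoint_accuracy": bp_acc, "n_true": len(truth_by_id),
            "n_null": len(nulls), "n_false_positive": fp}


def run_replicate(sim: SimConfig, n_events: int, workdir, config=None):
    """One replicate of the study: genome -> catalog -> planted events ->
    reads -> scored groups.  Returns (catalog, truth, group_results)."""
    from nahrcall import io as nio2
    from nahrcall.pipeline import score_sample

    reference, rows = make_genome(sim)
    catalog = catalog_from_simulation(reference, rows)
    haplotypes, truth = plant_events(reference, catalog, n_events, seed=sim.seed)
    repeat_iv = sorted([(e.lcr_a.start, e.lcr_a.end) for e in catalog.events]
                       + [(e.lcr_b.start, e.lcr_b.end) for e in catalog.events])
    prefix = Path(workdir) / f"rep{sim.seed}"
    res = simulate_reads(haplotypes, sim, prefix, repeat_intervals=repeat_iv,
                         write_fastq=False,
                         reference_lengths={sim.chrom: len(reference[sim.chrom])})
    bam = nio2.sam_to_indexed_bam(res["truth_sam"])
    results = score_sample(bam, catalog, reference, config)
    return catalog, truth, results


def simulation_study(seeds, n_events: int = 5, workdir=None, config=None,
                     sim_template: SimConfig | None = None) -> dict:
    """The scaled-down version of the published simulation protocol:
    per seeded replicate, plant ``n_events`` one-copy NAHR events, simulate
    15x reads, run the caller; pool gamma across all replicates for one
    empirical-null fdr fit; score the fdr-filtered calls against truth.
    """
    import dataclasses as _dc
    import tempfile

    from nahrcall.config import CallerConfig
    from nahrcall.pipeline import filtered_calls, finalize_calls

    config = config or CallerConfig()
    sim_template = sim_template or SimConfig()
    own_dir = workdir is None
    tmp = tempfile.TemporaryDirectory() if own_dir else None
    workdir = Path(tmp.name) if own_dir else Path(workdir)
    replicates = []
    try:
        for seed in seeds:
            sim = _dc.replace(sim_template, seed=int(seed))
            replicates.append(run_replicate(sim, n_events, workdir, config))
    finally:
        if tmp is not None:
            tmp.cleanup()

    all_gammas = []
    for _, _, results in replicates:
        for gr in results:
            all_gammas.extend(g for g in gr.gamma.values() if np.isfinite(g))

    agg = {"tp": 0, "true": 0, "fp": 0, "null": 0, "bp_ok": 0}
    gamma_rows = []
    per_replicate = []
    for catalog, truth, results in replicates:
        own = [g for gr in results for g in gr.gamma.values() if np.isfinite(g)]
        extra = list(all_gammas)
        for g in own:
            extra.remove(g)
        callres = finalize_calls(results, config, extra_gammas=extra)
        calls = filtered_calls(callres)
        metrics = evaluate_calls(truth, calls, [e.id for e in catalog.events])
        per_replicate.append(metrics)
        truth_by_id = {r["event_id"]: r for r in truth.rows}
        agg["true"] += metrics["n_true"]
        agg["null"] += metrics["n_null"]
        agg["fp"] += metrics["n_false_positive"]
        tp = round(metrics["sensitivity"] * metrics["n_true"])
        agg["tp"] += tp
        if tp and metrics["breakpoint_accuracy"] == metrics["breakpoint_accuracy"]:
            agg["bp_ok"] += round(metrics["breakpoint_accuracy"] * tp)
        for gr in results:
            for eid, g in gr.gamma.items():
                row = truth_by_id.get(eid)
                gamma_rows.append({
                    "event_id": eid, "gamma": g, "seed": catalog.events[0].chrom,
                    "truth_outcome": row["outcome"] if row else "none",
                })
    return {
        "sensitivity": agg["tp"] / agg["true"] if agg["true"] else float("nan"),
        "specificity": (agg["null"] - agg["fp"]) / agg["null"] if agg["null"] else float("nan"),
        "breakpoint_accuracy": agg["bp_ok"] / agg["tp"] if agg["tp"] else float("nan"),
        "n_true": agg["true"], "n_null": agg["null"], "n_false_positive": agg["fp"],
        "n_recovered": agg["tp"],
        "per_replicate": per_replicate,
        "gamma_rows": gamma_rows,
    }
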