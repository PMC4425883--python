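"""Shared fixtures: toy repeat pairs, a small end-to-end replicate, and the
session-scoped scaled-down simulation study used by the acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from nahrcall.catalog import (
    LCRInterval,
    PotentialEvent,
    align_pair,
    build_catalog,
    classify_outcomes,
    vps_from_alignment,
)

STUDY_SEEDS = (17, 18, 19, 20, 21)


def make_reference(seq_a: str, seq_b: str, z: str = None, flank: str = None,
                   chrom: str = "chrT", rng_seed: int = 0):
    """Assemble flank + A + Z + B + flank and the matching event."""
    rng = np.random.default_rng(rng_seed)
    bases = np.array(list("ACGT"))
    if z is None:
        z = "".join(rng.choice(bases, 60))
    if flank is None:
        flank = "".join(rng.choice(bases, 80))
    genome = flank + seq_a + z + seq_b + flank
    a = LCRInterval(chrom, len(flank), len(flank) + len(seq_a), "A")
    b_start = len(flank) + len(seq_a) + len(z)
    b = LCRInterval(chrom, b_start, b_start + len(seq_b), "B")
    event = PotentialEvent("E1", a, b, "positive", 0.95)
    event.seq_a, event.seq_b = seq_a, seq_b
    if seq_a == seq_b:
        event.aln_a, event.aln_b = seq_a, seq_b
        event.vps = []
    else:
        event.aln_a, event.aln_b = align_pair(seq_a, seq_b)
        event.vps = vps_from_alignment(event.aln_a, event.aln_b)
    event.allowed_outcomes = classify_outcomes(event)
    return {chrom: genome}, event


def random_snp_pair(rng: np.random.Generator, length: int = 60, n_vps: int = 4):
    """A gap-free toy repeat pair differing at n_vps SNP positions."""
    bases = "ACGT"
    a = "".join(rng.choice(list(bases), length))
    pos = np.sort(rng.choice(np.arange(2, length - 2), size=n_vps, replace=False))
    b = list(a)
    for p in pos:
        b[p] = bases[(bases.index(b[p]) + int(rng.integers(1, 4))) % 4]
    return a, "".join(b), pos


@pytest.fixture(scope="session")
def toy_catalog():
    rng = np.random.default_rng(7)
    seq_a, seq_b, _ = random_snp_pair(rng, length=80, n_vps=3)
    reference, event = make_reference(seq_a, seq_b, rng_seed=7)
    return reference, build_catalog([event])


@pytest.fixture(scope="session")
def sim_study(tmp_path_factory):
    """The scaled-down simulation study: 5 seeded replicates of a ~2 Mb
    genome with 30 positively oriented ~97%-identity pairs, 5 planted
    one-copy events each, 15x reads, fdr-filtered calls."""
    from nahrcall.simulate import simulation_study

    workdir = tmp_path_factory.mktemp("study")
    return simulation_study(seeds=STUDY_SEEDS, n_events=5, workdir=workdir)


@pytest.fixture(scope="session")
def mini_replicate(tmp_path_factory):
    """One small end-to-end replicate (6 loci) for pipeline-level tests."""
    from nahrcall import io as nio
    from nahrcall.simulate import (
        SimConfig,
        catalog_from_simulation,
        make_genome,
        plant_events,
        simulate_reads,
    )

    workdir = tmp_path_factory.mktemp("mini")
    sim = SimConfig(n_pairs=6, lcr_length=(1000, 1200), inter_lcr=(4000, 6000),
                    spacing=(12000, 18000), flank=8000, seed=3)
    reference, rows = make_genome(sim)
    catalog = catalog_from_simulation(reference, rows)
    haplotypes, truth = plant_events(reference, catalog, 2, seed=3)
    repeat_iv = sorted([(e.lcr_a.start, e.lcr_a.end) for e in catalog.events]
                       + [(e.lcr_b.start, e.lcr_b.end) for e in catalog.events])
    res = simulate_reads(haplotypes, sim, workdir / "mini", repeat_intervals=repeat_iv,
                         reference_lengths={sim.chrom: len(reference[sim.chrom])})
    bam = nio.sam_to_indexed_bam(res["truth_sam"])
    return {"sim": sim, "reference": reference, "catalog": catalog,
            "truth": truth, "bam": bam, "fastq": (res["fastq1"], res["fastq2"]),
            "n_fragments": res["n_fragments"], "workdir": workdir}
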