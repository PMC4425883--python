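"""Standard-format I/O: FASTA/FASTQ, SAM/BAM conversion, segdup and gene
tables, catalog serialization, call tables (TSV and VCF-like), depth tracks.

All on-disk coordinates are 1-based inclusive; conversion happens here.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CALLS_COLUMNS = [
    "event_id", "chrom", "outcome", "multiplicity", "breakpoint_index",
    "bp_region_a_start", "bp_region_a_end", "bp_region_b_start", "bp_region_b_end",
    "posterior", "gamma", "fdr", "log_odds",
    "n_hybrid_reads", "n_discordant_reads", "pass_fdr", "high_conf_breakpoint", "flags",
]
CALLS_VERSION = "nahrcall_calls_v1"


# --- FASTA / FASTQ ---------------------------------------------------------

def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads, path) -> None:
    """reads: iterable of (name, seq, qual_string)."""
    with open(path, "w") as fh:
        fh.write("".join(f"@{n}\n{s}\n+\n{q}\n" for n, s, q in reads))


# --- SAM / BAM -------------------------------------------------------------

def sam_to_indexed_bam(sam_path, bam_path=None) -> str:
    """Coordinate-sort a SAM into an indexed BAM (pysam)."""
    import pysam

    sam_path = str(sam_path)
    bam_path = str(bam_path or (sam_path[: -4] + ".bam" if sam_path.endswith(".sam")
                                else sam_path + ".bam"))
    pysam.sort("-o", bam_path, sam_path)
    pysam.index(bam_path)
    return bam_path


# --- segdup pair table -----------------------------------------------------

def write_segdup_table(rows, path) -> None:
    """rows: iterable of (chromA, startA, endA, chromB, startB, endB, strand,
    identity) with 0-based half-open coordinates; written 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("#chromA\tstartA\tendA\tchromB\tstartB\tendB\tstrand\tidentity\n")
        for ca, sa, ea, cb, sb, eb, strand, ident in rows:
            fh.write(f"{ca}\t{sa + 1}\t{ea}\t{cb}\t{sb + 1}\t{eb}\t{strand}\t{ident:.4f}\n")


# --- catalog dump / load ---------------------------------------------------

def save_catalog(catalog, prefix) -> None:
    """Serialize events, VPs, classes, and groups as tab-separated files."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ev_rows, vp_rows = [], []
    for e in catalog.events:
        ev_rows.append({
            "event_id": e.id,
            "chromA": e.lcr_a.chrom, "startA": e.lcr_a.start + 1, "endA": e.lcr_a.end,
            "chromB": e.lcr_b.chrom, "startB": e.lcr_b.start + 1, "endB": e.lcr_b.end,
            "orientation": e.orientation, "identity": e.identity,
            "n_vps": e.n_vps, "outcomes": ",".join(sorted(e.allowed_outcomes)),
            "flags": ",".join(e.flags),
        })
        for i, vp in enumerate(e.vps):
            pos_a, pos_b = e.vp_ref_positions(i)
            vp_rows.append({
                "event_id": e.id, "vp_index": i, "column": vp.column,
                "column_end": vp.column_end, "pos_a": pos_a + 1, "pos_b": pos_b + 1,
                "allele_a": vp.allele_a or "-", "allele_b": vp.allele_b or "-",
                "kind": vp.kind,
            })
    pd.DataFrame(ev_rows).to_csv(f"{prefix}.events.tsv", sep="\t", index=False)
    pd.DataFrame(vp_rows).to_csv(f"{prefix}.vps.tsv", sep="\t", index=False)
    cls_rows = [{
        "class_id": c.id, "copy_number_null": c.copy_number_null,
        "members": ";".join(f"{m.chrom}:{m.start + 1}-{m.end}" for m in c.members),
    } for c in catalog.classes]
    pd.DataFrame(cls_rows).to_csv(f"{prefix}.classes.tsv", sep="\t", index=False)
    grp_rows = [{
        "group_id": g.id, "events": ";".join(e.id for e in g.events),
        "exclusive_pairs": ";".join("|".join(sorted(p)) for p in sorted(
            g.exclusivity_pairs, key=lambda p: sorted(p))),
        "classes": ";".join(c.id for c in g.classes),
    } for g in catalog.groups]
    pd.DataFrame(grp_rows).to_csv(f"{prefix}.groups.tsv", sep="\t", index=False)


# --- calls -----------------------------------------------------------------

def calls_to_frame(calls) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "event_id": c.event_id, "chrom": c.chrom, "outcome": c.outcome,
            "multiplicity": c.multiplicity,
            "breakpoint_index": (c.breakpoint_index if not isinstance(c.breakpoint_index, tuple)
                                 else f"{c.breakpoint_index[0]}-{c.breakpoint_index[1]}"),
            "bp_region_a_start": c.breakpoint_region_a[0],
            "bp_region_a_end": c.breakpoint_region_a[1],
            "bp_region_b_start": c.breakpoint_region_b[0],
            "bp_region_b_end": c.breakpoint_region_b[1],
            "posterior": c.posterior, "gamma": c.gamma, "fdr": c.fdr,
            "log_odds": c.log_odds, "n_hybrid_reads": c.n_hybrid_reads,
            "n_discordant_reads": c.n_discordant_reads,
            "pass_fdr": c.pass_fdr, "high_conf_breakpoint": c.high_conf_breakpoint,
            "flags": ",".join(c.flags),
        })
    return pd.DataFrame(rows, columns=CALLS_COLUMNS)


def write_calls_tsv(calls, path) -> None:
    frame = calls_to_frame(calls)
    with open(path, "w") as fh:
        fh.write(f"#{CALLS_VERSION}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_calls_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", header=0,
                       names=CALLS_COLUMNS, skiprows=1)


def write_calls_vcf(calls, path, reference_name: str = "reference") -> None:
    """Minimal VCF-style records: SVTYPE=DEL/DUP with END and the breakpoint
    region in INFO; positions 1-based."""
    svtype = {"deletion": "DEL", "duplication": "DUP"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=nahrcall\n##reference={reference_name}\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=BPREGION,Number=.,Type=String,Description="Breakpoint region on each LCR (1-based inclusive)">\n')
        fh.write('##INFO=<ID=MULT,Number=1,Type=Integer,Description="Event multiplicity">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            if c.outcome not in svtype:
                continue
            pos = c.breakpoint_region_a[0]
            end = c.breakpoint_region_b[1]
            filt = "PASS" if c.pass_fdr else "fdr"
            info = (f"SVTYPE={svtype[c.outcome]};END={end};MULT={c.multiplicity};"
                    f"BPREGION={c.breakpoint_region_a[0]}-{c.breakpoint_region_a[1]},"
                    f"{c.breakpoint_region_b[0]}-{c.breakpoint_region_b[1]}")
            fh.write(f"{c.chrom}\t{pos}\t{c.event_id}\t.\t<{svtype[c.outcome]}>\t.\t{filt}\t{info}\n")


# --- gene table ------------------------------------------------------------

def read_gene_table(path) -> list[dict]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: gene rows need "
                                 "gene_id, chrom, start, end, type")
            gid, chrom, start, end, gtype = parts[:5]
            if gtype not in ("gene", "pseudogene"):
                raise ValueError(f"{path}:{lineno}: bad gene type {gtype!r}")
            genes.append({"gene_id": gid, "chrom": chrom,
                          "start": int(start) - 1, "end": int(end), "type": gtype})
    return genes


# --- depth track -----------------------------------------------------------

def write_depth_track(rows, path) -> None:
    """BED-graph-style track: chrom, start, end (1-based inclusive out),
    observed, expected_null, expected_alt per window."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tobserved\texpected_null\texpected_alt\n")
        for chrom, start, end, obs, en, ea in rows:
            fh.write(f"{chrom}\t{start + 1}\t{end}\t{obs:.2f}\t{en:.2f}\t{ea:.2f}\n")
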