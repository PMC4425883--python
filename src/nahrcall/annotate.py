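"""Gene-impact annotation of NAHR calls.

A deletion or duplication whose affected interval contains a gene deletes
or duplicates it outright; a breakpoint falling inside a gene creates a
fusion gene; a gene containing both mediating repeats is contracted by a
deletion or expanded by a duplication; a gene lying on a repeat outside the
breakpoint region is unaffected by the rearrangement.
"""

from __future__ import annotations

from dataclasses import dataclass

from nahrcall.catalog import PotentialEvent
from nahrcall.inference import EventCall


@dataclass(frozen=True)
class GeneImpact:
    gene_id: str
    gene_type: str  # gene | pseudogene
    impact: str     # fusion | deleted | duplicated | expanded | contracted | unaffected_on_lcr


def classify_gene_impact(call: EventCall, event: PotentialEvent, genes) -> list[GeneImpact]:
    """Impact labels for every gene overlapping the call's locus.

    ``genes``: iterable of dicts with gene_id, chrom, start, end (0-based
    half-open), type in {gene, pseudogene}.
    """
    if call.outcome not in ("deletion", "duplication"):
        return []
    impacts: list[GeneImpact] = []
    a, b = event.lcr_a, event.lcr_b
    locus_start, locus_end = event.locus_span()
    # breakpoint regions in 0-based half-open
    bp_a = (call.breakpoint_region_a[0] - 1, call.breakpoint_region_a[1])
    bp_b = (call.breakpoint_region_b[0] - 1, call.breakpoint_region_b[1])
    for g in genes:
        if g["chrom"] != event.chrom:
            continue
        gs, ge = g["start"], g["end"]
        if ge <= locus_start or gs >= locus_end:
            continue
        if not ("gene_id" in g and "type" in g):
            raise ValueError(f"malformed gene row: {g}")
        label = None
        overlaps_bp = (gs < bp_a[1] and bp_a[0] < ge) or (gs < bp_b[1] and bp_b[0] < ge)
        contains_both_lcrs = gs <= a.start and ge >= b.end
        inside_affected = gs >= a.start and ge <= b.end
        between_lcrs = gs >= a.end and ge <= b.start
        on_lcr = (gs < a.end and a.start < ge) or (gs < b.end and b.start < ge)
        if contains_both_lcrs:
            # the whole rearranged unit is internal to the gene
            label = "expanded" if call.outcome == "duplication" else "contracted"
        elif overlaps_bp:
            label = "fusion"
        elif between_lcrs or inside_affected and not on_lcr:
            label = "deleted" if call.outcome == "deletion" else "duplicated"
        elif on_lcr:
            label = "unaffected_on_lcr"
        if label:
            impacts.append(GeneImpact(g["gene_id"], g["type"], label))
    return impacts
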