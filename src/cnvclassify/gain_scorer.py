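"""Scoring algorithm for copy-number gains (duplications).

Sections 1, 3 and 4 are shared with the loss scorer (gains use their own
gene-count bins and match population gains only).  Section 2 applies the
gain-specific rules: complete/partial overlap of established triplosensitive
features, comparison against established benign-gain regions by *gene
content* rather than coordinates, a 0-point note when an established
haploinsufficient gene is fully duplicated, and breakpoint criteria for
duplication endpoints falling inside genes.

Breakpoint criteria (2I/2J/2L) are only resolved with precise breakpoints;
for imprecise calls a partially duplicated established HI gene falls back to
the conservative 0-point 2J and ordinary-gene breakpoints are not called.
"""

from __future__ import annotations

import logging
from typing import List, Optional

from .annotation_db import (
    AnnotationBundle,
    DosageRecord,
    benign_gain_regions,
    established_hi_features,
    established_ts_features,
)
from .intervals import (
    BreakpointLocation,
    GenomicInterval,
    breakpoints_within,
    fully_contains,
    overlap_length,
)
from .loss_scorer import (
    CnvCall,
    EvidenceItem,
    _item,
    _overlapping,
    score_section1,
    score_section3,
    score_section4_frequency,
)
from .rubric_config import Rubric

logger = logging.getLogger(__name__)

__all__ = ["score_section2_gain", "score_gain"]


def _coding_gene_set(bundle: AnnotationBundle, interval: GenomicInterval) -> frozenset:
    return frozenset(
        g.symbol for g, _ in bundle.gene_index.query(interval) if g.is_protein_coding
    )


def _breakpoint_interrupts_coding_gene(cnv: CnvCall, bundle: AnnotationBundle) -> bool:
    for gene, _ in bundle.gene_index.query(cnv.location):
        if not gene.is_protein_coding:
            continue
        if breakpoints_within(cnv.location, gene.location) is not BreakpointLocation.NONE:
            return True
    return False


def _benign_gain_comparison(
    cnv: CnvCall, bundle: AnnotationBundle, region: DosageRecord
) -> str:
    """Classify the CNV against one established benign-gain region.

    Returns the criterion id: identical gene content -> 2C; smaller than the
    region -> 2D (breakpoints clear of protein-coding genes) or 2E
    (potentially interrupting one); larger without additional protein-coding
    genes -> 2F; any other overlap -> 2G (additional genomic material).
    """
    cnv_genes = _coding_gene_set(bundle, cnv.location)
    region_genes = _coding_gene_set(bundle, region.location)
    if cnv_genes and cnv_genes == region_genes:
        return "2C"
    if fully_contains(region.location, cnv.location):
        if _breakpoint_interrupts_coding_gene(cnv, bundle):
            return "2E"
        return "2D"
    if fully_contains(cnv.location, region.location) and cnv_genes <= region_genes:
        return "2F"
    return "2G"


def score_section2_gain(
    cnv: CnvCall, bundle: AnnotationBundle, rubric: Rubric
) -> List[EvidenceItem]:
    """Section 2 of the gain rubric, in fixed criterion order (2A..2L)."""
    items: List[EvidenceItem] = []

    ts_hits = _overlapping(cnv, established_ts_features(bundle))
    contained = [d for d in ts_hits if fully_contains(cnv.location, d.location)]
    if contained:
        items.append(_item(rubric, "gain", "2A", [d.name for d in contained],
                           "established TS gene(s)/region(s) completely contained"))
    partial_regions = [d for d in ts_hits if d not in contained and d.scope == "region"]
    if partial_regions:
        items.append(_item(rubric, "gain", "2B", [d.name for d in partial_regions],
                           "partial overlap of established TS region(s)"))

    # Benign-gain comparison: evaluate every overlapping benign region, keep
    # the single most benign (lowest-scoring) outcome.
    best: Optional[EvidenceItem] = None
    for region in _overlapping(cnv, benign_gain_regions(bundle)):
        cid = _benign_gain_comparison(cnv, bundle, region)
        candidate = _item(rubric, "gain", cid, [region.name])
        logger.info("%s: benign-gain region %s -> %s", cnv.variant_id, region.name, cid)
        if best is None or candidate.points < best.points:
            best = candidate
    if best is not None:
        items.append(best)

    hi_genes = [d for d in established_hi_features(bundle) if d.scope == "gene"]
    hi_hits = _overlapping(cnv, hi_genes)
    hi_contained = [d for d in hi_hits if fully_contains(cnv.location, d.location)]
    if hi_contained:
        items.append(_item(rubric, "gain", "2H", [d.name for d in hi_contained],
                           "established HI gene(s) fully contained in the duplication"))

    items.extend(_breakpoint_family(cnv, bundle, rubric, hi_hits, hi_contained))
    return items


def _breakpoint_family(
    cnv: CnvCall,
    bundle: AnnotationBundle,
    rubric: Rubric,
    hi_hits: List[DosageRecord],
    hi_contained: List[DosageRecord],
) -> List[EvidenceItem]:
    """The 2I/2J/2L duplication-breakpoint criteria (single item at most)."""
    hi_partial = [d for d in hi_hits if d not in hi_contained]
    if not cnv.precise_breakpoints:
        if hi_partial:
            # Imprecise coordinates: geometry distinctions are unreliable, use
            # the conservative 0-point member of the family.
            return [_item(rubric, "gain", "2J", [d.name for d in hi_partial],
                          "established HI gene partially duplicated; imprecise "
                          "breakpoints, conservative call")]
        return []
    both, one = [], []
    for record in hi_partial:
        span = bundle.genes_by_symbol.get(record.name)
        span = span.location if span is not None else record.location
        geometry = breakpoints_within(cnv.location, span)
        if geometry is BreakpointLocation.BOTH:
            both.append(record)
        elif geometry is not BreakpointLocation.NONE:
            one.append(record)
    if both:
        return [_item(rubric, "gain", "2I", [d.name for d in both],
                      "both breakpoints within the same established HI gene")]
    if one:
        return [_item(rubric, "gain", "2J", [d.name for d in one],
                      "one breakpoint within an established HI gene; phenotype "
                      "consequence unknown")]
    ordinary = sorted(
        g.symbol
        for g, _ in bundle.gene_index.query(cnv.location)
        if g.is_protein_coding
        and breakpoints_within(cnv.location, g.location) is not BreakpointLocation.NONE
    )
    if ordinary:
        return [_item(rubric, "gain", "2L", ordinary,
                      "breakpoint(s) within gene(s) of no established dosage sensitivity")]
    return []


def score_gain(cnv: CnvCall, bundle: AnnotationBundle, rubric: Rubric) -> List[EvidenceItem]:
    """Evaluate all four rubric sections for a duplication, in rubric order."""
    if cnv.cnv_type != "gain":
        raise ValueError(f"{cnv.variant_id}: score_gain requires a gain, got {cnv.cnv_type}")
    evidence = [score_section1(cnv, bundle, rubric)]
    evidence.extend(score_section2_gain(cnv, bundle, rubric))
    evidence.append(score_section3(cnv, bundle, rubric))
    freq = score_section4_frequency(cnv, bundle, rubric)
    if freq is not None:
        evidence.append(freq)
    return evidence
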