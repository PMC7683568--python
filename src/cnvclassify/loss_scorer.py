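"""Scoring algorithm for copy-number losses (deletions).

The rubric is walked section by section and every section is always
evaluated, even after a benign or pathogenic total is already inevitable:

* Section 1 — genomic content: does the CNV overlap (>= 1 bp) any gene,
  protein-coding or noncoding, or any enhancer/promoter?
* Section 2 — established dosage-sensitive features (haploinsufficient
  genes and regions, curation score 3), established benign-loss regions,
  partial-overlap breakpoint geometry, and predicted haploinsufficiency.
* Section 3 — protein-coding gene count, binned.
* Section 4 — population frequency of similar variants: only evaluated for
  CNVs that overlap no established dosage-sensitive gene or region; a
  population CNV of the same type must cover >= 80 % of the query, and the
  mean frequency of all matches must exceed 1 % to call the variant common.

Section 1, 3 and 4 are shared verbatim with the gain scorer.

Partial overlaps of established haploinsufficient genes are resolved by
breakpoint geometry, strand-aware: the 5' end of a minus-strand gene is its
higher-coordinate edge.  With imprecise breakpoints the fine sub-criteria
(which exon/UTR an endpoint falls in) are downgraded to their conservative
0-point family member; full-containment criteria still fire.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal
from fractions import Fraction
from typing import List, Optional, Sequence, Tuple

from .annotation_db import (
    AnnotationBundle,
    DosageRecord,
    GeneRecord,
    benign_loss_regions,
    established_hi_features,
    established_ts_features,
    predicted_hi_genes,
)
from .intervals import (
    BreakpointLocation,
    GenomicInterval,
    breakpoints_within,
    fully_contains,
    overlap_length,
    query_coverage_fraction,
)
from .rubric_config import Rubric

logger = logging.getLogger(__name__)

__all__ = [
    "CnvCall",
    "EvidenceItem",
    "score_section1",
    "score_section2_loss",
    "score_section3",
    "score_section4_frequency",
    "score_loss",
    "overlaps_established_dosage_feature",
]

#: CNVs are conventionally defined as > 50 bp; shorter calls are warned about.
MIN_CNV_LENGTH = 50


@dataclass(frozen=True)
class CnvCall:
    """One query variant: location, type (loss/gain), breakpoint precision."""

    variant_id: str
    location: GenomicInterval
    cnv_type: str  # loss | gain
    precise_breakpoints: bool = True

    def __post_init__(self) -> None:
        if self.cnv_type not in ("loss", "gain"):
            raise ValueError(f"bad cnv_type {self.cnv_type!r}")
        if self.location.length <= MIN_CNV_LENGTH:
            logger.warning(
                "%s: length %d bp is at or below the conventional %d bp CNV "
                "minimum; scoring anyway",
                self.variant_id, self.location.length, MIN_CNV_LENGTH,
            )


@dataclass(frozen=True)
class EvidenceItem:
    """One fired rubric criterion: id, configured points, supporting features."""

    criterion_id: str
    points: Decimal
    supporting_features: Tuple[str, ...] = ()
    note: str = ""


def _item(rubric: Rubric, cnv_type: str, cid: str, features: Sequence[str] = (),
          note: str = "") -> EvidenceItem:
    return EvidenceItem(
        criterion_id=cid,
        points=rubric.points(cnv_type, cid),
        supporting_features=tuple(features),
        note=note,
    )


# ---------------------------------------------------------------------------
# Section 1 — genomic content (shared by losses and gains)


def score_section1(cnv: CnvCall, bundle: AnnotationBundle, rubric: Rubric) -> EvidenceItem:
    """1A (0) if any gene or regulatory element overlaps by >= 1 bp, else 1B (-0.60)."""
    gene_hits = bundle.gene_index.query(cnv.location)
    reg_hits = bundle.regulatory_index.query(cnv.location)
    if gene_hits or reg_hits:
        features = [g.symbol for g, _ in gene_hits] + [r.element_id for r, _ in reg_hits]
        return _item(rubric, cnv.cnv_type, "1A", features)
    return _item(rubric, cnv.cnv_type, "1B",
                 note="no genes or known functionally important elements overlapped")


# ---------------------------------------------------------------------------
# Section 2 — dosage-sensitive and benign features (loss rules)


def _overlapping(cnv: CnvCall, records: Sequence[DosageRecord]) -> List[DosageRecord]:
    hits = [d for d in records if overlap_length(cnv.location, d.location) >= 1]
    hits.sort(key=lambda d: (d.location.start, d.location.end, d.name))
    return hits


def _coding_exon_spans(gene: GeneRecord) -> List[GenomicInterval]:
    """Exon intervals clipped to the CDS, in genomic order."""
    spans = []
    for exon in gene.exons:
        if gene.cds is None:
            break
        start = max(exon.start, gene.cds.start)
        end = min(exon.end, gene.cds.end)
        if end > start:
            spans.append(GenomicInterval(exon.chrom, start, end))
    return spans


def _five_prime_removed(gene: GeneRecord, geometry: BreakpointLocation) -> bool:
    """Did the CNV remove the transcription-start end of the gene?

    ``RIGHT_ONLY`` geometry means the CNV removes the gene's low-coordinate
    edge, which is the 5' end for a plus-strand gene and the 3' end for a
    minus-strand gene.
    """
    low_side_removed = geometry is BreakpointLocation.RIGHT_ONLY
    return low_side_removed == (gene.strand == "+")


def _last_exon(gene: GeneRecord) -> GenomicInterval:
    """The transcriptionally last exon (highest coordinate on +, lowest on -)."""
    return gene.exons[-1] if gene.strand == "+" else gene.exons[0]


def _partial_hi_gene_subcriterion(
    cnv: CnvCall, gene: Optional[GeneRecord], record: DosageRecord
) -> Tuple[str, str]:
    """Choose the 2C/2D/2E sub-criterion for one partially deleted HI gene.

    Returns (criterion_id, note).  Falls back to the conservative 0-point
    member of the family whenever the decision cannot be made: unknown gene
    structure, or imprecise breakpoints.
    """
    span = gene.location if gene is not None else record.location
    geometry = breakpoints_within(cnv.location, span)
    if geometry is BreakpointLocation.BOTH:
        return "2E", f"both breakpoints within {record.name}"
    if geometry is BreakpointLocation.NONE:
        # Partial overlap always puts one endpoint strictly inside the span;
        # reaching here means record/gene spans disagree.  Be conservative.
        logger.warning("%s: inconsistent breakpoint geometry for %s",
                       cnv.variant_id, record.name)
        return "2E", f"ambiguous breakpoint geometry for {record.name}"
    if gene is None:
        logger.warning(
            "%s: no gene model for established HI gene %s; using conservative "
            "0-point sub-criterion", cnv.variant_id, record.name,
        )
        return "2C-2", f"gene model for {record.name} unavailable; conservative call"

    overlap_start = max(cnv.location.start, span.start)
    overlap_end = min(cnv.location.end, span.end)
    removed = GenomicInterval(span.chrom, overlap_start, overlap_end)

    if _five_prime_removed(gene, geometry):
        if not cnv.precise_breakpoints:
            return "2C-2", f"5' end of {record.name} removed; imprecise breakpoints, conservative call"
        if gene.cds is None:
            logger.warning("%s: %s lacks CDS annotation; conservative 5' call",
                           cnv.variant_id, record.name)
            return "2C-2", f"{record.name} lacks CDS annotation; conservative call"
        if overlap_length(removed, gene.cds) >= 1:
            return "2C-1", f"5' end of {record.name} removed, coding sequence involved"
        return "2C-2", f"5' end of {record.name} removed, only the 5' UTR involved"

    # 3' end removed
    if not cnv.precise_breakpoints:
        return "2D-1", f"3' end of {record.name} removed; imprecise breakpoints, conservative call"
    if gene.cds is None or not gene.exons:
        logger.warning("%s: %s lacks exon/CDS annotation; conservative 3' call",
                       cnv.variant_id, record.name)
        return "2D-1", f"{record.name} lacks exon/CDS annotation; conservative call"
    coding = _coding_exon_spans(gene)
    affected = [span_ for span_ in coding if overlap_length(span_, removed) >= 1]
    if not affected:
        return "2D-1", f"3' end of {record.name} removed, only the 3' UTR involved"
    last = _last_exon(gene)
    only_last = all(
        span_.start >= last.start and span_.end <= last.end for span_ in affected
    )
    if only_last:
        if gene.last_exon_pathogenic:
            return "2D-2", (f"only the last exon of {record.name} involved; "
                            "established pathogenic variants in this exon")
        return "2D-3", (f"only the last exon of {record.name} involved; "
                        "no established pathogenic variants in this exon")
    return "2D-4", f"coding exons of {record.name} in addition to the last exon involved"


def score_section2_loss(
    cnv: CnvCall, bundle: AnnotationBundle, rubric: Rubric
) -> List[EvidenceItem]:
    """Section 2 of the loss rubric, in fixed criterion order.

    Emits 2A for complete overlap of established HI features, 2B for a
    partially overlapped HI *region*, the single highest-scoring 2C/2D/2E
    sub-criterion across partially overlapped HI *genes*, 2F/2G for benign
    loss regions, and 2H when no established HI feature overlaps but
    haploinsufficiency is predicted for an overlapped gene.
    """
    items: List[EvidenceItem] = []
    hi_hits = _overlapping(cnv, established_hi_features(bundle))

    contained = [d for d in hi_hits if fully_contains(cnv.location, d.location)]
    if contained:
        items.append(_item(rubric, "loss", "2A", [d.name for d in contained],
                           "established HI gene(s)/region(s) completely contained"))
    partial = [d for d in hi_hits if d not in contained]
    partial_regions = [d for d in partial if d.scope == "region"]
    if partial_regions:
        items.append(_item(rubric, "loss", "2B", [d.name for d in partial_regions],
                           "partial overlap of established HI region(s)"))

    best: Optional[EvidenceItem] = None
    for record in partial:
        if record.scope != "gene":
            continue
        gene = bundle.genes_by_symbol.get(record.name)
        cid, note = _partial_hi_gene_subcriterion(cnv, gene, record)
        candidate = _item(rubric, "loss", cid, [record.name], note)
        logger.info("%s: partial HI gene %s -> %s", cnv.variant_id, record.name, cid)
        if best is None or candidate.points > best.points:
            best = candidate
    if best is not None:
        items.append(best)

    benign_hits = _overlapping(cnv, benign_loss_regions(bundle))
    containing = [d for d in benign_hits if fully_contains(d.location, cnv.location)]
    if containing:
        items.append(_item(rubric, "loss", "2F", [d.name for d in containing],
                           "completely contained within an established benign loss region"))
    elif benign_hits:
        items.append(_item(rubric, "loss", "2G", [d.name for d in benign_hits],
                           "overlaps a benign loss region but includes additional genomic material"))

    if not hi_hits:
        overlapped_genes = [g for g, _ in bundle.gene_index.query(cnv.location)]
        predicted = predicted_hi_genes(bundle, overlapped_genes)
        if predicted:
            items.append(_item(rubric, "loss", "2H", [g.symbol for g in predicted],
                               "haploinsufficiency predicted (HI index, pLI, LOEUF)"))
    return items


# ---------------------------------------------------------------------------
# Section 3 — protein-coding gene count (shared)


def score_section3(cnv: CnvCall, bundle: AnnotationBundle, rubric: Rubric) -> EvidenceItem:
    """Count protein-coding genes overlapped >= 1 bp; map through the type's bins."""
    coding = [
        g for g, _ in bundle.gene_index.query(cnv.location) if g.is_protein_coding
    ]
    cid = rubric.gene_count_criterion(cnv.cnv_type, len(coding))
    return _item(rubric, cnv.cnv_type, cid, [g.symbol for g in coding],
                 f"{len(coding)} protein-coding gene(s) overlapped")


# ---------------------------------------------------------------------------
# Section 4 — population frequency (shared)


def overlaps_established_dosage_feature(cnv: CnvCall, bundle: AnnotationBundle) -> bool:
    """Does the CNV overlap any established (score 3) HI or TS gene/region?"""
    for record in established_hi_features(bundle) + established_ts_features(bundle):
        if overlap_length(cnv.location, record.location) >= 1:
            return True
    return False


def score_section4_frequency(
    cnv: CnvCall, bundle: AnnotationBundle, rubric: Rubric
) -> Optional[EvidenceItem]:
    """4O (-1.00) when matching population CNVs show the variant is common.

    Only evaluated for CNVs with no established dosage-sensitive overlap.
    A population CNV matches if it is of the same type (loss/gain) and
    covers at least ``min_coverage`` of the query length; the arithmetic
    mean frequency of all matches must strictly exceed ``common_frequency``.
    All comparisons are exact (rational arithmetic).
    """
    if overlaps_established_dosage_feature(cnv, bundle):
        return None
    min_cov = Fraction(rubric.population.min_coverage)
    matches = []
    for record, _bp in bundle.population_index.query(cnv.location):
        if record.cnv_type != cnv.cnv_type:
            continue
        if query_coverage_fraction(cnv.location, record.location) >= min_cov:
            matches.append(record)
    if not matches:
        return None
    mean = sum(Fraction(m.frequency) for m in matches) / len(matches)
    if mean > Fraction(rubric.population.common_frequency):
        features = [
            f"{m.source}:{m.location}:{m.frequency}" for m in matches
        ]
        return _item(rubric, cnv.cnv_type, "4O", features,
                     f"mean population frequency {float(mean):.4g} exceeds threshold")
    return None


# ---------------------------------------------------------------------------
# Full loss walk


def score_loss(cnv: CnvCall, bundle: AnnotationBundle, rubric: Rubric) -> List[EvidenceItem]:
    """Evaluate all four rubric sections for a deletion, in rubric order."""
    if cnv.cnv_type != "loss":
        raise ValueError(f"{cnv.variant_id}: score_loss requires a loss, got {cnv.cnv_type}")
    evidence = [score_section1(cnv, bundle, rubric)]
    evidence.extend(score_section2_loss(cnv, bundle, rubric))
    evidence.append(score_section3(cnv, bundle, rubric))
    freq = score_section4_frequency(cnv, bundle, rubric)
    if freq is not None:
        evidence.append(freq)
    return evidence
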