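"""Totaling of evidence points and the five-tier clinical classification.

Scores are exact decimals throughout (two decimal places cover every rubric
value), so repeated additions of 0.15/0.45/0.90 can never drift across a
0.01-wide band edge the way binary floating point would.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from enum import IntEnum
from typing import Iterable, List, Sequence, Tuple

from .annotation_db import AnnotationBundle, predicted_hi_genes
from .gain_scorer import score_gain
from .loss_scorer import (
    CnvCall,
    EvidenceItem,
    overlaps_established_dosage_feature,  # noqa: F401  (re-exported convenience)
    score_loss,
)
from .rubric_config import ClassificationThresholds, Rubric

__all__ = [
    "Category",
    "ClassificationResult",
    "classify",
    "evaluate_cnv",
]


class Category(IntEnum):
    """Five-tier clinical classification, ordered from benign to pathogenic."""

    BENIGN = 0
    LIKELY_BENIGN = 1
    UNCERTAIN_SIGNIFICANCE = 2
    LIKELY_PATHOGENIC = 3
    PATHOGENIC = 4

    @property
    def label(self) -> str:
        return _LABELS[self]


_LABELS = {
    Category.BENIGN: "Benign",
    Category.LIKELY_BENIGN: "Likely benign",
    Category.UNCERTAIN_SIGNIFICANCE: "Uncertain significance",
    Category.LIKELY_PATHOGENIC: "Likely pathogenic",
    Category.PATHOGENIC: "Pathogenic",
}


@dataclass(frozen=True)
class ClassificationResult:
    """Full per-variant outcome: total, tier, evidence breakdown, gene lists."""

    variant: CnvCall
    total_score: Decimal
    category: Category
    evidence: Tuple[EvidenceItem, ...]
    dosage_genes: Tuple[str, ...]  # established + predicted, labeled
    coding_genes: Tuple[str, ...]


def classify(
    evidence: Iterable[EvidenceItem], thresholds: ClassificationThresholds
) -> Tuple[Decimal, Category]:
    """Sum evidence points exactly and map the total onto the five tiers."""
    total = sum((item.points for item in evidence), Decimal("0.00"))
    if total >= thresholds.pathogenic_min:
        category = Category.PATHOGENIC
    elif total >= thresholds.likely_pathogenic_min:
        category = Category.LIKELY_PATHOGENIC
    elif total <= thresholds.benign_max:
        category = Category.BENIGN
    elif total <= thresholds.likely_benign_max:
        category = Category.LIKELY_BENIGN
    else:
        category = Category.UNCERTAIN_SIGNIFICANCE
    return total, category


def _dosage_gene_labels(
    cnv: CnvCall, bundle: AnnotationBundle
) -> Tuple[List[str], List[str]]:
    """Established (labeled HI/TS) and predicted dosage-sensitive gene lists."""
    from .intervals import overlap_length  # local to avoid cycle at import time

    established = []
    for record in sorted(bundle.dosage, key=lambda d: (d.location.start, d.name)):
        if overlap_length(cnv.location, record.location) < 1:
            continue
        tags = []
        if record.established_hi:
            tags.append("HI")
        if record.established_ts:
            tags.append("TS")
        if tags:
            established.append(f"{record.name}({'/'.join(tags)})")
    overlapped = [g for g, _ in bundle.gene_index.query(cnv.location)]
    predicted = [g.symbol for g in predicted_hi_genes(bundle, overlapped)]
    return established, predicted


def evaluate_cnv(cnv: CnvCall, bundle: AnnotationBundle, rubric: Rubric) -> ClassificationResult:
    """Run the type-appropriate scorer and assemble the full result."""
    if cnv.cnv_type == "loss":
        evidence = score_loss(cnv, bundle, rubric)
    else:
        evidence = score_gain(cnv, bundle, rubric)
    total, category = classify(evidence, rubric.thresholds)
    established, predicted = _dosage_gene_labels(cnv, bundle)
    coding = tuple(
        g.symbol for g, _ in bundle.gene_index.query(cnv.location) if g.is_protein_coding
    )
    dosage = tuple(established + [f"{s}(predicted HI)" for s in predicted])
    return ClassificationResult(
        variant=cnv,
        total_score=total,
        category=category,
        evidence=tuple(evidence),
        dosage_genes=dosage,
        coding_genes=coding,
    )
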