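"""Synthetic annotation bundles and hand-scored CNV test sets.

This module makes the whole pipeline testable without any database
download.  It emits two things:

* a miniature annotation bundle (all five database files) whose chr1 carries
  one engineered scenario per 1-Mb block — an established HI gene here, a
  benign region there, population CNVs straddling the 80 %-coverage and
  1 %-frequency boundaries — plus seeded random filler features on chr2 with
  plausible exon structures;
* a scored test set: one CNV per scenario together with the expected
  evidence list, total and category, derived BY HAND from the scoring
  rubrics at authoring time and stored as literal data.  The expectations
  are never produced by calling the scorers, so comparing pipeline output
  against them is a true oracle test, not a regression snapshot.

Each scenario's ``note`` field records the worked derivation.  Scenario
coordinates are fixed; only the chr2 filler depends on the seed, and it can
never interact with chr1 scenarios.  Output files are byte-identical for a
fixed spec (canonical sorting, seeded randomness).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .annotation_db import (
    AnnotationBundle,
    DosageRecord,
    GenePredictionScores,
    GeneRecord,
    PopulationCnv,
    RegulatoryElement,
    write_bundle,
)
from .intervals import GenomicInterval

__all__ = [
    "FixtureError",
    "FixtureSpec",
    "Scenario",
    "build_bundle",
    "generate_bundle",
    "scenario_table",
    "generate_scored_testset",
    "ALL_SCENARIO_TAGS",
]

BLOCK = 1_000_000  # one scenario per block on chr1

# Standard test-gene layout: 10 kb span, 5 exons, CDS from +500 to +9500.
# 5' UTR is the first 500 bp (plus strand); 3' UTR the last 500 bp.
GENE_LEN = 10_000
EXON_OFFSETS = ((0, 1_000), (2_000, 3_000), (4_000, 5_000), (6_000, 7_000), (9_000, 10_000))
CDS_OFFSET = (500, 9_500)

FILLER_CHROM = "chr2"


class FixtureError(ValueError):
    """Raised for an infeasible fixture specification."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic bundle.

    The chr1 scenario blocks are fixed; the counts below control only the
    random filler on chr2.  ``scenarios`` selects a subset of scenario tags
    (empty tuple = all); selected scenarios keep their canonical block
    coordinates.
    """

    seed: int = 1
    n_genes: int = 40
    n_enhancers: int = 10
    n_dosage_records: int = 6
    n_population_cnvs: int = 15
    chrom_length: int = 50_000_000
    scenarios: Tuple[str, ...] = ()


@dataclass(frozen=True)
class Scenario:
    """One engineered CNV with its hand-derived expected classification."""

    tag: str
    chrom: str
    start: int
    end: int
    cnv_type: str  # loss | gain
    precise: bool
    expected_evidence: Tuple[Tuple[str, Decimal], ...]
    expected_total: Decimal
    expected_category: str
    note: str

    @property
    def variant_id(self) -> str:
        suffix = "DEL" if self.cnv_type == "loss" else "DUP"
        return f"{self.chrom}_{self.start}_{self.end}_{suffix}"


class _Registry:
    def __init__(self) -> None:
        self.genes: List[GeneRecord] = []
        self.regulatory: List[RegulatoryElement] = []
        self.dosage: List[DosageRecord] = []
        self.predictions: List[GenePredictionScores] = []
        self.population: List[PopulationCnv] = []
        self.scenarios: List[Scenario] = []


def _std_gene(symbol: str, start: int, strand: str = "+", coding: bool = True,
              last_exon_pathogenic: bool = False, chrom: str = "chr1") -> GeneRecord:
    exons = tuple(
        GenomicInterval(chrom, start + a, start + b) for a, b in EXON_OFFSETS
    )
    cds = (
        GenomicInterval(chrom, start + CDS_OFFSET[0], start + CDS_OFFSET[1])
        if coding else None
    )
    return GeneRecord(
        symbol=symbol,
        location=GenomicInterval(chrom, start, start + GENE_LEN),
        strand=strand,
        is_protein_coding=coding,
        exons=exons,
        cds=cds,
        last_exon_pathogenic=last_exon_pathogenic,
    )


def _dosage_gene(gene: GeneRecord, hi: int = 0, ts: int = 0) -> DosageRecord:
    return DosageRecord(name=gene.symbol, scope="gene", location=gene.location,
                        hi_score=hi, ts_score=ts)


def _region(name: str, start: int, end: int, hi: int = 0, ts: int = 0,
            chrom: str = "chr1") -> DosageRecord:
    return DosageRecord(name=name, scope="region",
                        location=GenomicInterval(chrom, start, end),
                        hi_score=hi, ts_score=ts)


def _ev(*pairs: Tuple[str, str]) -> Tuple[Tuple[str, Decimal], ...]:
    return tuple((cid, Decimal(pts)) for cid, pts in pairs)


_CATEGORY_FROM_TOTAL = None  # categories are written literally per scenario


def _build_scenario_registry() -> _Registry:  # noqa: C901 - a data table, not logic
    reg = _Registry()
    n = [0]  # scenario counter -> block base

    def scn(tag, start_off, end_off, cnv_type, evidence, total, category, note,
            precise=True, base=None):
        if base is None:
            base = n[0] * BLOCK
        reg.scenarios.append(Scenario(
            tag=tag, chrom="chr1", start=base + start_off, end=base + end_off,
            cnv_type=cnv_type, precise=precise,
            expected_evidence=_ev(*evidence),
            expected_total=Decimal(total), expected_category=category, note=note,
        ))
        return base

    def next_block() -> int:
        n[0] += 1
        return n[0] * BLOCK

    # ------------------------------------------------------------------ S01
    b = next_block()
    scn("gene-desert-del", 400_000, 450_000, "loss",
        [("1B", "-0.60"), ("3A", "0.00")], "-0.60", "Uncertain significance",
        "Feature desert: no genes or regulatory elements -> 1B; 0 coding genes "
        "-> 3A; no population match. Total -0.60.")

    # ------------------------------------------------------------------ S02
    b = next_block()
    scn("gene-desert-dup", 400_000, 450_000, "gain",
        [("1B", "-0.60"), ("3A", "0.00")], "-0.60", "Uncertain significance",
        "Same desert logic on the gain rubric. Total -0.60.")

    # ------------------------------------------------------------------ S03
    b = next_block()
    g = _std_gene("HIG3", b + 500_000)
    reg.genes.append(g)
    reg.dosage.append(_dosage_gene(g, hi=3))
    scn("hi-gene-contained", 480_000, 530_000, "loss",
        [("1A", "0.00"), ("2A", "1.00"), ("3A", "0.00")], "1.00", "Pathogenic",
        "Deletion fully contains established HI gene HIG3 -> 2A +1.00; gene "
        "overlap -> 1A; 1 coding gene -> 3A; frequency section gated by the "
        "dosage overlap. Total 1.00.")

    # ------------------------------------------------------------------ S04
    b = next_block()
    g = _std_gene("RG4", b + 535_000)
    reg.genes.append(g)
    reg.dosage.append(_region("HIR4", b + 450_000, b + 550_000, hi=3))
    scn("hi-region-partial", 540_000, 560_000, "loss",
        [("1A", "0.00"), ("2B", "0.00"), ("3A", "0.00")], "0.00",
        "Uncertain significance",
        "Deletion overlaps 10 kb of established HI region HIR4 without "
        "containing it -> 2B 0; overlaps gene RG4 -> 1A; 1 coding gene -> 3A; "
        "frequency gated. Total 0.00.")

    # ------------------------------------------------------------------ S05
    b = next_block()
    g = _std_gene("HIG5", b + 500_000)
    reg.genes.append(g)
    reg.dosage.append(_dosage_gene(g, hi=3))
    # Predictors pass for HIG5, but 2H must stay silent: an established HI
    # feature overlaps the deletion.
    reg.predictions.append(GenePredictionScores("HIG5", Decimal("3"), Decimal("0.99"), Decimal("0.10")))
    scn("hi-5prime-cds", 495_000, 502_500, "loss",
        [("1A", "0.00"), ("2C-1", "0.90"), ("3A", "0.00")], "0.90",
        "Likely pathogenic",
        "Right breakpoint inside HIG5 (+ strand): 5' end removed; removed "
        "span 500000-502500 intersects the CDS (starts at +500) -> 2C-1 "
        "+0.90. Predicted-HI is suppressed by the established overlap. "
        "Total 0.90.")

    # ------------------------------------------------------------------ S06
    b = next_block()
    g = _std_gene("HIG6", b + 500_000)
    reg.genes.append(g)
    reg.dosage.append(_dosage_gene(g, hi=3))
    scn("hi-5prime-utr-only", 495_000, 500_300, "loss",
        [("1A", "0.00"), ("2C-2", "0.00"), ("3A", "0.00")], "0.00",
        "Uncertain significance",
        "Only the first 300 bp of HIG6 removed, all 5' UTR (CDS starts at "
        "+500) -> 2C-2 0. Total 0.00.")

    # ------------------------------------------------------------------ S07
    b = next_block()
    g = _std_gene("HIG7", b + 500_000)
    reg.genes.append(g)
    reg.dosage.append(_dosage_gene(g, hi=3))
    scn("hi-3prime-utr-only", 509_600, 520_000, "loss",
        [("1A", "0.00"), ("2D-1", "0.00"), ("3A", "0.00")], "0.00",
        "Uncertain significance",
        "Left breakpoint at +9600, past the CDS end (+9500): only the 3' UTR "
        "removed -> 2D-1 0. Total 0.00.")

    # ------------------------------------------------------------------ S08
    b = next_block()
    g = _std_gene("HIG8", b + 500_000, last_exon_pathogenic=True)
    reg.genes.append(g)
    reg.dosage.append(_dosage_gene(g, hi=3))
    scn("hi-lastexon-pathogenic", 508_000, 520_000, "loss",
        [("1A", "0.00"), ("2D-2", "0.90"), ("3A", "0.00")], "0.90",
        "Likely pathogenic",
        "Breakpoint at +8000, in the intron before the last exon: only the "
        "last exon's coding bases (+9000..+9500) removed; pathogenic variants "
        "curated in that exon -> 2D-2 +0.90. Total 0.90.")

    # ------------------------------------------------------------------ S09
    b = next_block()
    g = _std_gene("HIG9", b + 500_000)
    reg.genes.append(g)
    reg.dosage.append(_dosage_gene(g, hi=3))
    scn("hi-lastexon-benignexon", 508_000, 520_000, "loss",
        [("1A", "0.00"), ("2D-3", "0.30"), ("3A", "0.00")], "0.30",
        "Uncertain significance",
        "Same geometry as the previous scenario but no curated pathogenic "
        "variants in the last exon -> 2D-3 +0.30. Total 0.30.")

    # ------------------------------------------------------------------ S10
    b = next_block()
    g = _std_gene("HIG10", b + 500_000)
    reg.genes.append(g)
    reg.dosage.append(_dosage_gene(g, hi=3))
    scn("hi-3prime-multiexon", 506_500, 520_000, "loss",
        [("1A", "0.00"), ("2D-4", "0.90"), ("3A", "0.00")], "0.90",
        "Likely pathogenic",
        "Breakpoint at +6500 removes part of coding exon 4 (+6000..+7000) and "
        "all of the last exon -> other exons in addition to the last -> 2D-4 "
        "+0.90. Total 0.90.")

    # ------------------------------------------------------------------ S11
    b = next_block()
    g = _std_gene("HIG11", b + 500_000)
    reg.genes.append(g)
    reg.dosage.append(_dosage_gene(g, hi=3))
    scn("hi-intragenic", 502_500, 508_500, "loss",
        [("1A", "0.00"), ("2E", "0.00"), ("3A", "0.00")], "0.00",
        "Uncertain significance",
        "Both breakpoints strictly inside HIG11 -> intragenic deletion 2E; "
        "frame consequence unknowable from coordinates, conservative 0. "
        "Total 0.00.")

    # ------------------------------------------------------------------ S12
    b = next_block()
    g = _std_gene("HIG12", b + 500_000, strand="-")
    reg.genes.append(g)
    reg.dosage.append(_dosage_gene(g, hi=3))
    scn("hi-5prime-minus-strand", 507_500, 520_000, "loss",
        [("1A", "0.00"), ("2C-1", "0.90"), ("3A", "0.00")], "0.90",
        "Likely pathogenic",
        "HIG12 is on the minus strand, so its 5' end is the high-coordinate "
        "edge; removing +7500..+10000 takes 5' UTR plus CDS (ends +9500) -> "
        "2C-1 +0.90. Total 0.90.")

    # ------------------------------------------------------------------ S13
    b = next_block()
    g = _std_gene("BG13", b + 500_000)
    reg.genes.append(g)
    reg.dosage.append(_region("BLR13", b + 450_000, b + 560_000, hi=40))
    scn("benign-region", 495_000, 515_000, "loss",
        [("1A", "0.00"), ("2F", "-1.00"), ("3A", "0.00")], "-1.00", "Benign",
        "Deletion completely contained in established benign-loss region "
        "BLR13 (hi_score 40) -> 2F -1.00; overlaps gene BG13 -> 1A. The "
        "benign region is not dosage sensitive, so the frequency section "
        "runs, but no population CNVs are present. Total -1.00.")

    # ------------------------------------------------------------------ S14
    b = next_block()
    reg.genes.append(_std_gene("BG14A", b + 500_000))
    reg.genes.append(_std_gene("BG14B", b + 530_000))
    reg.dosage.append(_region("BLR14", b + 450_000, b + 520_000, hi=40))
    scn("benign-region-extra-material", 495_000, 545_000, "loss",
        [("1A", "0.00"), ("2G", "0.00"), ("3A", "0.00")], "0.00",
        "Uncertain significance",
        "Deletion overlaps benign-loss region BLR14 but extends 25 kb beyond "
        "it, picking up gene BG14B -> additional genomic material -> 2G 0. "
        "Total 0.00.")

    # ------------------------------------------------------------------ S15
    b = next_block()
    g = _std_gene("PHI15", b + 500_000)
    reg.genes.append(g)
    reg.predictions.append(GenePredictionScores("PHI15", Decimal("4"), Decimal("0.97"), Decimal("0.20")))
    scn("predicted-hi", 495_000, 525_000, "loss",
        [("1A", "0.00"), ("2H", "0.15"), ("3A", "0.00")], "0.15",
        "Uncertain significance",
        "No established dosage features; PHI15 passes all three predictor "
        "gates (HI index 4 <= 10, pLI 0.97 >= 0.9, LOEUF 0.20 < 0.35) -> 2H "
        "+0.15 (once, regardless of gene count). Total 0.15.")

    # ------------------------------------------------------------------ S16
    b = next_block()
    for k in range(25):
        reg.genes.append(_std_gene(f"C16G{k:02d}", b + 400_000 + k * 12_000))
    scn("25-gene-cluster", 395_000, 700_000, "loss",
        [("1A", "0.00"), ("3B", "0.45"), ], "0.45", "Uncertain significance",
        "Deletion spans exactly 25 protein-coding genes and nothing else -> "
        "loss bin 25-34 -> 3B +0.45. Total 0.45.")

    # ------------------------------------------------------------------ S17
    b = next_block()
    for k in range(35):
        reg.genes.append(_std_gene(f"C17G{k:02d}", b + 400_000 + k * 12_000))
    scn("35-gene-cluster", 395_000, 820_000, "loss",
        [("1A", "0.00"), ("3C", "0.90"), ], "0.90", "Likely pathogenic",
        "35 protein-coding genes -> loss bin >= 35 -> 3C +0.90. Total 0.90.")

    # ------------------------------------------------------------------ S18
    b = next_block()
    reg.genes.append(_std_gene("CV18", b + 500_000))
    reg.population.append(PopulationCnv(GenomicInterval("chr1", b + 490_000, b + 530_000),
                                        "loss", Decimal("0.02"), "dgv-like"))
    reg.population.append(PopulationCnv(GenomicInterval("chr1", b + 490_000, b + 530_000),
                                        "loss", Decimal("0.01"), "gnomad-like"))
    scn("common-variant", 495_000, 525_000, "loss",
        [("1A", "0.00"), ("3A", "0.00"), ("4O", "-1.00")], "-1.00", "Benign",
        "Two population losses each cover 100 % of the query; mean frequency "
        "(0.02 + 0.01)/2 = 0.015 > 1 % -> 4O -1.00. Total -1.00.")

    # ------------------------------------------------------------------ S19
    b = next_block()
    reg.genes.append(_std_gene("CV19", b + 500_000))
    reg.population.append(PopulationCnv(GenomicInterval("chr1", b + 490_000, b + 530_000),
                                        "loss", Decimal("0.01"), "dgv-like"))
    scn("frequency-boundary", 495_000, 525_000, "loss",
        [("1A", "0.00"), ("3A", "0.00")], "0.00", "Uncertain significance",
        "Single matching population loss at frequency exactly 0.01: the "
        "common-variant rule is strict (> 1 %), so 4O does not fire. "
        "Total 0.00.")

    # ------------------------------------------------------------------ S20
    b = next_block()
    reg.genes.append(_std_gene("CV20", b + 500_000))
    reg.population.append(PopulationCnv(GenomicInterval("chr1", b + 500_000, b + 579_900),
                                        "loss", Decimal("0.05"), "dgv-like"))
    scn("coverage-below-80", 500_000, 600_000, "loss",
        [("1A", "0.00"), ("3A", "0.00")], "0.00", "Uncertain significance",
        "Population loss covers 79 900 of the 100 000 bp query = 79.9 % < "
        "80 %: not a match, 4O silent despite frequency 5 %. Total 0.00.")

    # ------------------------------------------------------------------ S21
    b = next_block()
    reg.genes.append(_std_gene("CV21", b + 500_000))
    reg.population.append(PopulationCnv(GenomicInterval("chr1", b + 500_000, b + 580_000),
                                        "loss", Decimal("0.05"), "dgv-like"))
    scn("coverage-exactly-80", 500_000, 600_000, "loss",
        [("1A", "0.00"), ("3A", "0.00"), ("4O", "-1.00")], "-1.00", "Benign",
        "Coverage exactly 80 000/100 000 = 80 %: the coverage rule is "
        "inclusive, frequency 5 % > 1 % -> 4O -1.00. Total -1.00.")

    # ------------------------------------------------------------------ S22
    b = next_block()
    reg.population.append(PopulationCnv(GenomicInterval("chr1", b + 400_000, b + 460_000),
                                        "loss", Decimal("0.05"), "gnomad-like"))
    scn("desert-common-variant", 410_000, 450_000, "loss",
        [("1B", "-0.60"), ("3A", "0.00"), ("4O", "-1.00")], "-1.60", "Benign",
        "Feature desert (1B -0.60) fully covered by a 5 % population loss "
        "(4O -1.00). Total -1.60.")

    # ------------------------------------------------------------------ S23 (+ S25 below, same block)
    b = next_block()
    g = _std_gene("TG23", b + 500_000)
    reg.genes.append(g)
    reg.dosage.append(_region("TSR23", b + 495_000, b + 515_000, ts=3))
    scn("ts-region-contained", 490_000, 520_000, "gain",
        [("1A", "0.00"), ("2A", "1.00"), ("3A", "0.00")], "1.00", "Pathogenic",
        "Duplication fully contains established TS region TSR23 -> gain 2A "
        "+1.00; gene overlap -> 1A. Total 1.00.")
    # S25: deletion with identical coordinates in the same block.  The TS
    # region means nothing to the loss rubric, so the call is uncertain —
    # the type-sensitivity check.
    scn("ts-region-del-same-coords", 490_000, 520_000, "loss",
        [("1A", "0.00"), ("3A", "0.00")], "0.00", "Uncertain significance",
        "Deletion of the same interval: triplosensitivity does not apply to "
        "losses and TSR23 is not haploinsufficient -> only 1A and 3A. "
        "Frequency gated by the established TS overlap. Total 0.00.",
        base=b)

    # ------------------------------------------------------------------ S24
    b = next_block()
    reg.genes.append(_std_gene("TG24", b + 545_000))
    reg.dosage.append(_region("TSR24", b + 450_000, b + 550_000, ts=3))
    scn("ts-region-partial", 540_000, 560_000, "gain",
        [("1A", "0.00"), ("2B", "0.00"), ("3A", "0.00")], "0.00",
        "Uncertain significance",
        "Duplication overlaps 10 kb of TS region TSR24 without containing it "
        "-> gain 2B 0; contains gene TG24 -> 1A. Total 0.00.")

    # ------------------------------------------------------------------ S26
    b = next_block()
    g = _std_gene("BGG26", b + 500_000)
    reg.genes.append(g)
    reg.dosage.append(_region("BGR26", b + 495_000, b + 515_000, ts=40))
    scn("benign-gain-identical-content", 493_000, 517_000, "gain",
        [("1A", "0.00"), ("2C", "-1.00"), ("3A", "0.00")], "-1.00", "Benign",
        "Duplication and benign-gain region BGR26 overlap the same single "
        "protein-coding gene BGG26 -> identical gene content -> gain 2C "
        "-1.00. Total -1.00.")

    # ------------------------------------------------------------------ S27
    b = next_block()
    reg.genes.append(_std_gene("BGG27", b + 500_000))
    reg.regulatory.append(RegulatoryElement("ENH27", "enhancer",
                                            GenomicInterval("chr1", b + 525_000, b + 530_000)))
    reg.dosage.append(_region("BGR27", b + 450_000, b + 550_000, ts=40))
    scn("benign-gain-smaller-clear", 520_000, 540_000, "gain",
        [("1A", "0.00"), ("2D", "-1.00"), ("3A", "0.00")], "-1.00", "Benign",
        "Duplication lies inside benign-gain region BGR27, overlaps no gene "
        "(gene content differs from the region's) and neither breakpoint "
        "touches a protein-coding gene -> gain 2D -1.00; the contained "
        "enhancer gives 1A. Total -1.00.")

    # ------------------------------------------------------------------ S28
    b = next_block()
    reg.genes.append(_std_gene("BGG28", b + 500_000))
    reg.genes.append(_std_gene("BGG28B", b + 535_000))
    reg.dosage.append(_region("BGR28", b + 450_000, b + 550_000, ts=40))
    scn("benign-gain-smaller-interrupt", 505_000, 530_000, "gain",
        [("1A", "0.00"), ("2E", "0.00"), ("2L", "0.00"), ("3A", "0.00")],
        "0.00", "Uncertain significance",
        "Duplication inside BGR28 with its left breakpoint at +5000 inside "
        "gene BGG28: smaller than the region but potentially interrupting a "
        "protein-coding gene -> gain 2E 0; the same breakpoint also fires 2L "
        "(gene of no established dosage sensitivity). Total 0.00.")

    # ------------------------------------------------------------------ S29
    b = next_block()
    reg.regulatory.append(RegulatoryElement("ENH29", "enhancer",
                                            GenomicInterval("chr1", b + 498_000, b + 502_000)))
    reg.dosage.append(_region("BGR29", b + 495_000, b + 505_000, ts=40))
    scn("benign-gain-larger-no-genes", 490_000, 510_000, "gain",
        [("1A", "0.00"), ("2F", "-1.00"), ("3A", "0.00")], "-1.00", "Benign",
        "Duplication strictly contains gene-free benign-gain region BGR29 and "
        "adds no protein-coding genes -> gain 2F -1.00; the enhancer inside "
        "gives 1A. Total -1.00.")

    # ------------------------------------------------------------------ S30
    b = next_block()
    reg.genes.append(_std_gene("BGG30A", b + 500_000))
    reg.genes.append(_std_gene("BGG30B", b + 560_000))
    reg.dosage.append(_region("BGR30", b + 450_000, b + 550_000, ts=40))
    scn("benign-gain-larger-extra-genes", 440_000, 575_000, "gain",
        [("1A", "0.00"), ("2G", "0.00"), ("3A", "0.00")], "0.00",
        "Uncertain significance",
        "Duplication contains benign-gain region BGR30 but also gene BGG30B "
        "outside it -> additional genomic material -> gain 2G 0. Total 0.00.")

    # ------------------------------------------------------------------ S31
    b = next_block()
    g = _std_gene("HIG31", b + 500_000)
    reg.genes.append(g)
    reg.dosage.append(_dosage_gene(g, hi=3))
    scn("gain-hi-gene-contained", 490_000, 530_000, "gain",
        [("1A", "0.00"), ("2H", "0.00"), ("3A", "0.00")], "0.00",
        "Uncertain significance",
        "Established HI gene HIG31 fully contained in the duplication -> gain "
        "2H 0 (dosage increase of an HI gene is not deletion evidence); "
        "frequency gated. Total 0.00.")

    # ------------------------------------------------------------------ S32
    b = next_block()
    g = _std_gene("HIG32", b + 500_000)
    reg.genes.append(g)
    reg.dosage.append(_dosage_gene(g, hi=3))
    scn("gain-breakpoint-in-hi-gene", 505_000, 550_000, "gain",
        [("1A", "0.00"), ("2J", "0.00"), ("3A", "0.00")], "0.00",
        "Uncertain significance",
        "One duplication breakpoint (+5000) strictly inside established HI "
        "gene HIG32 -> gain 2J 0 (phenotype consequence unknown). Total 0.00.")

    # ------------------------------------------------------------------ S33
    b = next_block()
    g = _std_gene("HIG33", b + 500_000)
    reg.genes.append(g)
    reg.dosage.append(_dosage_gene(g, hi=3))
    scn("gain-intragenic-hi-gene", 502_000, 508_000, "gain",
        [("1A", "0.00"), ("2I", "0.00"), ("3A", "0.00")], "0.00",
        "Uncertain significance",
        "Both duplication breakpoints inside established HI gene HIG33 -> "
        "gain 2I; conservative 0 (frame consequence unknown). Total 0.00.")

    # ------------------------------------------------------------------ S34
    b = next_block()
    reg.genes.append(_std_gene("OG34", b + 500_000))
    scn("gain-breakpoint-in-ordinary-gene", 505_000, 550_000, "gain",
        [("1A", "0.00"), ("2L", "0.00"), ("3A", "0.00")], "0.00",
        "Uncertain significance",
        "One breakpoint inside protein-coding gene OG34, which has no "
        "established dosage sensitivity -> gain 2L 0. Total 0.00.")

    # ------------------------------------------------------------------ S35
    b = next_block()
    for k in range(35):
        reg.genes.append(_std_gene(f"C35G{k:02d}", b + 400_000 + k * 12_000))
    scn("gain-35-genes", 395_000, 820_000, "gain",
        [("1A", "0.00"), ("3B", "0.45")], "0.45", "Uncertain significance",
        "35 protein-coding genes duplicated -> gain bin 35-49 -> 3B +0.45. "
        "Total 0.45.")

    # ------------------------------------------------------------------ S36
    b = next_block()
    for k in range(50):
        reg.genes.append(_std_gene(f"C36G{k:02d}", b + 400_000 + k * 12_000))
    scn("gain-50-genes", 395_000, 999_000, "gain",
        [("1A", "0.00"), ("3C", "0.90")], "0.90", "Likely pathogenic",
        "50 protein-coding genes duplicated -> gain bin >= 50 -> 3C +0.90. "
        "Total 0.90.")

    # ------------------------------------------------------------------ S37/S38 (same block)
    b = next_block()
    for k in range(30):
        reg.genes.append(_std_gene(f"C37G{k:02d}", b + 400_000 + k * 12_000))
    scn("30-genes-gain-bin", 395_000, 760_000, "gain",
        [("1A", "0.00"), ("3A", "0.00")], "0.00", "Uncertain significance",
        "30 protein-coding genes: below the 35-gene gain threshold -> 3A 0. "
        "Total 0.00.")
    scn("30-genes-loss-bin", 395_000, 760_000, "loss",
        [("1A", "0.00"), ("3B", "0.45")], "0.45", "Uncertain significance",
        "The same 30 genes deleted land in the 25-34 loss bin -> 3B +0.45 — "
        "the bins are type-specific. Total 0.45.",
        base=b)

    # ------------------------------------------------------------------ S39
    b = next_block()
    reg.population.append(PopulationCnv(GenomicInterval("chr1", b + 400_000, b + 460_000),
                                        "gain", Decimal("0.004"), "gnomad-like"))
    reg.population.append(PopulationCnv(GenomicInterval("chr1", b + 400_000, b + 460_000),
                                        "loss", Decimal("0.05"), "gnomad-like"))
    scn("gain-frequency-type-match", 410_000, 450_000, "gain",
        [("1B", "-0.60"), ("3A", "0.00")], "-0.60", "Uncertain significance",
        "Only same-type population CNVs count: the 5 % record is a loss, the "
        "matching gain is at 0.4 % <= 1 % -> no 4O. Total -0.60.")

    # ------------------------------------------------------------------ S40
    b = next_block()
    reg.population.append(PopulationCnv(GenomicInterval("chr1", b + 400_000, b + 460_000),
                                        "gain", Decimal("0.03"), "dgv-like"))
    scn("gain-common-variant", 410_000, 450_000, "gain",
        [("1B", "-0.60"), ("3A", "0.00"), ("4O", "-1.00")], "-1.60", "Benign",
        "Desert duplication fully covered by a 3 % population gain -> 1B and "
        "4O. Total -1.60.")

    # ------------------------------------------------------------------ S41
    b = next_block()
    g = _std_gene("HIG41", b + 500_000)
    reg.genes.append(g)
    reg.dosage.append(_dosage_gene(g, hi=3))
    scn("imprecise-5prime", 495_000, 502_500, "loss",
        [("1A", "0.00"), ("2C-2", "0.00"), ("3A", "0.00")], "0.00",
        "Uncertain significance",
        "Same geometry as the precise 5'-CDS scenario, but breakpoints are "
        "imprecise: the CDS/UTR distinction is not trusted and the "
        "conservative 2C-2 (0) is used instead of 2C-1. Total 0.00.",
        precise=False)

    # ------------------------------------------------------------------ S42
    b = next_block()
    reg.regulatory.append(RegulatoryElement("ENH42", "enhancer",
                                            GenomicInterval("chr1", b + 500_000, b + 501_000)))
    reg.regulatory.append(RegulatoryElement("PROM42", "promoter",
                                            GenomicInterval("chr1", b + 501_500, b + 502_000)))
    scn("regulatory-only", 499_000, 502_500, "loss",
        [("1A", "0.00"), ("3A", "0.00")], "0.00", "Uncertain significance",
        "Deletion overlaps an enhancer and a promoter but no genes: 1A fires "
        "on regulatory content alone; 0 coding genes -> 3A. Total 0.00.")

    # ------------------------------------------------------------------ S43
    b = next_block()
    reg.genes.append(_std_gene("NCG43", b + 500_000, coding=False))
    scn("noncoding-1bp-overlap", 490_000, 500_001, "loss",
        [("1A", "0.00"), ("3A", "0.00")], "0.00", "Uncertain significance",
        "Exactly 1 bp of noncoding gene NCG43 overlapped: the >= 1 bp content "
        "rule fires 1A; the coding-gene count stays 0 -> 3A. Total 0.00.")

    # ------------------------------------------------------------------ S44
    b = next_block()
    g = _std_gene("HIG44", b + 500_000)
    reg.genes.append(g)
    reg.dosage.append(_dosage_gene(g, hi=3))
    scn("imprecise-3prime", 508_000, 520_000, "loss",
        [("1A", "0.00"), ("2D-1", "0.00"), ("3A", "0.00")], "0.00",
        "Uncertain significance",
        "3'-end removal with imprecise breakpoints: exon-level distinctions "
        "are not trusted, conservative 2D-1 (0) instead of 2D-2/3/4. "
        "Total 0.00.", precise=False)

    # ------------------------------------------------------------------ S45
    b = next_block()
    g = _std_gene("HIG45", b + 500_000)
    reg.genes.append(g)
    reg.dosage.append(_dosage_gene(g, hi=3))
    scn("imprecise-hi-contained", 480_000, 530_000, "loss",
        [("1A", "0.00"), ("2A", "1.00"), ("3A", "0.00")], "1.00", "Pathogenic",
        "Imprecise breakpoints do not demote full containment: HIG45 lies "
        "20 kb clear of both ends -> 2A +1.00 still fires. Total 1.00.",
        precise=False)

    return reg


_FULL_REGISTRY: Optional[_Registry] = None


def _full_registry() -> _Registry:
    global _FULL_REGISTRY
    if _FULL_REGISTRY is None:
        _FULL_REGISTRY = _build_scenario_registry()
    return _FULL_REGISTRY


ALL_SCENARIO_TAGS: Tuple[str, ...] = tuple(
    s.tag for s in _full_registry().scenarios
)


def _validate_spec(spec: FixtureSpec) -> None:
    needed = (len(_full_registry().scenarios) + 2) * BLOCK
    if spec.chrom_length < needed:
        raise FixtureError(
            f"chrom_length {spec.chrom_length} cannot hold the scenario blocks "
            f"(need >= {needed})"
        )
    for name in ("n_genes", "n_enhancers", "n_dosage_records", "n_population_cnvs"):
        if getattr(spec, name) < 0:
            raise FixtureError(f"{name} must be non-negative")
    unknown = set(spec.scenarios) - set(ALL_SCENARIO_TAGS)
    if unknown:
        raise FixtureError(f"unknown scenario tags: {sorted(unknown)}")


def _filler_gene(rng: random.Random, symbol: str, start: int) -> GeneRecord:
    """A random but invariant-respecting gene model on the filler chromosome."""
    length = rng.randrange(8_000, 12_001, 500)
    n_exons = rng.randint(2, 10)
    pitch = length // n_exons
    exon_len = max(1, pitch // 2)
    exons = tuple(
        GenomicInterval(FILLER_CHROM, start + k * pitch, start + k * pitch + exon_len)
        for k in range(n_exons)
    )
    coding = rng.random() < 0.8
    cds = None
    if coding:
        cds = GenomicInterval(FILLER_CHROM, exons[0].start + exon_len // 2,
                              exons[-1].end - exon_len // 4)
    return GeneRecord(
        symbol=symbol,
        location=GenomicInterval(FILLER_CHROM, start, start + length),
        strand=rng.choice("+-"),
        is_protein_coding=coding,
        exons=exons,
        cds=cds,
    )


def _add_filler(reg_genes, reg_regulatory, reg_dosage, reg_predictions,
                reg_population, spec: FixtureSpec) -> None:
    rng = random.Random(spec.seed)
    fillers: List[GeneRecord] = []
    for k in range(spec.n_genes):
        gene = _filler_gene(rng, f"FIL{k:03d}", 100_000 + k * 25_000)
        fillers.append(gene)
        reg_genes.append(gene)
    for k in range(spec.n_enhancers):
        start = 100_000 + rng.randrange(0, max(1, spec.n_genes) * 25_000)
        kind = rng.choice(["enhancer", "promoter"])
        reg_regulatory.append(RegulatoryElement(
            f"FILREG{k:02d}", kind, GenomicInterval(FILLER_CHROM, start, start + rng.randint(500, 2_000))
        ))
    scores = [0, 1, 2, 30, 40]
    for k in range(min(spec.n_dosage_records, len(fillers))):
        gene = fillers[k]
        reg_dosage.append(DosageRecord(
            name=gene.symbol, scope="gene", location=gene.location,
            hi_score=rng.choice(scores), ts_score=rng.choice(scores),
        ))
    for k, gene in enumerate(fillers[: spec.n_genes // 3]):
        loeuf = None if k % 5 == 4 else Decimal(str(round(rng.uniform(0.2, 1.5), 3)))
        reg_predictions.append(GenePredictionScores(
            symbol=gene.symbol,
            hi_index=Decimal(str(round(rng.uniform(11, 95), 2))),
            pli=Decimal(str(round(rng.uniform(0.0, 0.85), 3))),
            loeuf_upper=loeuf,
        ))
    for k in range(spec.n_population_cnvs):
        start = 100_000 + rng.randrange(0, max(25_000, spec.n_genes * 25_000))
        length = rng.randrange(10_000, 80_000, 1_000)
        reg_population.append(PopulationCnv(
            location=GenomicInterval(FILLER_CHROM, start, start + length),
            cnv_type=rng.choice(["loss", "gain"]),
            frequency=Decimal(str(round(rng.uniform(0.0, 0.2), 4))),
            source=rng.choice(["dgv-like", "gnomad-like"]),
        ))


def _selected(spec: FixtureSpec) -> List[Scenario]:
    scenarios = _full_registry().scenarios
    if not spec.scenarios:
        return list(scenarios)
    wanted = set(spec.scenarios)
    return [s for s in scenarios if s.tag in wanted]


def build_bundle(spec: FixtureSpec, build: str = "GRCh38") -> AnnotationBundle:
    """Assemble the synthetic bundle in memory (scenario features + filler)."""
    _validate_spec(spec)
    full = _full_registry()
    genes = list(full.genes)
    regulatory = list(full.regulatory)
    dosage = list(full.dosage)
    predictions = list(full.predictions)
    population = list(full.population)
    _add_filler(genes, regulatory, dosage, predictions, population, spec)
    return AnnotationBundle(
        build=build,
        genes=genes,
        regulatory=regulatory,
        dosage=dosage,
        predictions={p.symbol: p for p in predictions},
        population=population,
    )


def generate_bundle(spec: FixtureSpec, out_dir: "str | Path",
                    build: str = "GRCh38") -> Path:
    """Write all five database files under ``out_dir/<build>/``; deterministic."""
    bundle = build_bundle(spec, build=build)
    return write_bundle(bundle, out_dir)


def scenario_table(spec: FixtureSpec) -> List[Scenario]:
    """The selected scenarios with their hand-derived expectations."""
    _validate_spec(spec)
    return _selected(spec)


EXPECTED_HEADER = ("#variant_id\ttag\tchrom\tstart\tend\ttype\tprecise"
                   "\tevidence\ttotal\tcategory\tnote")


def generate_scored_testset(spec: FixtureSpec, out_dir: "str | Path") -> Dict[str, Path]:
    """Write the CNV inputs and the expected-results table.

    Returns paths for ``precise_bed``, ``imprecise_bed`` and ``expected``.
    Precision is a per-run flag in the command-line tool, so precise and
    imprecise scenarios go into separate BED files scored in two runs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenarios = scenario_table(spec)
    paths = {
        "precise_bed": out / "cnvs_precise.bed",
        "imprecise_bed": out / "cnvs_imprecise.bed",
        "expected": out / "expected_results.tsv",
    }
    with open(paths["precise_bed"], "w", encoding="utf-8") as precise_handle, \
            open(paths["imprecise_bed"], "w", encoding="utf-8") as imprecise_handle:
        for s in scenarios:
            token = "DEL" if s.cnv_type == "loss" else "DUP"
            handle = precise_handle if s.precise else imprecise_handle
            handle.write(f"{s.chrom}\t{s.start}\t{s.end}\t{token}\n")
    with open(paths["expected"], "w", encoding="utf-8") as handle:
        handle.write(EXPECTED_HEADER + "\n")
        for s in scenarios:
            evidence = ";".join(f"{cid}:{pts:.2f}" for cid, pts in s.expected_evidence)
            handle.write("\t".join([
                s.variant_id, s.tag, s.chrom, str(s.start), str(s.end),
                "DEL" if s.cnv_type == "loss" else "DUP",
                "1" if s.precise else "0",
                evidence, f"{s.expected_total:.2f}", s.expected_category,
                s.note,
            ]) + "\n")
    return paths
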