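"""Loss rubric logic on small hand-built bundles."""

from decimal import Decimal

import pytest

from cnvclassify.annotation_db import (
    AnnotationBundle,
    DosageRecord,
    GenePredictionScores,
    GeneRecord,
    PopulationCnv,
    RegulatoryElement,
)
from cnvclassify.intervals import GenomicInterval
from cnvclassify.loss_scorer import (
    CnvCall,
    score_loss,
    score_section1,
    score_section2_loss,
    score_section3,
    score_section4_frequency,
)


def gi(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


# A 10 kb test gene: 5 exons, CDS 500..9500 (5' UTR 0..500, 3' UTR 9500..10000).
def make_gene(symbol, start, strand="+", coding=True, last_exon_pathogenic=False):
    offs = [(0, 1000), (2000, 3000), (4000, 5000), (6000, 7000), (9000, 10000)]
    return GeneRecord(
        symbol, gi(start, start + 10_000), strand, coding,
        exons=tuple(gi(start + a, start + b) for a, b in offs),
        cds=gi(start + 500, start + 9_500) if coding else None,
        last_exon_pathogenic=last_exon_pathogenic,
    )


def make_bundle(genes=(), regulatory=(), dosage=(), predictions=(), population=()):
    return AnnotationBundle(
        build="GRCh38", genes=list(genes), regulatory=list(regulatory),
        dosage=list(dosage), predictions={p.symbol: p for p in predictions},
        population=list(population),
    )


def hi_gene(gene):
    return DosageRecord(gene.symbol, "gene", gene.location, 3, 0)


def loss(start, end, precise=True):
    return CnvCall(f"del_{start}_{end}", gi(start, end), "loss", precise)


def ids(items):
    return [item.criterion_id for item in items]


class TestSection1:
    def test_enhancer_only_fires_1a(self, rubric):
        bundle = make_bundle(regulatory=[
            RegulatoryElement("E1", "enhancer", gi(5_000, 6_000))])
        item = score_section1(loss(4_000, 7_000), bundle, rubric)
        assert item.criterion_id == "1A" and item.points == 0

    def test_feature_desert_fires_1b(self, rubric):
        item = score_section1(loss(4_000, 7_000), make_bundle(), rubric)
        assert item.criterion_id == "1B" and item.points == Decimal("-0.60")

    def test_single_bp_gene_overlap_suffices(self, rubric):
        bundle = make_bundle(genes=[make_gene("G", 10_000, coding=False)])
        assert score_section1(loss(5_000, 10_001), bundle, rubric).criterion_id == "1A"
        assert score_section1(loss(5_000, 10_000), bundle, rubric).criterion_id == "1B"


class TestSection2PartialGeometry:
    """2C/2D/2E selection by breakpoint position, strand and exon layout."""

    @pytest.mark.parametrize("start,end,strand,expected", [
        (95_000, 102_500, "+", "2C-1"),   # 5' removal hits CDS
        (95_000, 100_300, "+", "2C-2"),   # 5' UTR only
        (109_600, 120_000, "+", "2D-1"),  # 3' UTR only
        (108_000, 120_000, "+", "2D-3"),  # last exon only, no pathogenic variants
        (106_500, 120_000, "+", "2D-4"),  # exon 4 + last exon
        (102_500, 108_500, "+", "2E"),    # intragenic
        (107_500, 120_000, "-", "2C-1"),  # minus strand: high edge is 5'
        (95_000, 102_500, "-", "2D-4"),   # minus strand: low edge is 3'; exons 1-2 coding removed
    ])
    def test_subcriterion_selection(self, rubric, start, end, strand, expected):
        gene = make_gene("HI1", 100_000, strand=strand)
        bundle = make_bundle(genes=[gene], dosage=[hi_gene(gene)])
        items = score_section2_loss(loss(start, end), bundle, rubric)
        assert ids(items) == [expected]

    def test_last_exon_pathogenic_flag_upgrades(self, rubric):
        gene = make_gene("HI1", 100_000, last_exon_pathogenic=True)
        bundle = make_bundle(genes=[gene], dosage=[hi_gene(gene)])
        items = score_section2_loss(loss(108_000, 120_000), bundle, rubric)
        assert ids(items) == ["2D-2"]
        assert items[0].points == Decimal("0.90")

    def test_imprecise_breakpoints_downgrade_to_zero_point(self, rubric):
        gene = make_gene("HI1", 100_000)
        bundle = make_bundle(genes=[gene], dosage=[hi_gene(gene)])
        precise = score_section2_loss(loss(95_000, 102_500), bundle, rubric)
        imprecise = score_section2_loss(loss(95_000, 102_500, precise=False), bundle, rubric)
        assert ids(precise) == ["2C-1"]
        assert ids(imprecise) == ["2C-2"]
        assert imprecise[0].points == 0

    def test_missing_gene_model_conservative(self, rubric, caplog):
        # dosage gene with no matching gene record: structure unknown
        record = DosageRecord("GHOST", "gene", gi(100_000, 110_000), 3, 0)
        bundle = make_bundle(dosage=[record])
        with caplog.at_level("WARNING"):
            items = score_section2_loss(loss(95_000, 102_500), bundle, rubric)
        assert ids(items) == ["2C-2"]
        assert items[0].points == 0
        assert any("conservative" in r.message for r in caplog.records)

    def test_multiple_partial_genes_keep_single_best(self, rubric):
        g1 = make_gene("HIA", 100_000)
        g2 = make_gene("HIB", 120_000)
        bundle = make_bundle(genes=[g1, g2], dosage=[hi_gene(g1), hi_gene(g2)])
        # removes 3' UTR of HIA (2D-1, 0) and 5' CDS of HIB (2C-1, +0.90)
        items = score_section2_loss(loss(109_600, 122_500), bundle, rubric)
        assert ids(items) == ["2C-1"]
        assert items[0].supporting_features == ("HIB",)


class TestSection2ContainmentAndBenign:
    def test_contained_hi_gene_fires_2a_only(self, rubric):
        gene = make_gene("HI1", 100_000)
        bundle = make_bundle(genes=[gene], dosage=[hi_gene(gene)])
        items = score_section2_loss(loss(90_000, 120_000), bundle, rubric)
        assert ids(items) == ["2A"]
        assert items[0].points == Decimal("1.00")

    def test_partial_hi_region_fires_2b_not_2a(self, rubric):
        region = DosageRecord("HIR", "region", gi(100_000, 200_000), 3, 0)
        bundle = make_bundle(dosage=[region])
        items = score_section2_loss(loss(190_000, 210_000), bundle, rubric)
        assert ids(items) == ["2B"]
        # 2A and 2B are mutually exclusive for the same record
        contained = score_section2_loss(loss(90_000, 210_000), bundle, rubric)
        assert ids(contained) == ["2A"]

    def test_benign_region_containment_vs_extra_material(self, rubric):
        region = DosageRecord("BLR", "region", gi(100_000, 200_000), 40, 0)
        bundle = make_bundle(dosage=[region])
        assert ids(score_section2_loss(loss(120_000, 180_000), bundle, rubric)) == ["2F"]
        assert ids(score_section2_loss(loss(120_000, 220_000), bundle, rubric)) == ["2G"]

    def test_predicted_hi_suppressed_by_established_overlap(self, rubric):
        gene = make_gene("HI1", 100_000)
        scores = GenePredictionScores("HI1", Decimal("4"), Decimal("0.97"), Decimal("0.2"))
        with_established = make_bundle(genes=[gene], dosage=[hi_gene(gene)],
                                       predictions=[scores])
        without = make_bundle(genes=[gene], predictions=[scores])
        assert "2H" not in ids(score_section2_loss(loss(90_000, 120_000), with_established, rubric))
        items = score_section2_loss(loss(90_000, 120_000), without, rubric)
        assert ids(items) == ["2H"]
        assert items[0].points == Decimal("0.15")

    def test_2h_fires_once_for_multiple_predicted_genes(self, rubric):
        genes = [make_gene("P1", 100_000), make_gene("P2", 120_000)]
        preds = [GenePredictionScores(g.symbol, Decimal("4"), Decimal("0.97"), Decimal("0.2"))
                 for g in genes]
        bundle = make_bundle(genes=genes, predictions=preds)
        items = score_section2_loss(loss(90_000, 140_000), bundle, rubric)
        assert ids(items) == ["2H"]
        assert items[0].supporting_features == ("P1", "P2")


class TestSection3:
    @pytest.mark.parametrize("n,expected,points", [
        (0, "3A", "0.00"), (24, "3A", "0.00"), (25, "3B", "0.45"),
        (35, "3C", "0.90"),
    ])
    def test_loss_bins(self, rubric, n, expected, points):
        genes = [make_gene(f"G{k}", 100_000 + k * 12_000) for k in range(n)]
        bundle = make_bundle(genes=genes)
        cnv = loss(90_000, 100_000 + n * 12_000 + 1)
        item = score_section3(cnv, bundle, rubric)
        assert item.criterion_id == expected
        assert item.points == Decimal(points)
        assert len(item.supporting_features) == n

    def test_noncoding_genes_not_counted(self, rubric):
        genes = [make_gene("NC", 100_000, coding=False)]
        item = score_section3(loss(90_000, 120_000), make_bundle(genes=genes), rubric)
        assert item.criterion_id == "3A"
        assert item.supporting_features == ()


class TestSection4:
    def pop(self, start, end, freq, cnv_type="loss"):
        return PopulationCnv(gi(start, end), cnv_type, Decimal(freq), "src")

    def test_mean_frequency_rule(self, rubric):
        bundle = make_bundle(population=[
            self.pop(0, 100_000, "0.005"), self.pop(0, 100_000, "0.025")])
        item = score_section4_frequency(loss(10_000, 50_000), bundle, rubric)
        assert item is not None and item.criterion_id == "4O"
        assert item.points == Decimal("-1.00")

    def test_frequency_exactly_one_percent_not_common(self, rubric):
        bundle = make_bundle(population=[self.pop(0, 100_000, "0.01")])
        assert score_section4_frequency(loss(10_000, 50_000), bundle, rubric) is None

    def test_coverage_boundary_inclusive_at_80(self, rubric):
        at_80 = make_bundle(population=[self.pop(0, 80_000, "0.05")])
        below = make_bundle(population=[self.pop(0, 79_999, "0.05")])
        cnv = loss(0, 100_000)
        assert score_section4_frequency(cnv, at_80, rubric) is not None
        assert score_section4_frequency(cnv, below, rubric) is None

    def test_gated_by_established_dosage_overlap(self, rubric):
        gene = make_gene("HI1", 10_000)
        bundle = make_bundle(genes=[gene], dosage=[hi_gene(gene)],
                             population=[self.pop(0, 100_000, "0.05")])
        assert score_section4_frequency(loss(0, 100_000), bundle, rubric) is None

    def test_only_matching_type_pooled(self, rubric):
        bundle = make_bundle(population=[
            self.pop(0, 100_000, "0.05", cnv_type="gain"),
            self.pop(0, 100_000, "0.004", cnv_type="loss")])
        assert score_section4_frequency(loss(10_000, 50_000), bundle, rubric) is None


class TestFullWalk:
    def test_desert_deletion_total(self, rubric):
        evidence = score_loss(loss(10_000, 50_000), make_bundle(), rubric)
        assert ids(evidence) == ["1B", "3A"]
        assert sum(e.points for e in evidence) == Decimal("-0.60")

    def test_hi_gene_deletion_total(self, rubric):
        genes = [make_gene("HI1", 100_000), make_gene("G2", 120_000),
                 make_gene("G3", 140_000)]
        bundle = make_bundle(genes=genes, dosage=[hi_gene(genes[0])])
        evidence = score_loss(loss(90_000, 160_000), bundle, rubric)
        assert ids(evidence) == ["1A", "2A", "3A"]
        assert sum(e.points for e in evidence) == Decimal("1.00")

    def test_adding_common_population_cnv_never_raises_total(self, rubric, bundle):
        """Monotone benignity over every fixture scenario."""
        from cnvclassify.fixtures import scenario_table, FixtureSpec

        for s in scenario_table(FixtureSpec(seed=1)):
            if s.cnv_type != "loss":
                continue
            cnv = CnvCall(s.variant_id, gi(s.start, s.end, s.chrom), "loss", s.precise)
            base_total = sum(e.points for e in score_loss(cnv, bundle, rubric))
            extra = PopulationCnv(cnv.location, "loss", Decimal("0.5"), "extra")
            augmented = AnnotationBundle(
                build=bundle.build, genes=bundle.genes, regulatory=bundle.regulatory,
                dosage=bundle.dosage, predictions=bundle.predictions,
                population=bundle.population + [extra],
            )
            new_total = sum(e.points for e in score_loss(cnv, augmented, rubric))
            assert new_total <= base_total

    def test_determinism(self, rubric, bundle):
        cnv = loss(3_480_000, 3_530_000)  # the contained-HI-gene scenario block
        first = score_loss(cnv, bundle, rubric)
        second = score_loss(cnv, bundle, rubric)
        assert first == second

    def test_wrong_type_rejected(self, rubric):
        cnv = CnvCall("d", gi(0, 1_000), "gain")
        with pytest.raises(ValueError, match="requires a loss"):
            score_loss(cnv, make_bundle(), rubric)
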