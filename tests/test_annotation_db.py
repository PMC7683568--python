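"""Database loading, validation diagnostics, and the dosage/prediction rules."""

from decimal import Decimal
from pathlib import Path

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cnvclassify.annotation_db import (
    AnnotationBundle,
    AnnotationError,
    DosageRecord,
    GenePredictionScores,
    GeneRecord,
    benign_gain_regions,
    benign_loss_regions,
    established_hi_features,
    established_ts_features,
    load_bundle,
    predicted_hi_genes,
    write_bundle,
)
from cnvclassify.intervals import GenomicInterval


def gi(chrom, start, end):
    return GenomicInterval(chrom, start, end)


def small_bundle(**over):
    genes = over.get("genes", [])
    return AnnotationBundle(
        build=over.get("build", "GRCh38"),
        genes=genes,
        regulatory=over.get("regulatory", []),
        dosage=over.get("dosage", []),
        predictions=over.get("predictions", {}),
        population=over.get("population", []),
    )


class TestLoading:
    def test_counts_preserved_through_load(self, db_dir, bundle):
        loaded = load_bundle(db_dir, "GRCh38")
        assert len(loaded.genes) == len(bundle.genes)
        assert len(loaded.regulatory) == len(bundle.regulatory)
        assert len(loaded.dosage) == len(bundle.dosage)
        assert len(loaded.predictions) == len(bundle.predictions)
        assert len(loaded.population) == len(bundle.population)

    def test_malformed_line_error_names_file_and_line(self, db_dir, tmp_path):
        import shutil
        bad = tmp_path / "bad"
        shutil.copytree(db_dir / "GRCh38", bad / "GRCh38")
        genes = bad / "GRCh38" / "genes.tsv"
        lines = genes.read_text().splitlines()
        # corrupt data line 7 (header is line 1): end <= start
        fields = lines[6].split("\t")
        fields[2] = fields[1]
        lines[6] = "\t".join(fields)
        genes.write_text("\n".join(lines) + "\n")
        with pytest.raises(AnnotationError, match=r"genes\.tsv, line 7"):
            load_bundle(bad, "GRCh38")

    def test_missing_file_and_unknown_build_fatal(self, db_dir, tmp_path):
        with pytest.raises(AnnotationError, match="unknown genome build"):
            load_bundle(db_dir, "hg19")
        (tmp_path / "GRCh37").mkdir()
        with pytest.raises(AnnotationError, match="genes.tsv"):
            load_bundle(tmp_path, "GRCh37")

    def test_roundtrip_is_content_idempotent(self, db_dir, tmp_path):
        loaded = load_bundle(db_dir, "GRCh38")
        write_bundle(loaded, tmp_path / "b")
        reloaded = load_bundle(tmp_path / "b", "GRCh38")
        write_bundle(reloaded, tmp_path / "c")
        for name in ("genes", "regulatory", "dosage", "predictions", "population"):
            first = (tmp_path / "b" / "GRCh38" / f"{name}.tsv").read_bytes()
            second = (tmp_path / "c" / "GRCh38" / f"{name}.tsv").read_bytes()
            assert first == second


class TestGeneInvariants:
    def test_exon_outside_span_rejected(self):
        with pytest.raises(AnnotationError, match="exon outside"):
            GeneRecord("G", gi("chr1", 100, 200), "+", True,
                       exons=(gi("chr1", 50, 150),))

    def test_unsorted_exons_rejected(self):
        with pytest.raises(AnnotationError, match="unsorted"):
            GeneRecord("G", gi("chr1", 0, 1000), "+", True,
                       exons=(gi("chr1", 500, 600), gi("chr1", 100, 200)))

    def test_cds_outside_span_rejected(self):
        with pytest.raises(AnnotationError, match="CDS outside"):
            GeneRecord("G", gi("chr1", 100, 200), "+", True,
                       cds=gi("chr1", 100, 300))


class TestDosageScores:
    def make(self, hi=0, ts=0):
        return DosageRecord("D", "gene", gi("chr1", 0, 100), hi, ts)

    def test_only_score_3_establishes(self):
        records = [self.make(hi=3), self.make(hi=2), self.make(hi=3, ts=3),
                   self.make(hi=0), self.make(hi=30), self.make(hi=40)]
        bundle = small_bundle(dosage=records)
        assert established_hi_features(bundle) == [records[0], records[2]]
        assert established_ts_features(bundle) == [records[2]]
        # score-3 + everything-else partitions the collection
        not_established = [d for d in records if not d.established_hi]
        assert len(not_established) + len(established_hi_features(bundle)) == len(records)

    def test_dialect_scores_30_40_not_established_but_40_is_benign(self):
        bundle = small_bundle(dosage=[self.make(hi=40, ts=40), self.make(hi=30)])
        assert established_hi_features(bundle) == []
        assert established_ts_features(bundle) == []
        assert len(benign_loss_regions(bundle)) == 1
        assert len(benign_gain_regions(bundle)) == 1

    def test_score_40_accepted_from_file(self, tmp_path, db_dir):
        import shutil
        root = tmp_path / "d"
        shutil.copytree(db_dir / "GRCh38", root / "GRCh38")
        dosage = root / "GRCh38" / "dosage.tsv"
        with open(dosage, "a") as handle:
            handle.write("chr3\t100\t200\tDIAL40\tgene\t40\t0\n")
        loaded = load_bundle(root, "GRCh38")
        rec = next(d for d in loaded.dosage if d.name == "DIAL40")
        assert not rec.established_hi
        assert rec in benign_loss_regions(loaded)

    def test_invalid_score_rejected(self):
        with pytest.raises(AnnotationError, match="bad hi_score"):
            self.make(hi=5)


def make_gene(symbol):
    return GeneRecord(symbol, gi("chr1", 0, 1000), "+", True)


class TestPredictedHi:
    @pytest.mark.parametrize("hi,pli,loeuf,included", [
        ("5", "0.99", "0.20", True),
        ("5", "0.99", "0.35", False),   # LOEUF bound is strict
        ("10", "0.9", "0.30", True),    # HI index and pLI bounds are inclusive
        ("10.01", "0.99", "0.20", False),
        ("5", "0.89", "0.20", False),
    ])
    def test_threshold_boundaries(self, hi, pli, loeuf, included):
        gene = make_gene("G1")
        scores = GenePredictionScores("G1", Decimal(hi), Decimal(pli), Decimal(loeuf))
        bundle = small_bundle(genes=[gene], predictions={"G1": scores})
        assert (gene in predicted_hi_genes(bundle, [gene])) is included

    def test_missing_scores_excluded(self):
        gene = make_gene("G1")
        scores = GenePredictionScores("G1", Decimal("5"), None, Decimal("0.2"))
        bundle = small_bundle(genes=[gene], predictions={"G1": scores})
        assert predicted_hi_genes(bundle, [gene]) == []
        assert predicted_hi_genes(small_bundle(genes=[gene]), [gene]) == []

    @given(
        hi=st.decimals(min_value=0, max_value=100, places=2),
        pli=st.decimals(min_value=0, max_value=1, places=3),
        loeuf=st.decimals(min_value=0, max_value=2, places=3),
    )
    def test_monotone_in_each_threshold(self, hi, pli, loeuf):
        """A gene passing the strict gates passes any relaxed version of them."""
        scores = GenePredictionScores("G", hi, pli, loeuf)
        if scores.predicted_haploinsufficient:
            assert hi <= 10 and pli >= Decimal("0.9") and loeuf < Decimal("0.35")
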