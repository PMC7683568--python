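"""Typed readers, writers and the in-memory lookup model for annotation databases.

Five databases feed the scorers, one TSV-with-BED-prefix file each, per
genome build (layout ``<db_dir>/<build>/<name>.tsv``):

``genes.tsv``
    chrom  start  end  symbol  strand  coding  exon_starts  exon_ends
    cds_start  cds_end  last_exon_pathogenic
``regulatory.tsv``
    chrom  start  end  element_id  kind(enhancer|promoter)
``dosage.tsv``
    chrom  start  end  name  scope(gene|region)  hi_score  ts_score
``predictions.tsv``
    symbol  hi_index  pli  loeuf_upper      (``.`` marks a missing value)
``population.tsv``
    chrom  start  end  cnv_type(loss|gain)  frequency  source

Dosage curation scores follow the ClinGen 0-3 scale with the 30
("autosomal recessive") and 40 ("dosage sensitivity unlikely") dialect
codes.  Only a literal score of 3 establishes dosage sensitivity; the
40 code additionally marks an established *benign* region for the
benign-overlap criteria.  Missing files and malformed lines are fatal,
with filename and line number in the diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

from .intervals import FeatureIndex, GenomicInterval, IntervalError, overlap_length

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationError",
    "GeneRecord",
    "RegulatoryElement",
    "DosageRecord",
    "GenePredictionScores",
    "PopulationCnv",
    "AnnotationBundle",
    "SUPPORTED_BUILDS",
    "ESTABLISHED_SCORE",
    "BENIGN_SCORE",
    "load_bundle",
    "write_bundle",
    "established_hi_features",
    "established_ts_features",
    "benign_loss_regions",
    "benign_gain_regions",
    "predicted_hi_genes",
]

SUPPORTED_BUILDS = ("GRCh37", "GRCh38")

#: ClinGen curation score establishing haploinsufficiency / triplosensitivity.
ESTABLISHED_SCORE = 3
#: Dialect code "dosage sensitivity unlikely" — marks established benign regions.
BENIGN_SCORE = 40

VALID_DOSAGE_SCORES = {0, 1, 2, 3, 30, 40}

# Predicted-haploinsufficiency gates: DECIPHER HI index <= 10 %,
# gnomAD pLI >= 0.9, LOEUF upper bound < 0.35.  The first two are
# inclusive, the third strict.
HI_INDEX_MAX = Decimal("10")
PLI_MIN = Decimal("0.9")
LOEUF_UPPER_MAX = Decimal("0.35")

DATABASE_FILES = {
    "genes": "genes.tsv",
    "regulatory": "regulatory.tsv",
    "dosage": "dosage.tsv",
    "predictions": "predictions.tsv",
    "population": "population.tsv",
}


class AnnotationError(ValueError):
    """Fatal database problem (missing file, malformed line, bad invariant)."""


@dataclass(frozen=True)
class GeneRecord:
    """A gene model: span, strand, coding status, exon structure.

    ``exons`` may be empty for noncoding entries with no curated structure;
    ``cds`` is the coding span and is absent for noncoding genes.
    ``last_exon_pathogenic`` is a curation flag: established pathogenic
    variants are known in the gene's last exon (drives one of the
    3'-truncation sub-criteria).
    """

    symbol: str
    location: GenomicInterval
    strand: str
    is_protein_coding: bool
    exons: tuple = ()
    cds: Optional[GenomicInterval] = None
    last_exon_pathogenic: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.symbol}: bad strand {self.strand!r}")
        prev_end = None
        for exon in self.exons:
            if exon.chrom != self.location.chrom:
                raise AnnotationError(f"gene {self.symbol}: exon on wrong chromosome")
            if exon.start < self.location.start or exon.end > self.location.end:
                raise AnnotationError(f"gene {self.symbol}: exon outside gene span")
            if prev_end is not None and exon.start < prev_end:
                raise AnnotationError(
                    f"gene {self.symbol}: exons overlap or are unsorted"
                )
            prev_end = exon.end
        if self.cds is not None:
            if (
                self.cds.chrom != self.location.chrom
                or self.cds.start < self.location.start
                or self.cds.end > self.location.end
            ):
                raise AnnotationError(f"gene {self.symbol}: CDS outside gene span")


@dataclass(frozen=True)
class RegulatoryElement:
    element_id: str
    kind: str  # enhancer | promoter
    location: GenomicInterval

    def __post_init__(self) -> None:
        if self.kind not in ("enhancer", "promoter"):
            raise AnnotationError(
                f"regulatory element {self.element_id}: bad kind {self.kind!r}"
            )


@dataclass(frozen=True)
class DosageRecord:
    """A curated dosage-sensitivity entry (gene or region) with HI/TS scores."""

    name: str
    scope: str  # gene | region
    location: GenomicInterval
    hi_score: int
    ts_score: int

    def __post_init__(self) -> None:
        if self.scope not in ("gene", "region"):
            raise AnnotationError(f"dosage record {self.name}: bad scope {self.scope!r}")
        for label, score in (("hi", self.hi_score), ("ts", self.ts_score)):
            if score not in VALID_DOSAGE_SCORES:
                raise AnnotationError(
                    f"dosage record {self.name}: bad {label}_score {score!r}"
                )

    @property
    def established_hi(self) -> bool:
        return self.hi_score == ESTABLISHED_SCORE

    @property
    def established_ts(self) -> bool:
        return self.ts_score == ESTABLISHED_SCORE


@dataclass(frozen=True)
class GenePredictionScores:
    """Per-gene haploinsufficiency predictor scores; ``None`` marks missing."""

    symbol: str
    hi_index: Optional[Decimal]  # percentage, [0, 100]
    pli: Optional[Decimal]  # probability, [0, 1]
    loeuf_upper: Optional[Decimal]  # non-negative ratio

    def __post_init__(self) -> None:
        if self.hi_index is not None and not 0 <= self.hi_index <= 100:
            raise AnnotationError(f"{self.symbol}: hi_index out of [0, 100]")
        if self.pli is not None and not 0 <= self.pli <= 1:
            raise AnnotationError(f"{self.symbol}: pLI out of [0, 1]")
        if self.loeuf_upper is not None and self.loeuf_upper < 0:
            raise AnnotationError(f"{self.symbol}: negative LOEUF upper bound")

    @property
    def predicted_haploinsufficient(self) -> bool:
        """All three predictor gates pass; any missing score fails the test."""
        if self.hi_index is None or self.pli is None or self.loeuf_upper is None:
            return False
        return (
            self.hi_index <= HI_INDEX_MAX
            and self.pli >= PLI_MIN
            and self.loeuf_upper < LOEUF_UPPER_MAX
        )


@dataclass(frozen=True)
class PopulationCnv:
    location: GenomicInterval
    cnv_type: str  # loss | gain
    frequency: Decimal
    source: str

    def __post_init__(self) -> None:
        if self.cnv_type not in ("loss", "gain"):
            raise AnnotationError(f"population CNV: bad type {self.cnv_type!r}")
        if not 0 <= self.frequency <= 1:
            raise AnnotationError(
                f"population CNV {self.location}: frequency {self.frequency} out of [0, 1]"
            )


@dataclass
class AnnotationBundle:
    """All five databases for one genome build, indexed for interval lookup."""

    build: str
    genes: List[GeneRecord]
    regulatory: List[RegulatoryElement]
    dosage: List[DosageRecord]
    predictions: Dict[str, GenePredictionScores]
    population: List[PopulationCnv]
    gene_index: FeatureIndex = field(init=False)
    regulatory_index: FeatureIndex = field(init=False)
    dosage_index: FeatureIndex = field(init=False)
    population_index: FeatureIndex = field(init=False)
    genes_by_symbol: Dict[str, GeneRecord] = field(init=False)

    def __post_init__(self) -> None:
        if self.build not in SUPPORTED_BUILDS:
            raise AnnotationError(
                f"unknown genome build {self.build!r}; supported: {SUPPORTED_BUILDS}"
            )
        self.gene_index = FeatureIndex(self.genes)
        self.regulatory_index = FeatureIndex(self.regulatory)
        self.dosage_index = FeatureIndex(self.dosage)
        self.population_index = FeatureIndex(self.population)
        self.genes_by_symbol = {g.symbol: g for g in self.genes}
        for symbol in self.predictions:
            if symbol not in self.genes_by_symbol:
                logger.warning(
                    "prediction scores for %s do not match any gene record", symbol
                )


# ---------------------------------------------------------------------------
# Parsing helpers


def _parse_int(token: str, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise AnnotationError(f"non-integer {what}: {token!r}") from None


def _parse_decimal(token: str, what: str) -> Decimal:
    try:
        return Decimal(token)
    except InvalidOperation:
        raise AnnotationError(f"non-numeric {what}: {token!r}") from None


def _parse_bool(token: str, what: str) -> bool:
    if token in ("1", "true", "True"):
        return True
    if token in ("0", "false", "False"):
        return False
    raise AnnotationError(f"bad boolean {what}: {token!r}")


def _parse_opt_decimal(token: str, what: str) -> Optional[Decimal]:
    if token in (".", "", "NA"):
        return None
    return _parse_decimal(token, what)


def _interval(chrom: str, start: str, end: str) -> GenomicInterval:
    return GenomicInterval(chrom, _parse_int(start, "start"), _parse_int(end, "end"))


def _data_lines(path: Path):
    """Yield (line_number, fields) for non-comment, non-blank lines."""
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def _require_columns(fields: Sequence[str], n: int) -> None:
    if len(fields) != n:
        raise AnnotationError(f"expected {n} tab-separated columns, found {len(fields)}")


def _load_file(path: Path, n_columns: int, parse_row):
    if not path.is_file():
        raise AnnotationError(f"missing database file: {path}")
    records = []
    for lineno, fields in _data_lines(path):
        try:
            _require_columns(fields, n_columns)
            records.append(parse_row(fields))
        except (AnnotationError, IntervalError) as exc:
            raise AnnotationError(f"{path.name}, line {lineno}: {exc}") from None
    return records


def _parse_exon_list(chrom: str, starts: str, ends: str) -> tuple:
    if starts == "." and ends == ".":
        return ()
    start_tokens = [t for t in starts.split(",") if t]
    end_tokens = [t for t in ends.split(",") if t]
    if len(start_tokens) != len(end_tokens):
        raise AnnotationError("exon_starts and exon_ends differ in length")
    return tuple(
        GenomicInterval(chrom, _parse_int(s, "exon start"), _parse_int(e, "exon end"))
        for s, e in zip(start_tokens, end_tokens)
    )


def _parse_gene_row(f: Sequence[str]) -> GeneRecord:
    location = _interval(f[0], f[1], f[2])
    cds = None
    if f[8] != "." or f[9] != ".":
        cds = _interval(f[0], f[8], f[9])
    return GeneRecord(
        symbol=f[3],
        location=location,
        strand=f[4],
        is_protein_coding=_parse_bool(f[5], "coding flag"),
        exons=_parse_exon_list(location.chrom, f[6], f[7]),
        cds=cds,
        last_exon_pathogenic=_parse_bool(f[10], "last_exon_pathogenic"),
    )


def _parse_regulatory_row(f: Sequence[str]) -> RegulatoryElement:
    return RegulatoryElement(element_id=f[3], kind=f[4], location=_interval(f[0], f[1], f[2]))


def _parse_dosage_row(f: Sequence[str]) -> DosageRecord:
    return DosageRecord(
        name=f[3],
        scope=f[4],
        location=_interval(f[0], f[1], f[2]),
        hi_score=_parse_int(f[5], "hi_score"),
        ts_score=_parse_int(f[6], "ts_score"),
    )


def _parse_prediction_row(f: Sequence[str]) -> GenePredictionScores:
    return GenePredictionScores(
        symbol=f[0],
        hi_index=_parse_opt_decimal(f[1], "hi_index"),
        pli=_parse_opt_decimal(f[2], "pli"),
        loeuf_upper=_parse_opt_decimal(f[3], "loeuf_upper"),
    )


def _parse_population_row(f: Sequence[str]) -> PopulationCnv:
    return PopulationCnv(
        location=_interval(f[0], f[1], f[2]),
        cnv_type=f[3],
        frequency=_parse_decimal(f[4], "frequency"),
        source=f[5],
    )


def load_bundle(db_dir: "str | Path", build: str) -> AnnotationBundle:
    """Load and validate all five databases for one genome build.

    ``db_dir`` must contain a ``<build>/`` subdirectory with the five TSV
    files named in :data:`DATABASE_FILES`.  Record counts are logged;
    any malformed line aborts with a file/line diagnostic.
    """
    if build not in SUPPORTED_BUILDS:
        raise AnnotationError(
            f"unknown genome build {build!r}; supported: {SUPPORTED_BUILDS}"
        )
    base = Path(db_dir) / build
    if not base.is_dir():
        raise AnnotationError(f"database directory not found: {base}")
    genes = _load_file(base / DATABASE_FILES["genes"], 11, _parse_gene_row)
    regulatory = _load_file(base / DATABASE_FILES["regulatory"], 5, _parse_regulatory_row)
    dosage = _load_file(base / DATABASE_FILES["dosage"], 7, _parse_dosage_row)
    predictions = _load_file(base / DATABASE_FILES["predictions"], 4, _parse_prediction_row)
    population = _load_file(base / DATABASE_FILES["population"], 6, _parse_population_row)
    logger.info(
        "loaded %s bundle: %d genes, %d regulatory elements, %d dosage records, "
        "%d prediction rows, %d population CNVs",
        build, len(genes), len(regulatory), len(dosage), len(predictions), len(population),
    )
    return AnnotationBundle(
        build=build,
        genes=genes,
        regulatory=regulatory,
        dosage=dosage,
        predictions={p.symbol: p for p in predictions},
        population=population,
    )


# ---------------------------------------------------------------------------
# Serialization (canonical form; fixtures and round-trip tests share it)


def _fmt_exons(exons: tuple) -> "tuple[str, str]":
    if not exons:
        return ".", "."
    return (
        ",".join(str(e.start) for e in exons),
        ",".join(str(e.end) for e in exons),
    )


def _gene_row(g: GeneRecord) -> List[str]:
    starts, ends = _fmt_exons(g.exons)
    return [
        g.location.chrom, str(g.location.start), str(g.location.end), g.symbol,
        g.strand, "1" if g.is_protein_coding else "0", starts, ends,
        str(g.cds.start) if g.cds else ".", str(g.cds.end) if g.cds else ".",
        "1" if g.last_exon_pathogenic else "0",
    ]


def _regulatory_row(r: RegulatoryElement) -> List[str]:
    return [r.location.chrom, str(r.location.start), str(r.location.end), r.element_id, r.kind]


def _dosage_row(d: DosageRecord) -> List[str]:
    return [
        d.location.chrom, str(d.location.start), str(d.location.end),
        d.name, d.scope, str(d.hi_score), str(d.ts_score),
    ]


def _prediction_row(p: GenePredictionScores) -> List[str]:
    fmt = lambda v: "." if v is None else str(v)
    return [p.symbol, fmt(p.hi_index), fmt(p.pli), fmt(p.loeuf_upper)]


def _population_row(p: PopulationCnv) -> List[str]:
    return [
        p.location.chrom, str(p.location.start), str(p.location.end),
        p.cnv_type, str(p.frequency), p.source,
    ]


_LOC_KEY = lambda rec: (rec.location.chrom, rec.location.start, rec.location.end)

_WRITERS = {
    "genes": (
        "#chrom\tstart\tend\tsymbol\tstrand\tcoding\texon_starts\texon_ends"
        "\tcds_start\tcds_end\tlast_exon_pathogenic",
        _gene_row,
        lambda b: sorted(b.genes, key=lambda g: (*_LOC_KEY(g), g.symbol)),
    ),
    "regulatory": (
        "#chrom\tstart\tend\telement_id\tkind",
        _regulatory_row,
        lambda b: sorted(b.regulatory, key=lambda r: (*_LOC_KEY(r), r.element_id)),
    ),
    "dosage": (
        "#chrom\tstart\tend\tname\tscope\thi_score\tts_score",
        _dosage_row,
        lambda b: sorted(b.dosage, key=lambda d: (*_LOC_KEY(d), d.name)),
    ),
    "predictions": (
        "#symbol\thi_index\tpli\tloeuf_upper",
        _prediction_row,
        lambda b: sorted(b.predictions.values(), key=lambda p: p.symbol),
    ),
    "population": (
        "#chrom\tstart\tend\tcnv_type\tfrequency\tsource",
        _population_row,
        lambda b: sorted(b.population, key=lambda p: (*_LOC_KEY(p), p.source, p.cnv_type)),
    ),
}


def write_bundle(bundle: AnnotationBundle, db_dir: "str | Path") -> Path:
    """Serialize a bundle to ``<db_dir>/<build>/`` in canonical sorted form."""
    base = Path(db_dir) / bundle.build
    base.mkdir(parents=True, exist_ok=True)
    for name, (header, to_row, select) in _WRITERS.items():
        path = base / DATABASE_FILES[name]
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(header + "\n")
            for record in select(bundle):
                handle.write("\t".join(to_row(record)) + "\n")
    return base


# ---------------------------------------------------------------------------
# Selectors used by the scorers


def established_hi_features(bundle: AnnotationBundle) -> List[DosageRecord]:
    """Dosage records with a haploinsufficiency curation score of exactly 3."""
    return [d for d in bundle.dosage if d.established_hi]


def established_ts_features(bundle: AnnotationBundle) -> List[DosageRecord]:
    """Dosage records with a triplosensitivity curation score of exactly 3."""
    return [d for d in bundle.dosage if d.established_ts]


def benign_loss_regions(bundle: AnnotationBundle) -> List[DosageRecord]:
    """Established benign copy-number-loss features (hi_score 40 dialect)."""
    return [d for d in bundle.dosage if d.hi_score == BENIGN_SCORE]


def benign_gain_regions(bundle: AnnotationBundle) -> List[DosageRecord]:
    """Established benign copy-number-gain features (ts_score 40 dialect)."""
    return [d for d in bundle.dosage if d.ts_score == BENIGN_SCORE]


def predicted_hi_genes(
    bundle: AnnotationBundle, genes: Iterable[GeneRecord]
) -> List[GeneRecord]:
    """Genes passing all three haploinsufficiency-prediction gates.

    Genes without a prediction row, or with any missing score, are excluded.
    """
    selected = []
    for gene in genes:
        scores = bundle.predictions.get(gene.symbol)
        if scores is not None and scores.predicted_haploinsufficient:
            selected.append(gene)
    return selected


def genes_overlapping(
    bundle: AnnotationBundle,
    interval: GenomicInterval,
    containment: str = "overlap",
) -> List[GeneRecord]:
    """Genes intersecting ``interval``.

    ``containment="overlap"`` (default) requires >= 1 bp of overlap;
    ``"full"`` requires the gene to lie entirely within the interval.
    """
    hits = [g for g, _ in bundle.gene_index.query(interval)]
    if containment == "full":
        hits = [
            g
            for g in hits
            if interval.start <= g.location.start and interval.end >= g.location.end
            and interval.chrom == g.location.chrom
        ]
    elif containment != "overlap":
        raise ValueError(f"containment must be 'overlap' or 'full', not {containment!r}")
    return hits
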