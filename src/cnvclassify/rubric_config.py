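"""Rubric configuration: criterion point values, gene-count bins, thresholds.

The scoring rubrics assign each fired criterion a signed point value and map
the summed total onto the five clinical tiers.  All of these numbers are
data, not code: the defaults ship in ``data/acmg_cnv_rubric.yaml`` and a
guideline revision is a config change.  Points are carried as
:class:`~decimal.Decimal` so that sums like 0.45 + 0.45 are exactly 0.90 —
the classification bands are only 0.01 apart, so binary floating point is
not acceptable here.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from decimal import Decimal, InvalidOperation
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

__all__ = [
    "RubricError",
    "RubricCriterion",
    "ClassificationThresholds",
    "PopulationRule",
    "GeneCountBin",
    "Rubric",
    "load_rubric",
    "REQUIRED_LOSS_CRITERIA",
    "REQUIRED_GAIN_CRITERIA",
]

# Every criterion the scorers can emit must be present in a loaded config.
REQUIRED_LOSS_CRITERIA = (
    "1A", "1B",
    "2A", "2B", "2C-1", "2C-2", "2D-1", "2D-2", "2D-3", "2D-4",
    "2E", "2F", "2G", "2H",
    "3A", "3B", "3C",
    "4O",
)
REQUIRED_GAIN_CRITERIA = (
    "1A", "1B",
    "2A", "2B", "2C", "2D", "2E", "2F", "2G", "2H", "2I", "2J", "2L",
    "3A", "3B", "3C",
    "4O",
)

SCHEMA_VERSION = 1


class RubricError(ValueError):
    """Raised for a syntactically or semantically invalid rubric config."""


@dataclass(frozen=True)
class RubricCriterion:
    criterion_id: str
    cnv_type: str  # loss | gain
    points: Decimal
    description: str


@dataclass(frozen=True)
class ClassificationThresholds:
    """Cut points of the five-tier classification on the total-score line.

    Pathogenic: total >= pathogenic_min; Likely pathogenic:
    likely_pathogenic_min <= total < pathogenic_min; Benign:
    total <= benign_max; Likely benign: benign_max < total <=
    likely_benign_max; everything between is Uncertain significance.
    """

    pathogenic_min: Decimal
    likely_pathogenic_min: Decimal
    likely_benign_max: Decimal
    benign_max: Decimal

    def __post_init__(self) -> None:
        if not (
            self.benign_max < self.likely_benign_max
            < self.likely_pathogenic_min < self.pathogenic_min
        ):
            raise RubricError(
                "threshold ordering violated: need benign_max < likely_benign_max "
                "< likely_pathogenic_min < pathogenic_min, got "
                f"{self.benign_max}, {self.likely_benign_max}, "
                f"{self.likely_pathogenic_min}, {self.pathogenic_min}"
            )


@dataclass(frozen=True)
class PopulationRule:
    """Matching rules for the population-frequency criterion."""

    min_coverage: Decimal  # fraction of query length, inclusive
    common_frequency: Decimal  # mean frequency must strictly exceed this


@dataclass(frozen=True)
class GeneCountBin:
    """One gene-count bin: counts up to ``max_count`` (inclusive; None = open)."""

    max_count: Optional[int]
    criterion_id: str


@dataclass(frozen=True)
class Rubric:
    criteria: Dict[Tuple[str, str], RubricCriterion]  # (cnv_type, id) -> criterion
    thresholds: ClassificationThresholds
    population: PopulationRule
    gene_count_bins: Dict[str, Tuple[GeneCountBin, ...]]
    schema_version: int = SCHEMA_VERSION

    def criterion(self, cnv_type: str, criterion_id: str) -> RubricCriterion:
        try:
            return self.criteria[(cnv_type, criterion_id)]
        except KeyError:
            raise RubricError(
                f"criterion {criterion_id!r} for {cnv_type} not in rubric config"
            ) from None

    def points(self, cnv_type: str, criterion_id: str) -> Decimal:
        return self.criterion(cnv_type, criterion_id).points

    def criterion_ids(self, cnv_type: str) -> List[str]:
        return [cid for (ct, cid) in self.criteria if ct == cnv_type]

    def gene_count_criterion(self, cnv_type: str, count: int) -> str:
        """Map a protein-coding gene count through the configured bins."""
        for bin_ in self.gene_count_bins[cnv_type]:
            if bin_.max_count is None or count <= bin_.max_count:
                return bin_.criterion_id
        raise RubricError(f"no gene-count bin for count {count}")  # pragma: no cover


def _decimal(value, what: str) -> Decimal:
    try:
        return Decimal(str(value))
    except InvalidOperation:
        raise RubricError(f"non-numeric {what}: {value!r}") from None


def _parse_criteria(raw: list, cnv_type: str, required) -> Dict[Tuple[str, str], RubricCriterion]:
    criteria: Dict[Tuple[str, str], RubricCriterion] = {}
    for entry in raw:
        cid = str(entry["id"])
        key = (cnv_type, cid)
        if key in criteria:
            raise RubricError(f"duplicate {cnv_type} criterion {cid}")
        points = _decimal(entry["points"], f"{cnv_type} {cid} points")
        if not points.is_finite():
            raise RubricError(f"{cnv_type} {cid}: points must be finite")
        criteria[key] = RubricCriterion(
            criterion_id=cid,
            cnv_type=cnv_type,
            points=points,
            description=str(entry.get("description", "")),
        )
    missing = [cid for cid in required if (cnv_type, cid) not in criteria]
    if missing:
        raise RubricError(
            f"rubric config is missing required {cnv_type} criteria: {', '.join(missing)}"
        )
    return criteria


def _parse_bins(raw: list, cnv_type: str, criteria) -> Tuple[GeneCountBin, ...]:
    bins = []
    prev_max = -1
    for i, entry in enumerate(raw):
        max_count = entry.get("max")
        cid = str(entry["criterion"])
        if (cnv_type, cid) not in criteria:
            raise RubricError(f"gene-count bin references unknown criterion {cid}")
        if max_count is None:
            if i != len(raw) - 1:
                raise RubricError("only the last gene-count bin may be open-ended")
        else:
            max_count = int(max_count)
            if max_count <= prev_max:
                raise RubricError("gene-count bins must be strictly increasing")
            prev_max = max_count
        bins.append(GeneCountBin(max_count=max_count, criterion_id=cid))
    if not bins or bins[-1].max_count is not None:
        raise RubricError(f"{cnv_type} gene-count bins must end with an open bin")
    return tuple(bins)


def load_rubric(config_path: "str | Path | None" = None) -> Rubric:
    """Load the rubric from ``config_path``, or the built-in defaults.

    Validates completeness (every criterion the scorers reference must be
    present), threshold ordering, and bin structure; any violation raises
    :class:`RubricError` naming the offending entry.
    """
    if config_path is None:
        source = importlib.resources.files("cnvclassify.data") / "acmg_cnv_rubric.yaml"
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(config_path).read_text(encoding="utf-8")
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise RubricError(f"rubric config is not valid YAML: {exc}") from None
    if not isinstance(raw, dict):
        raise RubricError("rubric config must be a mapping")
    version = raw.get("schema_version")
    if version != SCHEMA_VERSION:
        raise RubricError(f"unsupported rubric schema_version: {version!r}")

    try:
        thr = raw["thresholds"]
        thresholds = ClassificationThresholds(
            pathogenic_min=_decimal(thr["pathogenic_min"], "pathogenic_min"),
            likely_pathogenic_min=_decimal(thr["likely_pathogenic_min"], "likely_pathogenic_min"),
            likely_benign_max=_decimal(thr["likely_benign_max"], "likely_benign_max"),
            benign_max=_decimal(thr["benign_max"], "benign_max"),
        )
        pop = raw["population"]
        population = PopulationRule(
            min_coverage=_decimal(pop["min_coverage"], "min_coverage"),
            common_frequency=_decimal(pop["common_frequency"], "common_frequency"),
        )
        criteria = _parse_criteria(raw["loss"], "loss", REQUIRED_LOSS_CRITERIA)
        criteria.update(_parse_criteria(raw["gain"], "gain", REQUIRED_GAIN_CRITERIA))
        bins = {
            "loss": _parse_bins(raw["gene_count_bins"]["loss"], "loss", criteria),
            "gain": _parse_bins(raw["gene_count_bins"]["gain"], "gain", criteria),
        }
    except KeyError as exc:
        raise RubricError(f"rubric config is missing required key: {exc}") from None
    if not 0 < population.min_coverage <= 1:
        raise RubricError("population min_coverage must be in (0, 1]")
    if not 0 <= population.common_frequency < 1:
        raise RubricError("population common_frequency must be in [0, 1)")
    return Rubric(
        criteria=criteria,
        thresholds=thresholds,
        population=population,
        gene_count_bins=bins,
        schema_version=version,
    )
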