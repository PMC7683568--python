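"""Exact genomic-interval arithmetic for CNV annotation.

Every coordinate in this package follows the BED convention: 0-based,
half-open ``[start, end)``.  Chromosome labels are normalized to a single
``chr``-prefixed dialect at construction time so that ``"1"`` and ``"chr1"``
compare equal everywhere downstream.

The operations here (overlap length, containment, query-coverage fraction,
breakpoint geometry, batch intersection) underlie every criterion of the
scoring rubrics: "full or partial (>= 1 bp) overlap" tests, the "complete
overlap" criteria, the >= 80 % population-CNV coverage rule, and the
partial-overlap sub-criteria that depend on which CNV endpoint falls inside
a gene.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from typing import Any, Iterable, List, Sequence, Tuple

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "IntervalError",
    "BreakpointLocation",
    "normalize_chrom",
    "overlap_length",
    "fully_contains",
    "query_coverage_fraction",
    "breakpoints_within",
    "find_overlaps",
    "FeatureIndex",
]


class IntervalError(ValueError):
    """Raised for malformed genomic coordinates or chromosome labels."""


_CHROM_RE = re.compile(r"^(?:chr)?(\d{1,2}|[XYM]|MT)$", re.IGNORECASE)


def normalize_chrom(label: str) -> str:
    """Normalize a chromosome label to the canonical ``chr``-prefixed form.

    Accepts both the UCSC (``chr1``) and Ensembl (``1``) dialects, case
    insensitively; ``MT`` maps to ``chrM``.

    >>> normalize_chrom("1")
    'chr1'
    >>> normalize_chrom("chrx")
    'chrX'
    """
    m = _CHROM_RE.match(label.strip())
    if not m:
        raise IntervalError(f"unrecognized chromosome label: {label!r}")
    name = m.group(1).upper()
    if name == "MT":
        name = "M"
    if name.isdigit():
        num = int(name)
        if not 1 <= num <= 22:
            raise IntervalError(f"chromosome number out of range: {label!r}")
        name = str(num)
    return "chr" + name


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome.

    Empty and inverted intervals are rejected at construction; the
    chromosome label is normalized (see :func:`normalize_chrom`).
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if not isinstance(self.start, int) or not isinstance(self.end, int):
            raise IntervalError(f"coordinates must be integers: {self.start!r}, {self.end!r}")
        if self.start < 0:
            raise IntervalError(f"negative start coordinate: {self.start}")
        if self.end <= self.start:
            raise IntervalError(
                f"empty or inverted interval: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


class BreakpointLocation(Enum):
    """Which endpoints of a CNV fall strictly inside a feature.

    An endpoint exactly on a feature boundary does not count as inside: a
    deletion ending exactly where a gene starts removes none of it.
    ``BOTH`` implies the CNV is contained in the feature.
    """

    NONE = "none"
    LEFT_ONLY = "left_only"
    RIGHT_ONLY = "right_only"
    BOTH = "both"


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Length in bp of the intersection of ``a`` and ``b`` (0 if disjoint).

    Symmetric; different chromosomes give 0, never an error.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def fully_contains(outer: GenomicInterval, inner: GenomicInterval) -> bool:
    """True iff ``inner`` lies entirely within ``outer`` (boundaries may touch)."""
    return (
        outer.chrom == inner.chrom
        and outer.start <= inner.start
        and outer.end >= inner.end
    )


def query_coverage_fraction(query: GenomicInterval, subject: GenomicInterval) -> Fraction:
    """Fraction of the query interval covered by the subject, as an exact rational.

    Used for the population-CNV matching rule, where coverage of at least
    80 % of the query CNV length is required; returning a
    :class:`~fractions.Fraction` keeps that boundary comparison exact.
    """
    return Fraction(overlap_length(query, subject), query.length)


def breakpoints_within(cnv: GenomicInterval, feature: GenomicInterval) -> BreakpointLocation:
    """Report which CNV endpoints fall strictly inside ``feature``.

    Strict interior containment: ``feature.start < endpoint < feature.end``.
    The left endpoint is the CNV start; the right endpoint is the CNV end.
    """
    if cnv.chrom != feature.chrom:
        return BreakpointLocation.NONE
    left = feature.start < cnv.start < feature.end
    right = feature.start < cnv.end < feature.end
    if left and right:
        return BreakpointLocation.BOTH
    if left:
        return BreakpointLocation.LEFT_ONLY
    if right:
        return BreakpointLocation.RIGHT_ONLY
    return BreakpointLocation.NONE


def _record_key(record: Any) -> str:
    """Stable identifier used to break sort ties between co-located records."""
    for attr in ("symbol", "name", "element_id", "variant_id", "source"):
        value = getattr(record, attr, None)
        if value is not None:
            return str(value)
    return repr(record)


def _sorted_hits(hits: Iterable[Tuple[Any, int]]) -> List[Tuple[Any, int]]:
    return sorted(
        hits,
        key=lambda pair: (
            pair[0].location.start,
            pair[0].location.end,
            _record_key(pair[0]),
        ),
    )


def find_overlaps(
    cnv: GenomicInterval,
    features: "Sequence[Any] | FeatureIndex",
) -> List[Tuple[Any, int]]:
    """All located records overlapping ``cnv`` by >= 1 bp, with overlap lengths.

    ``features`` is either a plain sequence of records carrying a
    ``.location`` attribute (scanned linearly) or a prebuilt
    :class:`FeatureIndex`.  The result is deterministic: sorted by feature
    start, then end, then record identifier.
    """
    if isinstance(features, FeatureIndex):
        return features.query(cnv)
    hits = []
    for record in features:
        bp = overlap_length(cnv, record.location)
        if bp >= 1:
            hits.append((record, bp))
    return _sorted_hits(hits)


class FeatureIndex:
    """Per-chromosome interval-tree index over located records.

    Query semantics are identical to the linear scan in
    :func:`find_overlaps`; the brute-force equivalence of the two paths is
    exercised by the test suite.
    """

    def __init__(self, records: Iterable[Any] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._records: List[Any] = []
        for record in records:
            self.add(record)

    def add(self, record: Any) -> None:
        loc: GenomicInterval = record.location
        tree = self._trees.setdefault(loc.chrom, IntervalTree())
        tree.addi(loc.start, loc.end, record)
        self._records.append(record)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    def query(self, interval: GenomicInterval) -> List[Tuple[Any, int]]:
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        hits = []
        for hit in tree.overlap(interval.start, interval.end):
            record = hit.data
            bp = overlap_length(interval, record.location)
            if bp >= 1:
                hits.append((record, bp))
        return _sorted_hits(hits)
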