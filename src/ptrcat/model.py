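"""Core domain types shared across the pipeline.

All coordinates are 0-based, half-open ([start, end)) everywhere inside the
package; conversion to the 1-based inclusive convention of TRF ``.dat`` files
and catalog TSVs happens only at the I/O boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "GenomicInterval",
    "Transcript",
    "MergedRegion",
    "TRCandidate",
    "FlankPair",
    "TargetPlacement",
    "PlacementStatus",
    "PolymorphismMeasurement",
    "CatalogRecord",
    "QUALITY_RANK",
]

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    """Reverse complement with IUPAC ambiguity codes preserved."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strictly non-empty genomic interval, 0-based half-open."""

    sequence_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.sequence_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.sequence_id == other.sequence_id
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.sequence_id != other.sequence_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    gene_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class MergedRegion:
    """Union of overlapping same-strand transcripts on one sequence."""

    interval: GenomicInterval
    member_transcripts: tuple[str, ...]


@dataclass(frozen=True)
class TRCandidate:
    """A candidate tandem repeat on the reference genome.

    ``unit_count_ref`` is the (possibly fractional) copy number reported by the
    detector; ``sequence`` is the actual locus sequence, which may diverge from
    ``motif`` repeated for fuzzy repeats.
    """

    interval: GenomicInterval
    motif: str
    unit_count_ref: float
    sequence: str
    source_tools: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(self.motif) < 1:
            raise ValueError("motif must be non-empty")
        if self.unit_count_ref <= 0:
            raise ValueError("unit_count_ref must be positive")
        if len(self.sequence) != self.interval.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != interval length "
                f"{self.interval.length}"
            )

    def with_tools(self, tools: frozenset[str]) -> "TRCandidate":
        return replace(self, source_tools=tools)


@dataclass(frozen=True)
class FlankPair:
    """The two anchoring flanks of a reference TR (up to ``flank_bp`` each)."""

    left: str
    right: str
    tr_id: str = ""
    clipped_left: bool = False
    clipped_right: bool = False


class PlacementStatus:
    PLACED = "PLACED"
    ONE_FLANK_ONLY = "ONE_FLANK_ONLY"
    WRONG_ORDER = "WRONG_ORDER"
    MULTI_MAPPED = "MULTI_MAPPED"
    LOW_IDENTITY = "LOW_IDENTITY"
    COMBINED_BELOW_450 = "COMBINED_BELOW_450"

    ALL = (PLACED, ONE_FLANK_ONLY, WRONG_ORDER, MULTI_MAPPED,
           LOW_IDENTITY, COMBINED_BELOW_450)


@dataclass(frozen=True)
class TargetPlacement:
    """Outcome of anchoring one TR's flanks on one target sequence.

    A zero-length enclosed segment (flanks adjacent: complete repeat loss) is a
    legal PLACED result; since :class:`GenomicInterval` forbids empty
    intervals, the raw span is kept as a pair and ``target_interval`` is None
    in that case.
    """

    status: str
    target_sequence_id: str = ""
    target_span: Optional[tuple[int, int]] = None
    target_sequence: str = ""
    identity_left: float = 0.0
    identity_right: float = 0.0
    matches_total: int = 0

    @property
    def target_interval(self) -> Optional[GenomicInterval]:
        if self.target_span is None or self.target_span[0] >= self.target_span[1]:
            return None
        return GenomicInterval(self.target_sequence_id, *self.target_span)


QUALITY_RANK = {"high": 2, "medium": 1, "low": 0}


@dataclass(frozen=True)
class PolymorphismMeasurement:
    """Result of the two alignment tests on one (reference TR, target locus)."""

    delta_units: int
    units_target: int
    matches_aln1: int
    matches_aln2: int
    quality: str
    target_genome: str = ""
    target_sequence_id: str = ""
    target_span: tuple[int, int] = (0, 0)
    test1_passed: bool = True
    test2_passed: bool = True

    def __post_init__(self) -> None:
        if self.quality not in QUALITY_RANK:
            raise ValueError(f"quality must be high/medium/low, got {self.quality!r}")
        if self.units_target < 0:
            raise ValueError("units_target must be >= 0")

    @property
    def target_interval(self) -> Optional[GenomicInterval]:
        if self.target_span[0] >= self.target_span[1]:
            return None
        return GenomicInterval(self.target_sequence_id, *self.target_span)


@dataclass(frozen=True)
class CatalogRecord:
    """A finished catalog entry: one polymorphic TR with provenance."""

    tr: TRCandidate
    best: PolymorphismMeasurement
    all_measurements: tuple[PolymorphismMeasurement, ...]
    polymorphic_genomes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.best not in self.all_measurements:
            raise ValueError("best measurement must be among all_measurements")
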