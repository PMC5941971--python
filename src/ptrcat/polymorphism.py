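"""Measuring repeat expansion/contraction between a reference TR and its
placed target locus.

Let S be the shorter and T the longer of (reference TR sequence, enclosed
target segment), n = |S|, m = |T|. Two tests decide whether the pair is a
credible copy-number variant of one locus:

* Test 1 — S must be an approximate prefix of T: H(S, T[0:n]) <= k with
  k = floor(0.1 * n), where H is the Sellers evolutionary distance
  (leftmost-aligned, truncated edit distance).
* Test 2 — the residual T[n:m] must continue the same repeat: H(S, T[n:m])
  <= k' with k' = floor(0.1 * min(n, m - n - 1)).

The unit count of the longer string is then estimated as the rounded ratio of
the total number of matched bases in the two alignments over the motif size.
When the residual is longer than S, the second alignment is iterated over
successive length-n chunks of the residual and the matches summed; for
residuals shorter than S (the dominant case) this is a single alignment of
the truncated pair. A third test grades the measurement (high/medium/low) by
the mutual consistency of the two alignments' matched spans.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .align import AlignmentResult, evolutionary_distance, global_align
from .model import (
    PolymorphismMeasurement,
    QUALITY_RANK,
    TargetPlacement,
    TRCandidate,
)

__all__ = [
    "TestThresholds",
    "thresholds_for",
    "test1",
    "test2",
    "estimate_target_units",
    "classify_quality",
    "measure_polymorphism",
    "select_best_measurement",
    "round_half_away",
]


def round_half_away(x: float) -> int:
    """Round half away from zero (so 2.5 -> 3 and -2.5 -> -3)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class TestThresholds:
    k: int
    k_prime: int


def thresholds_for(n: int, m: int) -> TestThresholds:
    """Mismatch budgets: k = floor(0.1 n); k' = floor(0.1 min(n, m - n - 1)).

    The second formula is applied verbatim even though the residual has
    length m - n (the printed off-by-one); for m <= n + 1 it degenerates to
    zero tolerance.
    """
    if m < n:
        raise ValueError("caller must orient so that n <= m")
    k = n // 10
    k_prime = max(0, min(n, m - n - 1)) // 10
    return TestThresholds(k=k, k_prime=k_prime)


def test1(S: str, T: str, thresholds: TestThresholds) -> bool:
    """Is S an approximate prefix of T (within k edits)?"""
    n = len(S)
    return evolutionary_distance(S, T[:n]) <= thresholds.k


def test2(S: str, T: str, thresholds: TestThresholds) -> bool:
    """Does the residual T[n:] continue the repeat (within k' edits)?

    Vacuously true when there is no residual. H's truncation rule limits the
    comparison to the leading min(n, m - n) bases.
    """
    residual = T[len(S):]
    if not residual:
        return True
    return evolutionary_distance(S, residual) <= thresholds.k_prime


def estimate_target_units(matches_aln1: int, matches_aln2: int,
                          motif_size: float) -> int:
    """Units of the longer string: rounded total matches over motif size."""
    if motif_size < 2:
        raise ValueError("motif_size must be >= 2 (size-1 motifs are filtered)")
    return round_half_away((matches_aln1 + matches_aln2) / motif_size)


def _align_pair(S: str, T: str) -> tuple[AlignmentResult,
                                         Optional[AlignmentResult], int, int]:
    """First alignment (S vs T prefix) and chunked second alignment over the
    residual; returns (aln1, first-chunk aln2 with subject span shifted onto
    T, total matches1, total matches2)."""
    n = len(S)
    aln1 = global_align(S, T[:n])
    matches2 = 0
    first_aln2: Optional[AlignmentResult] = None
    pos = n
    while pos < len(T):
        chunk = T[pos:pos + n]
        aln = global_align(S[:len(chunk)], chunk)
        if first_aln2 is None:
            first_aln2 = AlignmentResult(
                matches=aln.matches, score=aln.score,
                query_span=aln.query_span,
                subject_span=(aln.subject_span[0] + pos,
                              aln.subject_span[1] + pos),
            )
        matches2 += aln.matches
        pos += n
    return aln1, first_aln2, aln1.matches, matches2


def classify_quality(aln1: AlignmentResult,
                     aln2: Optional[AlignmentResult],
                     motif_size: float,
                     small_gap: Optional[int] = None) -> str:
    """Grade the mutual consistency of the two alignments.

    high: the matched spans on T are adjacent and the matched spans on S
    overlap. medium: a small gap (default: one motif length) separates the T
    spans, the S spans still overlap, and — for motifs up to 4 bp with a
    second alignment shorter than 8 bp — more than half of the shorter
    aligned string is matched. Anything else, including disjoint S spans,
    is low.
    """
    if aln2 is None or aln2.matches == 0:
        return "low"
    if small_gap is None:
        small_gap = max(1, int(round(motif_size)))
    gap_t = aln2.subject_span[0] - aln1.subject_span[1]
    s_overlap = (min(aln1.query_span[1], aln2.query_span[1])
                 - max(aln1.query_span[0], aln2.query_span[0]))
    if not s_overlap > 0:
        return "low"
    if gap_t == 0:
        return "high"
    if 0 < gap_t <= small_gap:
        aln2_len = max(aln2.query_span[1] - aln2.query_span[0],
                       aln2.subject_span[1] - aln2.subject_span[0])
        if motif_size <= 4 and aln2_len < 8:
            shorter = min(aln2.query_span[1] - aln2.query_span[0],
                          aln2.subject_span[1] - aln2.subject_span[0])
            if not aln2.matches > 0.5 * shorter:
                return "low"
        return "medium"
    return "low"


def measure_polymorphism(tr: TRCandidate, placement: TargetPlacement,
                         target_genome: str = "",
                         small_gap: Optional[int] = None,
                         ) -> PolymorphismMeasurement:
    """Run the full measurement on one placed (reference TR, target) pair.

    The pair is oriented so the shorter string plays S; delta is positive for
    target expansion, negative for contraction. A failed Test 1 or Test 2
    forces quality low. Equal-length pairs are non-polymorphic by
    definition (substitution-only variation is not a repeat-number change).
    """
    if placement.status != "PLACED":
        raise ValueError("measure_polymorphism requires a PLACED placement")
    S_ref = tr.sequence
    T_tgt = placement.target_sequence
    units_ref = round_half_away(tr.unit_count_ref)
    motif_size = float(len(tr.motif))
    span = placement.target_span or (0, 0)

    if len(T_tgt) == 0:
        # flanks adjacent on the target: complete loss of the repeat
        return PolymorphismMeasurement(
            delta_units=-units_ref, units_target=0,
            matches_aln1=0, matches_aln2=0, quality="high",
            target_genome=target_genome,
            target_sequence_id=placement.target_sequence_id,
            target_span=span)

    if len(T_tgt) == len(S_ref):
        th = thresholds_for(len(S_ref), len(T_tgt))
        t1 = test1(S_ref, T_tgt, th)
        aln1 = global_align(S_ref, T_tgt)
        return PolymorphismMeasurement(
            delta_units=0, units_target=units_ref,
            matches_aln1=aln1.matches, matches_aln2=0,
            quality="high" if t1 else "low",
            target_genome=target_genome,
            target_sequence_id=placement.target_sequence_id,
            target_span=span, test1_passed=t1, test2_passed=True)

    expanded = len(T_tgt) > len(S_ref)
    S, T = (S_ref, T_tgt) if expanded else (T_tgt, S_ref)
    th = thresholds_for(len(S), len(T))
    t1 = test1(S, T, th)
    t2 = test2(S, T, th)
    aln1, aln2, m1, m2 = _align_pair(S, T)

    units_long = estimate_target_units(m1, m2, motif_size)
    if expanded:
        units_target = units_long
    else:
        # the target is the fully matched prefix; its units come from aln1
        units_target = round_half_away(m1 / motif_size)
    units_target = max(0, units_target)
    delta = units_target - units_ref

    if not (t1 and t2):
        quality = "low"
    else:
        quality = classify_quality(aln1, aln2, motif_size, small_gap)
    return PolymorphismMeasurement(
        delta_units=delta, units_target=units_target,
        matches_aln1=m1, matches_aln2=m2, quality=quality,
        target_genome=target_genome,
        target_sequence_id=placement.target_sequence_id,
        target_span=span, test1_passed=t1, test2_passed=t2)


def select_best_measurement(
    measurements: Sequence[PolymorphismMeasurement],
) -> PolymorphismMeasurement:
    """Rank by quality (high > medium > low), then by decreasing |delta|,
    then leftmost target location; return the top measurement."""
    if not measurements:
        raise ValueError("select_best_measurement requires >= 1 measurement")
    return min(
        measurements,
        key=lambda m: (-QUALITY_RANK[m.quality], -abs(m.delta_units),
                       m.target_sequence_id, m.target_span),
    )
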