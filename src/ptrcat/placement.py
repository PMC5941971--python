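"""Locating a reference TR on a target sequence via its flanking regions.

The TR sequence itself is a poor anchor (repeats are not unique and their
length varies between genomes), so the locus is found by locally aligning the
two fixed-size flanks and taking the target segment strictly between them.
A placement is rejected, with a typed status, when only one flank aligns
well, when the flanks land in the wrong order, when a flank has multiple
near-best placements (segmental-duplication ambiguity), or when the combined
match count falls below the 450-of-500 rule.
"""
from __future__ import annotations

from .align import LocalHit, local_align
from .model import FlankPair, PlacementStatus, TargetPlacement, TRCandidate

__all__ = [
    "extract_flanks",
    "place_flanks",
    "DEFAULT_FLANK_BP",
    "MIN_IDENTITY_PCT",
    "COMBINED_MATCH_FRACTION",
]

DEFAULT_FLANK_BP = 250
MIN_IDENTITY_PCT = 90.0
# at least 450 of the 500 flank bases must be matched; scaled for clipped flanks
COMBINED_MATCH_FRACTION = 0.9
# a second hit counts as an ambiguous mapping when its score is within this
# fraction of the best qualifying hit's score
NEAR_BEST_BAND = 0.05


def extract_flanks(tr: TRCandidate, reference_sequence: str,
                   flank_bp: int = DEFAULT_FLANK_BP) -> FlankPair:
    """The up-to-``flank_bp`` bases on either side of the TR on its reference
    sequence; flanks shorter than ``flank_bp`` (locus near a sequence end)
    are clip-flagged."""
    start, end = tr.interval.start, tr.interval.end
    left = reference_sequence[max(0, start - flank_bp):start]
    right = reference_sequence[end:end + flank_bp]
    return FlankPair(
        left=left, right=right,
        tr_id=f"{tr.interval.sequence_id}:{start}-{end}",
        clipped_left=len(left) < flank_bp,
        clipped_right=len(right) < flank_bp,
    )


def _qualifying_hits(flank: str, target: str,
                     min_identity: float) -> list[LocalHit]:
    """Hits with identity >= threshold, restricted to the near-best band."""
    hits = [h for h in local_align(flank, target)
            if h.identity_pct >= min_identity]
    if not hits:
        return []
    best = hits[0].score
    return [h for h in hits if h.score >= best * (1 - NEAR_BEST_BAND)]


def place_flanks(flanks: FlankPair, target_sequence: str,
                 target_sequence_id: str = "target",
                 min_identity: float = MIN_IDENTITY_PCT) -> TargetPlacement:
    """Place a flank pair on a target sequence.

    PLACED requires exactly one qualifying hit per flank, left before right,
    both at >= 90% identity and with combined matches covering at least 90%
    of the available flank bases. The enclosed segment boundaries are the
    hits' ends extrapolated to the full flank extents, so terminal
    substitutions trimmed by the local alignment do not shift the repeat
    boundary; a zero-length segment (flanks adjacent) means complete loss of
    the repeat in the target.
    """
    if len(flanks.left) < 20 or len(flanks.right) < 20:
        return TargetPlacement(status=PlacementStatus.LOW_IDENTITY,
                               target_sequence_id=target_sequence_id)
    hits_l = _qualifying_hits(flanks.left, target_sequence, min_identity)
    hits_r = _qualifying_hits(flanks.right, target_sequence, min_identity)

    if not hits_l and not hits_r:
        return TargetPlacement(status=PlacementStatus.LOW_IDENTITY,
                               target_sequence_id=target_sequence_id)
    if not hits_l or not hits_r:
        only = hits_l or hits_r
        return TargetPlacement(status=PlacementStatus.ONE_FLANK_ONLY,
                               target_sequence_id=target_sequence_id,
                               identity_left=hits_l[0].identity_pct if hits_l else 0.0,
                               identity_right=hits_r[0].identity_pct if hits_r else 0.0,
                               matches_total=only[0].matches)
    if len(hits_l) > 1 or len(hits_r) > 1:
        return TargetPlacement(status=PlacementStatus.MULTI_MAPPED,
                               target_sequence_id=target_sequence_id)

    hl, hr = hits_l[0], hits_r[0]
    # extrapolate to the flank extremities (boundaries adjacent to the TR)
    left_boundary = hl.subject_end + (len(flanks.left) - hl.query_end)
    right_boundary = hr.subject_start - hr.query_start
    if right_boundary < left_boundary:
        return TargetPlacement(status=PlacementStatus.WRONG_ORDER,
                               target_sequence_id=target_sequence_id,
                               identity_left=hl.identity_pct,
                               identity_right=hr.identity_pct,
                               matches_total=hl.matches + hr.matches)

    available = len(flanks.left) + len(flanks.right)
    required = int(round(COMBINED_MATCH_FRACTION * available))
    matches_total = hl.matches + hr.matches
    if matches_total < required:
        return TargetPlacement(status=PlacementStatus.COMBINED_BELOW_450,
                               target_sequence_id=target_sequence_id,
                               identity_left=hl.identity_pct,
                               identity_right=hr.identity_pct,
                               matches_total=matches_total)

    right_boundary = min(right_boundary, len(target_sequence))
    left_boundary = max(0, left_boundary)
    return TargetPlacement(
        status=PlacementStatus.PLACED,
        target_sequence_id=target_sequence_id,
        target_span=(left_boundary, right_boundary),
        target_sequence=target_sequence[left_boundary:right_boundary],
        identity_left=hl.identity_pct,
        identity_right=hr.identity_pct,
        matches_total=matches_total,
    )
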