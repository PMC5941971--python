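"""Consolidation of TR candidates from multiple detectors.

Covers exact duplicate removal (merging tool provenance), interval Jaccard,
the iterative >50%-overlap removal rule, and the low-quality filters applied
when finishing a catalog (N stretches, single-base motifs, duplicate spans,
spurious detector output).
"""
from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal

from .model import GenomicInterval, TRCandidate

__all__ = [
    "CandidatePool",
    "RejectReason",
    "dedupe_exact",
    "jaccard_coefficient",
    "iterative_overlap_removal",
    "apply_low_quality_filters",
]

_N_STRETCH = re.compile(r"N{10,}")


@dataclass(frozen=True)
class CandidatePool:
    candidates: tuple[TRCandidate, ...]
    per_tool_counts: dict[str, int]


class RejectReason:
    N_STRETCH = "N_STRETCH"
    MOTIF_1 = "MOTIF_1"
    DUPLICATE_SPAN = "DUPLICATE_SPAN"
    SPURIOUS = "SPURIOUS"


def dedupe_exact(candidates: Iterable[TRCandidate]) -> CandidatePool:
    """Remove exact duplicates, unioning tool provenance.

    Two candidates are identical when they agree on interval, motif and unit
    count; the survivor carries the union of the source tools.
    """
    per_tool: Counter[str] = Counter()
    merged: dict[tuple, TRCandidate] = {}
    for c in candidates:
        for tool in c.source_tools:
            per_tool[tool] += 1
        key = (c.interval, c.motif, round(c.unit_count_ref, 6))
        prev = merged.get(key)
        if prev is None:
            merged[key] = c
        else:
            merged[key] = prev.with_tools(prev.source_tools | c.source_tools)
    return CandidatePool(candidates=tuple(merged.values()),
                         per_tool_counts=dict(per_tool))


def jaccard_coefficient(a: GenomicInterval, b: GenomicInterval) -> float:
    """Intersection-over-union of the base sets of two intervals."""
    if a.sequence_id != b.sequence_id:
        return 0.0
    inter = a.intersection_length(b)
    union = a.length + b.length - inter
    return inter / union


def _overlap_violates(a: TRCandidate, b: TRCandidate,
                      mode: Literal["shorter", "both"]) -> float:
    """Overlap fraction of the pair (wrt the shorter member), 0 if not violating."""
    inter = a.interval.intersection_length(b.interval)
    if inter == 0:
        return 0.0
    shorter = min(a.interval.length, b.interval.length)
    longer = max(a.interval.length, b.interval.length)
    frac = inter / shorter
    if mode == "shorter":
        return frac if frac > 0.5 else 0.0
    return frac if (frac > 0.5 and inter / longer > 0.5) else 0.0


def _removal_victim(a: TRCandidate, b: TRCandidate) -> TRCandidate:
    """Which of an overlapping pair is removed: the shorter; tie by size ->
    the larger motif; tie again -> the rightmost."""
    if a.interval.length != b.interval.length:
        return a if a.interval.length < b.interval.length else b
    if len(a.motif) != len(b.motif):
        return a if len(a.motif) > len(b.motif) else b
    return max(a, b, key=lambda c: (c.interval.start, c.interval.end, c.motif))


def iterative_overlap_removal(
    candidates: Iterable[TRCandidate],
    mode: Literal["shorter", "both"] = "shorter",
) -> list[TRCandidate]:
    """Iteratively remove heavily overlapping TR until a fixed point.

    Rule: if two TR overlap by more than 50% of their size, the shorter (tie
    by size: the one with the larger motif) is removed. ``mode`` selects
    whether "their size" means the shorter member's size (default) or both
    members' sizes. Pairs are handled in order of decreasing overlap
    fraction, ties broken leftmost, so the output is deterministic.
    """
    alive = list(candidates)
    while True:
        worst = None
        worst_key = None
        for i in range(len(alive)):
            for j in range(i + 1, len(alive)):
                frac = _overlap_violates(alive[i], alive[j], mode)
                if frac == 0.0:
                    continue
                a, b = alive[i], alive[j]
                key = (-frac,
                       min(a.interval.start, b.interval.start),
                       max(a.interval.start, b.interval.start))
                if worst_key is None or key < worst_key:
                    worst_key = key
                    worst = (a, b)
        if worst is None:
            return alive
        alive.remove(_removal_victim(*worst))


def _motif_locus_identity(candidate: TRCandidate) -> float:
    """Best fraction of locus bases matching a tiling of the motif, over all
    cyclic frames of the motif."""
    seq = candidate.sequence
    motif = candidate.motif
    p = len(motif)
    best = 0.0
    for offset in range(p):
        hits = sum(1 for i, base in enumerate(seq)
                   if base == motif[(i + offset) % p])
        best = max(best, hits / len(seq))
    return best


def apply_low_quality_filters(
    candidates: Iterable[TRCandidate],
    min_motif_identity: float = 0.5,
) -> tuple[list[TRCandidate], list[tuple[TRCandidate, str]]]:
    """Reject low-quality candidates with machine-readable reasons.

    Rejections: a stretch of >= 10 consecutive N in the locus sequence;
    motif of size 1; spurious detector output (unit count < 2 or motif not
    matching the locus at >= ``min_motif_identity`` in any cyclic frame);
    duplicate spans (identical nucleotides with different motif/unit
    parameters) — the candidate whose motif x units best predicts the span
    length survives, tie broken toward the smaller motif.
    """
    kept: list[TRCandidate] = []
    rejected: list[tuple[TRCandidate, str]] = []
    survivors_by_span: dict[tuple[str, int, int], TRCandidate] = {}

    prelim: list[TRCandidate] = []
    for c in candidates:
        if _N_STRETCH.search(c.sequence):
            rejected.append((c, RejectReason.N_STRETCH))
        elif len(c.motif) == 1:
            rejected.append((c, RejectReason.MOTIF_1))
        elif (c.unit_count_ref < 2
              or _motif_locus_identity(c) < min_motif_identity):
            rejected.append((c, RejectReason.SPURIOUS))
        else:
            prelim.append(c)

    def span_fit(c: TRCandidate) -> tuple[float, int]:
        return (abs(len(c.motif) * c.unit_count_ref - c.interval.length),
                len(c.motif))

    for c in prelim:
        span = (c.interval.sequence_id, c.interval.start, c.interval.end)
        prev = survivors_by_span.get(span)
        if prev is None:
            survivors_by_span[span] = c
        elif span_fit(c) < span_fit(prev):
            survivors_by_span[span] = c
            rejected.append((prev, RejectReason.DUPLICATE_SPAN))
        else:
            rejected.append((c, RejectReason.DUPLICATE_SPAN))
    kept = list(survivors_by_span.values())
    return kept, rejected


def write_rejections_tsv(rejected: list[tuple[TRCandidate, str]],
                         path) -> None:
    """Audit log of filtered candidates (id, reason code)."""
    with open(path, "w") as fh:
        fh.write("#seq_id\tstart\tend\tmotif\treason\n")
        for c, reason in rejected:
            iv = c.interval
            fh.write(f"{iv.sequence_id}\t{iv.start + 1}\t{iv.end}\t"
                     f"{c.motif}\t{reason}\n")
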