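"""Built-in mismatch-tolerant tandem-repeat detector.

A seed-and-extend scanner: a seed is an exact adjacent doublet of a motif;
extension proceeds unit by unit, charging Hamming mismatches of each unit
against the seed motif into a single global budget proportional to the span
(``max_mismatch_fraction``). Because the seed is the first motif instance in
the scanning direction, output can legitimately differ between left-to-right
and right-to-left scans — the reason merged genic regions are kept separated
by strand upstream.

This detector lets the pipeline run end to end without external tools; it is
not meant to match TRF/mreps output item for item.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .model import GenomicInterval, TRCandidate

__all__ = ["DetectorParams", "detect_tandem_repeats", "consensus_motif"]


@dataclass(frozen=True)
class DetectorParams:
    min_motif: int = 2
    max_motif: int = 100
    min_units: int = 3
    max_mismatch_fraction: float = 0.15

    def __post_init__(self) -> None:
        if not (1 <= self.min_motif <= self.max_motif):
            raise ValueError("need 1 <= min_motif <= max_motif")
        if self.min_units < 2:
            raise ValueError("min_units must be >= 2")
        if not (0 <= self.max_mismatch_fraction < 0.5):
            raise ValueError("max_mismatch_fraction must be in [0, 0.5)")


def consensus_motif(unit_strings: Iterable[str]) -> str:
    """Per-position majority base over equal-length units; ties go to the
    first unit's base."""
    units = list(unit_strings)
    if not units:
        raise ValueError("need at least one unit")
    p = len(units[0])
    if any(len(u) != p for u in units):
        raise ValueError("units must have equal length")
    out = []
    for pos in range(p):
        counts: dict[str, int] = {}
        for u in units:
            counts[u[pos]] = counts.get(u[pos], 0) + 1
        best = max(counts.values())
        first = units[0][pos]
        if counts[first] == best:
            out.append(first)
        else:
            out.append(max(counts, key=lambda b: (counts[b], b == first)))
    return "".join(out)


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _scan_forward(seq: str, params: DetectorParams,
                  p: int) -> list[tuple[int, int, int]]:
    """All maximal repeat runs of period p as (start, end, mismatches)."""
    L = len(seq)
    frac = params.max_mismatch_fraction
    runs: list[tuple[int, int, int]] = []
    i = 0
    floor_pos = 0  # left edge of territory not claimed by an earlier run
    while i + 2 * p <= L:
        seed = seq[i:i + p]
        if seq[i + p:i + 2 * p] != seed or "N" in seed:
            i += 1
            continue
        # extension is score-driven (match +1, mismatch -2 per base, so a
        # unit with >1/3 mismatches scores negative and random sequence
        # cannot be absorbed), with the global mismatch budget floor(frac * span) as a
        # feasibility constraint on the chosen endpoint
        ends = [(i + 2 * p, 0, 0)]  # (end, cum_mismatch, cum_score)
        cum_mm = cum_score = best_score = 0
        j = i + 2 * p
        while j + p <= L:
            mm = _hamming(seq[j:j + p], seed)
            cum_mm += mm
            cum_score += p - 3 * mm
            ends.append((j + p, cum_mm, cum_score))
            best_score = max(best_score, cum_score)
            if cum_score < best_score - 2 * p:
                break
            j += p
        best_end, best_cum, _ = max(
            (e for e in ends if e[1] <= int(frac * (e[0] - i))),
            key=lambda e: (e[2], e[0]))
        # the seed is only the first *exact* doublet; a mutated unit may
        # precede it — extend left the same way
        starts = [(i, best_cum, 0)]
        cum_mm, cum_score, best_score = best_cum, 0, 0
        k = i
        while k - p >= floor_pos:
            mm = _hamming(seq[k - p:k], seed)
            cum_mm += mm
            cum_score += p - 3 * mm
            starts.append((k - p, cum_mm, cum_score))
            best_score = max(best_score, cum_score)
            if cum_score < best_score - 2 * p:
                break
            k -= p
        start, best_cum, _ = max(
            (s for s in starts if s[1] <= int(frac * (best_end - s[0]))),
            key=lambda s: (s[2], -s[0]))
        units = (best_end - start) // p
        if units >= params.min_units:
            runs.append((start, best_end, best_cum))
            floor_pos = best_end
            i = best_end
        else:
            i += 1
    return runs


def detect_tandem_repeats(
    sequence: str,
    params: DetectorParams = DetectorParams(),
    direction: Literal["left_to_right", "right_to_left"] = "left_to_right",
    sequence_id: str = "seq",
) -> list[TRCandidate]:
    """Detect tandem repeats by seed-and-extend with a mismatch budget.

    ``right_to_left`` scans the reversed sequence and maps the calls back, so
    the seed is taken from the opposite end — reproducing the direction
    sensitivity of seed-based detectors.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    seq = sequence.upper()
    rev = direction == "right_to_left"
    work = seq[::-1] if rev else seq
    L = len(seq)

    raw: list[tuple[int, int, int]] = []  # (start, end, period)
    for p in range(params.min_motif, params.max_motif + 1):
        if 2 * p > len(work):
            break
        for start, end, _cum in _scan_forward(work, params, p):
            raw.append((start, end, p))

    # suppress harmonics: a call whose period is a multiple of a smaller
    # period covering at least the same interval is redundant
    raw.sort(key=lambda r: (r[2], r[0]))
    accepted: list[tuple[int, int, int]] = []
    for start, end, p in raw:
        if any(p % q == 0 and s2 <= start and e2 >= end
               for s2, e2, q in accepted if q < p):
            continue
        accepted.append((start, end, p))

    out: list[TRCandidate] = []
    for start, end, p in accepted:
        if rev:
            start, end = L - end, L - start
        locus = seq[start:end]
        units = [locus[k:k + p] for k in range(0, len(locus) - p + 1, p)]
        motif = consensus_motif(units)
        out.append(TRCandidate(
            interval=GenomicInterval(sequence_id, start, end),
            motif=motif,
            unit_count_ref=float(len(units)),
            sequence=locus,
            source_tools=frozenset({"builtin"}),
        ))
    out.sort(key=lambda c: (c.interval.start, c.interval.end, len(c.motif)))
    return out
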