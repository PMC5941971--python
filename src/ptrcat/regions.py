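"""Input preparation: merge overlapping transcripts per strand and extract
extended sequences for scanning.

Most TR detectors seed on the first occurrence of a motif, so their output
depends on the scanning direction; transcripts coding on opposite strands are
therefore kept separate and merging only joins same-strand overlaps.
"""
from __future__ import annotations

from typing import Iterable, Mapping

from .model import GenomicInterval, MergedRegion, Transcript, reverse_complement

__all__ = [
    "merge_transcripts",
    "extend_interval",
    "extract_sequence",
    "DEFAULT_GENE_PAD",
    "DEFAULT_FLANK_PAD",
    "DEFAULT_EXPANSION_PAD",
]

# pad applied to merged genic regions before TR detection
DEFAULT_GENE_PAD = 1000
# allowance for flanks of TR at gene-image boundaries on targets
DEFAULT_FLANK_PAD = 250
# allowance for repeat expansions pushing a flank past the target boundary
DEFAULT_EXPANSION_PAD = 1250


def merge_transcripts(transcripts: Iterable[Transcript]) -> list[MergedRegion]:
    """Merge transcripts that share >= 1 base, within one sequence and strand.

    Bookended (touching) transcripts are not merged: avoiding double scanning
    only requires joining true overlaps.
    """
    groups: dict[tuple[str, str], list[Transcript]] = {}
    for t in transcripts:
        groups.setdefault((t.interval.sequence_id, t.interval.strand), []).append(t)

    regions: list[MergedRegion] = []
    for (seq_id, strand), members in sorted(groups.items()):
        members.sort(key=lambda t: (t.interval.start, t.interval.end))
        cur_start = cur_end = None
        cur_members: list[str] = []
        for t in members:
            iv = t.interval
            if cur_start is None or iv.start >= cur_end:  # no shared base
                if cur_start is not None:
                    regions.append(MergedRegion(
                        GenomicInterval(seq_id, cur_start, cur_end, strand),
                        tuple(cur_members)))
                cur_start, cur_end = iv.start, iv.end
                cur_members = [t.transcript_id]
            else:
                cur_end = max(cur_end, iv.end)
                cur_members.append(t.transcript_id)
        if cur_start is not None:
            regions.append(MergedRegion(
                GenomicInterval(seq_id, cur_start, cur_end, strand),
                tuple(cur_members)))
    regions.sort(key=lambda r: (r.interval.sequence_id, r.interval.start,
                                r.interval.strand))
    return regions


def extend_interval(interval: GenomicInterval, pad_bp: int,
                    sequence_length: int) -> GenomicInterval:
    """Extend an interval by ``pad_bp`` on both sides, clamped to the sequence."""
    if pad_bp < 0:
        raise ValueError("pad_bp must be >= 0")
    return GenomicInterval(
        interval.sequence_id,
        max(0, interval.start - pad_bp),
        min(sequence_length, interval.end + pad_bp),
        interval.strand,
    )


def extract_sequence(genome: Mapping[str, str],
                     interval: GenomicInterval) -> str:
    """Extract an interval's sequence; '-' strand returns the reverse complement."""
    seq = genome.get(interval.sequence_id)
    if seq is None:
        raise KeyError(f"unknown sequence {interval.sequence_id!r}")
    if interval.end > len(seq):
        raise IndexError(
            f"interval [{interval.start}, {interval.end}) exceeds sequence "
            f"length {len(seq)}")
    sub = seq[interval.start:interval.end]
    return reverse_complement(sub) if interval.strand == "-" else sub
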