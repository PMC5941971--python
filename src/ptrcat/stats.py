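"""Catalog comparison and summary statistics.

Jaccard-threshold catalog matching, stratified PTR/TR ratios with bootstrap
confidence intervals, the signed delta histogram, and the windowed Spearman
correlation between repeat-unit counts and SNP density.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .candidates import jaccard_coefficient
from .model import CatalogRecord, GenomicInterval, TRCandidate
from .polymorphism import round_half_away

__all__ = [
    "RatioStratum",
    "match_catalogs",
    "ptr_tr_ratio",
    "delta_histogram",
    "snp_density_correlation",
]


def _as_interval(item) -> GenomicInterval:
    if isinstance(item, GenomicInterval):
        return item
    if isinstance(item, CatalogRecord):
        return item.tr.interval
    if isinstance(item, TRCandidate):
        return item.interval
    raise TypeError(f"cannot interpret {type(item).__name__} as an interval")


def match_catalogs(source: Sequence, target: Sequence,
                   j: float) -> tuple[int, int]:
    """Count source items with/without a Jaccard-j match in the target.

    Matching is strict (> j), except j = 1.0 where >= is used so identical
    intervals can still match. The roles are asymmetric; counts sum to
    |source|.
    """
    src = [_as_interval(x) for x in source]
    tgt = [_as_interval(x) for x in target]
    by_seq: dict[str, list[GenomicInterval]] = {}
    for iv in tgt:
        by_seq.setdefault(iv.sequence_id, []).append(iv)
    for ivs in by_seq.values():
        ivs.sort(key=lambda iv: iv.start)

    overlap = 0
    for iv in src:
        candidates = by_seq.get(iv.sequence_id, [])
        hit = False
        for other in candidates:
            if other.start >= iv.end:
                break
            jc = jaccard_coefficient(iv, other)
            if (jc >= j) if j >= 1.0 else (jc > j):
                hit = True
                break
        overlap += hit
    return overlap, len(src) - overlap


@dataclass(frozen=True)
class RatioStratum:
    motif_size_class: tuple[int, int]
    repeat_unit_class: tuple[int, int]
    n_tr: int
    n_ptr: int
    ratio: Optional[float]
    ci95: Optional[tuple[float, float]]


def ptr_tr_ratio(
    candidates: Sequence[TRCandidate],
    catalog: Sequence[CatalogRecord],
    motif_bins: Sequence[tuple[int, int]],
    unit_bins: Sequence[tuple[int, int]],
    n_boot: int = 1000,
    seed: int = 0,
) -> list[RatioStratum]:
    """PTR/TR ratio per (motif-size, unit-count) stratum with a percentile
    bootstrap 95% CI over resampled loci.

    Bins are closed ranges [lo, hi]. A stratum without candidates is emitted
    with ratio None. Deterministic under a fixed seed.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    ptr_keys = {(r.tr.interval.sequence_id, r.tr.interval.start,
                 r.tr.interval.end) for r in catalog}
    rng = np.random.default_rng(seed)
    out: list[RatioStratum] = []
    for mlo, mhi in motif_bins:
        for ulo, uhi in unit_bins:
            members = [c for c in candidates
                       if mlo <= len(c.motif) <= mhi
                       and ulo <= round_half_away(c.unit_count_ref) <= uhi]
            n_tr = len(members)
            if n_tr == 0:
                out.append(RatioStratum((mlo, mhi), (ulo, uhi), 0, 0,
                                        None, None))
                continue
            flags = np.array(
                [(c.interval.sequence_id, c.interval.start,
                  c.interval.end) in ptr_keys for c in members], dtype=float)
            n_ptr = int(flags.sum())
            resampled = rng.integers(0, n_tr, size=(n_boot, n_tr))
            boot = flags[resampled].mean(axis=1)
            lo, hi = np.percentile(boot, [2.5, 97.5])
            ratio = n_ptr / n_tr
            ci = (min(float(lo), ratio), max(float(hi), ratio))
            out.append(RatioStratum((mlo, mhi), (ulo, uhi), n_tr, n_ptr,
                                    ratio, ci))
    return out


def delta_histogram(catalog: Iterable[CatalogRecord]) -> dict[int, int]:
    """Counts of signed unit-count deltas (best measurement per record)."""
    return dict(Counter(rec.best.delta_units for rec in catalog))


def snp_density_correlation(
    catalog: Sequence[CatalogRecord],
    snp_positions: dict[str, Sequence[int]],
    window_bp: int,
    regions: Optional[Sequence[GenomicInterval]] = None,
) -> tuple[float, float]:
    """Spearman correlation between per-window mean repeat-unit count and
    per-window SNP count.

    Windows are non-overlapping, left-aligned to each region's start;
    partial trailing windows are dropped. Windows containing no catalog
    entry are skipped (the mean unit count is undefined there). Raises
    ValueError with fewer than 3 usable windows.
    """
    if not (5000 <= window_bp <= 50000):
        raise ValueError("window_bp must be within [5000, 50000]")
    if regions is None:
        span_end: dict[str, int] = {}
        for rec in catalog:
            iv = rec.tr.interval
            span_end[iv.sequence_id] = max(span_end.get(iv.sequence_id, 0),
                                           iv.end)
        for seq_id, positions in snp_positions.items():
            if positions:
                span_end[seq_id] = max(span_end.get(seq_id, 0),
                                       max(positions) + 1)
        regions = [GenomicInterval(s, 0, e) for s, e in span_end.items() if e > 0]

    unit_means: list[float] = []
    snp_counts: list[int] = []
    for region in regions:
        snps = np.asarray(snp_positions.get(region.sequence_id, ()), dtype=int)
        recs = [r for r in catalog
                if r.tr.interval.sequence_id == region.sequence_id]
        for wstart in range(region.start, region.end - window_bp + 1,
                            window_bp):
            wend = wstart + window_bp
            units = [round_half_away(r.tr.unit_count_ref) for r in recs
                     if wstart <= r.tr.interval.start < wend]
            if not units:
                continue
            unit_means.append(float(np.mean(units)))
            snp_counts.append(int(((snps >= wstart) & (snps < wend)).sum()))
    if len(unit_means) < 3:
        raise ValueError("need at least 3 non-empty windows")
    rho, p = sps.spearmanr(unit_means, snp_counts)
    return float(rho), float(p)
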