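"""Assembling the final catalog and tracing its provenance.

A TR enters the catalog only when its best measurement across all target
genomes is of high or medium quality AND shows a non-zero unit-count delta;
low-quality measurements never contribute. Provenance summaries count, at a
Jaccard threshold j, how many catalog entries trace back to a single
discovery tool (or target genome) versus several — the statistic that
justifies a multi-tool discovery phase.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .candidates import jaccard_coefficient
from .model import CatalogRecord, PolymorphismMeasurement, TRCandidate
from .polymorphism import select_best_measurement

__all__ = ["ProvenanceSummary", "build_catalog", "provenance_summary"]


@dataclass(frozen=True)
class ProvenanceSummary:
    per_tool_ptr_counts: dict[str, int]
    per_genome_ptr_counts: dict[str, int]
    single_tool: int
    multi_tool: int
    single_genome: int
    multi_genome: int
    jaccard_threshold: float


def build_catalog(
    measured: Iterable[tuple[TRCandidate,
                             Mapping[str, Sequence[PolymorphismMeasurement]]]],
) -> list[CatalogRecord]:
    """Build catalog records from per-candidate, per-genome measurements.

    ``measured`` yields (candidate, {genome: measurements}) pairs. Each
    genome's own best measurement decides whether that genome shows the
    polymorphism; the record-level best is selected across all measurements
    by the same ranking, and the record is emitted only if that best is
    high/medium quality with delta != 0.
    """
    records: list[CatalogRecord] = []
    for tr, by_genome in measured:
        all_ms: list[PolymorphismMeasurement] = []
        polymorphic = set()
        for genome, ms in by_genome.items():
            if not ms:
                continue
            all_ms.extend(ms)
            gbest = select_best_measurement(list(ms))
            if gbest.quality in ("high", "medium") and gbest.delta_units != 0:
                polymorphic.add(genome)
        if not all_ms:
            continue
        best = select_best_measurement(all_ms)
        if best.quality in ("high", "medium") and best.delta_units != 0:
            records.append(CatalogRecord(
                tr=tr, best=best, all_measurements=tuple(all_ms),
                polymorphic_genomes=frozenset(polymorphic)))
    return records


def _matches_at(a, b, j: float) -> bool:
    jc = jaccard_coefficient(a, b)
    return jc >= j if j >= 1.0 else jc > j


def provenance_summary(
    catalog: Sequence[CatalogRecord],
    j: float,
    tool_candidates: Optional[Mapping[str, Sequence[TRCandidate]]] = None,
) -> ProvenanceSummary:
    """Attribute each catalog entry to discovery tools and target genomes.

    With ``tool_candidates`` (raw per-tool candidate lists), a record is
    attributed to every tool owning a candidate whose interval matches the
    record's at Jaccard threshold j (strict >, except >= at j = 1.0);
    otherwise the record's own merged source_tools are used. Genome
    attribution always uses the record's polymorphic_genomes.
    """
    if not (0.0 < j <= 1.0):
        raise ValueError("j must be in (0, 1]")
    per_tool: dict[str, int] = {}
    per_genome: dict[str, int] = {}
    single_tool = multi_tool = 0
    single_genome = multi_genome = 0
    for rec in catalog:
        if tool_candidates is not None:
            tools = {tool for tool, cands in tool_candidates.items()
                     if any(_matches_at(rec.tr.interval, c.interval, j)
                            for c in cands)}
        else:
            tools = set(rec.tr.source_tools)
        for t in tools:
            per_tool[t] = per_tool.get(t, 0) + 1
        if len(tools) >= 2:
            multi_tool += 1
        else:
            single_tool += 1
        genomes = rec.polymorphic_genomes
        for g in genomes:
            per_genome[g] = per_genome.get(g, 0) + 1
        if len(genomes) >= 2:
            multi_genome += 1
        else:
            single_genome += 1
    return ProvenanceSummary(
        per_tool_ptr_counts=per_tool, per_genome_ptr_counts=per_genome,
        single_tool=single_tool, multi_tool=multi_tool,
        single_genome=single_genome, multi_genome=multi_genome,
        jaccard_threshold=j)
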