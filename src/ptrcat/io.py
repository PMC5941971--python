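"""Readers and writers for the standard formats the pipeline touches.

Conventions at the boundary:

* FASTA — via Biopython; sequences are uppercased, IUPAC codes and N kept.
* TRF ``.dat`` — 1-based inclusive coordinates, converted on read.
* generic TR TSV and catalog TSV — 1-based inclusive coordinates, tab
  separated, one documented header line starting with ``#``.
* BED — 0-based half-open, as BED always is.
"""
from __future__ import annotations

import csv
from collections import OrderedDict
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .model import (
    CatalogRecord,
    GenomicInterval,
    PolymorphismMeasurement,
    Transcript,
    TRCandidate,
)

__all__ = [
    "FormatError",
    "read_fasta",
    "write_fasta",
    "parse_trf_dat",
    "read_tr_tsv",
    "write_tr_tsv",
    "read_transcripts_bed",
    "read_snp_bed",
    "write_bed",
    "write_catalog",
    "read_catalog",
]


class FormatError(ValueError):
    """Malformed input file."""


def read_fasta(path: str | Path) -> "OrderedDict[str, str]":
    """Read a FASTA file into an ordered id -> uppercase sequence map."""
    path = Path(path)
    records: "OrderedDict[str, str]" = OrderedDict()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty header")
        if not seq:
            raise FormatError(f"{path}: empty sequence for record {rec.id!r}")
        records[rec.id] = seq
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def parse_trf_dat(path: str | Path) -> list[TRCandidate]:
    """Parse a Tandem Repeats Finder ``.dat`` table.

    Records are whitespace-separated lines of 15 fields following a
    ``Sequence:`` header: start end period copy-number consensus-size %match
    %indel score A C G T entropy motif sequence, with 1-based inclusive
    coordinates. The parser does not deduplicate.
    """
    path = Path(path)
    candidates: list[TRCandidate] = []
    seq_id = ""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("Sequence:"):
                seq_id = line.split(":", 1)[1].strip().split()[0]
                continue
            if line.startswith(("Parameters:", "Tandem Repeats Finder",
                                "Gary Benson", "Program written",
                                "Version")):
                continue
            fields = line.split()
            if len(fields) < 15:
                continue
            try:
                start = int(fields[0])
                end = int(fields[1])
                copy_number = float(fields[3])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-numeric field in record at line {lineno}"
                ) from exc
            motif, sequence = fields[13], fields[14]
            interval = GenomicInterval(seq_id or "unknown", start - 1, end)
            candidates.append(TRCandidate(
                interval=interval, motif=motif.upper(),
                unit_count_ref=copy_number, sequence=sequence.upper(),
                source_tools=frozenset({"TRF"}),
            ))
    return candidates


_TR_TSV_HEADER = "#seq_id\tstart\tend\tstrand\tmotif\tunits\ttools\tsequence"


def write_tr_tsv(candidates: Iterable[TRCandidate], path: str | Path) -> None:
    """Write TR candidates as tab-separated text (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write(_TR_TSV_HEADER + "\n")
        for c in candidates:
            iv = c.interval
            fh.write("\t".join([
                iv.sequence_id, str(iv.start + 1), str(iv.end), iv.strand,
                c.motif, repr(c.unit_count_ref),
                ",".join(sorted(c.source_tools)) or ".",
                c.sequence,
            ]) + "\n")


def read_tr_tsv(path: str | Path) -> list[TRCandidate]:
    candidates: list[TRCandidate] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise FormatError(f"{path}:{lineno}: expected 8 columns")
            seq_id, start, end, strand, motif, units, tools, seq = fields[:8]
            tools_set = frozenset() if tools == "." else frozenset(tools.split(","))
            candidates.append(TRCandidate(
                interval=GenomicInterval(seq_id, int(start) - 1, int(end), strand),
                motif=motif, unit_count_ref=float(units),
                sequence=seq, source_tools=tools_set,
            ))
    return candidates


def read_transcripts_bed(path: str | Path) -> list[Transcript]:
    """Read transcripts from BED: chrom start end name score strand [gene]."""
    transcripts: list[Transcript] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(
                    f"{path}:{lineno}: BED transcripts need >= 6 columns")
            chrom, start, end, name, _score, strand = fields[:6]
            gene = fields[6] if len(fields) > 6 else name
            transcripts.append(Transcript(
                transcript_id=name, gene_id=gene,
                interval=GenomicInterval(chrom, int(start), int(end), strand),
            ))
    return transcripts


def read_snp_bed(path: str | Path) -> dict[str, list[int]]:
    """Read SNP positions (BED start column) grouped by sequence."""
    positions: dict[str, list[int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            positions.setdefault(fields[0], []).append(int(fields[1]))
    for v in positions.values():
        v.sort()
    return positions


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              names: Iterable[str] | None = None) -> None:
    names_list = list(names) if names is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names_list[i] if names_list else f"region_{i}"
            fh.write(f"{iv.sequence_id}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# --- catalog TSV -----------------------------------------------------------
#
# One row per (record, measurement); the record-level fields repeat and the
# best measurement carries is_best=1. Reference coordinates are 1-based
# inclusive; target spans are kept 0-based half-open (they index plain target
# sequences, not genome coordinates).

_CATALOG_COLUMNS = [
    "record_id", "seq_id", "start", "end", "strand", "motif", "units_ref",
    "tools", "tr_sequence", "is_best", "delta_units", "units_target",
    "matches_aln1", "matches_aln2", "quality", "target_genome",
    "target_seq_id", "target_start", "target_end", "test1", "test2",
    "polymorphic_genomes",
]


def write_catalog(records: Iterable[CatalogRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("#" + "\t".join(_CATALOG_COLUMNS) + "\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for rid, rec in enumerate(records):
            iv = rec.tr.interval
            for m in rec.all_measurements:
                writer.writerow([
                    rid, iv.sequence_id, iv.start + 1, iv.end, iv.strand,
                    rec.tr.motif, repr(rec.tr.unit_count_ref),
                    ",".join(sorted(rec.tr.source_tools)) or ".",
                    rec.tr.sequence,
                    1 if m == rec.best else 0,
                    f"{m.delta_units:+d}", m.units_target,
                    m.matches_aln1, m.matches_aln2, m.quality,
                    m.target_genome or ".", m.target_sequence_id or ".",
                    m.target_span[0], m.target_span[1],
                    int(m.test1_passed), int(m.test2_passed),
                    ",".join(sorted(rec.polymorphic_genomes)) or ".",
                ])


def read_catalog(path: str | Path) -> list[CatalogRecord]:
    rows_by_record: "OrderedDict[str, list[dict[str, str]]]" = OrderedDict()
    with open(path) as fh:
        header = fh.readline().lstrip("#").rstrip("\n").split("\t")
        if header != _CATALOG_COLUMNS:
            raise FormatError(f"{path}: unexpected catalog header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            row = dict(zip(header, line.split("\t")))
            rows_by_record.setdefault(row["record_id"], []).append(row)

    records: list[CatalogRecord] = []
    for rows in rows_by_record.values():
        r0 = rows[0]
        tr = TRCandidate(
            interval=GenomicInterval(r0["seq_id"], int(r0["start"]) - 1,
                                     int(r0["end"]), r0["strand"]),
            motif=r0["motif"], unit_count_ref=float(r0["units_ref"]),
            sequence=r0["tr_sequence"],
            source_tools=(frozenset() if r0["tools"] == "."
                          else frozenset(r0["tools"].split(","))),
        )
        measurements = []
        best = None
        for row in rows:
            m = PolymorphismMeasurement(
                delta_units=int(row["delta_units"]),
                units_target=int(row["units_target"]),
                matches_aln1=int(row["matches_aln1"]),
                matches_aln2=int(row["matches_aln2"]),
                quality=row["quality"],
                target_genome="" if row["target_genome"] == "." else row["target_genome"],
                target_sequence_id=("" if row["target_seq_id"] == "."
                                    else row["target_seq_id"]),
                target_span=(int(row["target_start"]), int(row["target_end"])),
                test1_passed=bool(int(row["test1"])),
                test2_passed=bool(int(row["test2"])),
            )
            measurements.append(m)
            if row["is_best"] == "1":
                best = m
        if best is None:
            raise FormatError(f"{path}: record without a best measurement")
        genomes = (frozenset() if r0["polymorphic_genomes"] == "."
                   else frozenset(r0["polymorphic_genomes"].split(",")))
        records.append(CatalogRecord(tr=tr, best=best,
                                     all_measurements=tuple(measurements),
                                     polymorphic_genomes=genomes))
    return records
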