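"""Shared I/O: FASTA, BED-like interval tables, labelled TSV matrices, and
small reporting helpers.

All genomic coordinates are 0-based half-open. Matrices are plain TSV with a
header row of column labels and row labels in the first column; lines
starting with ``#`` are treated as provenance comments and skipped on read.
"""

from __future__ import annotations

import decimal
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError

# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence mapping."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    """Write sequences wrapped at 80 columns, in mapping order."""
    recs = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# Intervals (BED-like TSV: scaffold, start, end, type)

class IntervalSet:
    """Per-scaffold sorted lists of (start, end, type), 0-based half-open."""

    def __init__(self, intervals: Mapping[str, Iterable[tuple[int, int, str]]] | None = None):
        self._by_scaffold: dict[str, list[tuple[int, int, str]]] = {}
        if intervals:
            for scaffold, ivs in intervals.items():
                for start, end, typ in ivs:
                    self.add(scaffold, start, end, typ)

    def add(self, scaffold: str, start: int, end: int, typ: str = "") -> None:
        if not (0 <= start < end):
            raise FormatError(
                f"invalid interval [{start}, {end}) on {scaffold!r}: need 0 <= start < end"
            )
        self._by_scaffold.setdefault(scaffold, []).append((int(start), int(end), typ))
        self._by_scaffold[scaffold].sort()

    def scaffolds(self) -> list[str]:
        return sorted(self._by_scaffold)

    def on(self, scaffold: str) -> list[tuple[int, int, str]]:
        return list(self._by_scaffold.get(scaffold, []))

    def __iter__(self):
        for scaffold in self.scaffolds():
            for iv in self._by_scaffold[scaffold]:
                yield (scaffold, *iv)

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_scaffold.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._by_scaffold == other._by_scaffold

    def total_length(self) -> int:
        return sum(e - s for _, s, e, _ in self)


def read_intervals(path: str | Path) -> IntervalSet:
    ivs = IntervalSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            scaffold, start, end = parts[0], int(parts[1]), int(parts[2])
            typ = parts[3] if len(parts) > 3 else ""
            ivs.add(scaffold, start, end, typ)
    return ivs


def write_intervals(ivs: IntervalSet, path: str | Path, header: Mapping[str, object] | None = None) -> None:
    with open(path, "w") as fh:
        for key, value in (header or {}).items():
            fh.write(f"# {key}={value}\n")
        for scaffold, start, end, typ in ivs:
            fh.write(f"{scaffold}\t{start}\t{end}\t{typ}\n")


# ---------------------------------------------------------------------------
# Labelled matrices

def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        raise FormatError(f"duplicate row labels in {path}")
    if df.columns.has_duplicates:
        raise FormatError(f"duplicate column labels in {path}")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, header: Mapping[str, object] | None = None) -> None:
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise FormatError("matrix row/column labels must be unique")
    with open(path, "w") as fh:
        for key, value in (header or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# Reporting helpers

def proportion(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage with half-up rounding, as printed in genome reports.

    Half-up (not banker's) rounding so that e.g. 386/6,556 prints as 5.9.
    """
    if denominator <= 0:
        raise FormatError("denominator must be a positive integer")
    if numerator < 0:
        raise FormatError("numerator must be non-negative")
    value = decimal.Decimal(100) * decimal.Decimal(numerator) / decimal.Decimal(denominator)
    quantum = decimal.Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=decimal.ROUND_HALF_UP))
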