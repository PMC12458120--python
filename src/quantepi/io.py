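"""Readers/writers for bedGraph, BED and header-bearing TSV tables.

bedGraph dialect: ``track`` definition lines and ``#`` comments are
skipped; fields may be separated by spaces or tabs. Writers emit signal
with 6 decimal places so write-then-read round trips are exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any, Callable

import pandas as pd

from .core import GenomicInterval, QuantTrack, ValidationError

__all__ = [
    "ParseError",
    "read_bedgraph",
    "write_bedgraph",
    "read_bed",
    "write_bed",
    "read_table",
    "ColumnSpec",
]


class ParseError(ValueError):
    """A file line failed to parse; message carries the 1-based line number."""


def _data_lines(path: str | Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            yield lineno, line.split()


def read_bedgraph(
    path: str | Path, chrom_lengths: dict[str, int] | None = None
) -> QuantTrack:
    """Load a bedGraph file into a :class:`QuantTrack`.

    Lines are sorted on load; overlapping intervals or negative values are
    rejected. An empty file yields an empty (valid) track.
    """
    records: list[tuple[str, int, int, float]] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
            value = float(fields[3])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if value < 0:
            raise ValidationError(f"{path}:{lineno}: negative signal {value}")
        records.append((chrom, start, end, value))
    try:
        return QuantTrack.from_records(records, chrom_lengths=chrom_lengths)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_bedgraph(track: QuantTrack, path: str | Path) -> None:
    """Write a track as tab-separated bedGraph with 6-decimal signal."""
    with open(path, "w") as fh:
        for chrom, start, end, value in track.intervals():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6f}\n")


def read_bed(
    path: str | Path, with_name: bool = False
) -> list[GenomicInterval] | list[tuple[GenomicInterval, str]]:
    """Load BED3 (or BED4 when ``with_name``) preserving input order.

    Intervals are 0-based half-open exactly as written; zero-width records
    are rejected.
    """
    out: list = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 fields")
        try:
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if with_name:
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: name column required")
            out.append((iv, fields[3]))
        else:
            out.append(iv)
    return out


def write_bed(
    intervals,
    path: str | Path,
    names: list[str] | None = None,
    scores: list[float] | None = None,
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None:
                fields.append(str(names[i]))
            if scores is not None:
                fields.append(f"{scores[i]:.6g}")
            fh.write("\t".join(fields) + "\n")


@dataclass(frozen=True)
class ColumnSpec:
    """One required table column: name, parser, optional range validator."""

    name: str
    dtype: Callable[[str], Any] = str
    validate: Callable[[Any], bool] | None = None


def read_table(path: str | Path, schema: list[ColumnSpec]) -> pd.DataFrame:
    """Read a header-bearing TSV, enforcing a typed column schema.

    Extra columns are carried through untouched; rows keep file order. A
    header-only file yields an empty frame with the schema's columns.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c.name for c in schema if c.name not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    for col in schema:
        parsed = []
        for row_idx, cell in enumerate(df[col.name]):
            try:
                value = col.dtype(cell)
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"{path}: row {row_idx + 1}, column {col.name!r}: "
                    f"cannot parse {cell!r}"
                ) from exc
            if col.validate is not None and not col.validate(value):
                raise ValidationError(
                    f"{path}: row {row_idx + 1}, column {col.name!r}: "
                    f"value {value!r} out of range"
                )
            parsed.append(value)
        df[col.name] = parsed
    return df
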