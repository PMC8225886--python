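"""Readers and writers for the interval and table formats the pipeline touches.

All coordinates are 0-based, half-open everywhere inside the package;
conversion happens only at format boundaries (narrowPeak stores the summit
as an offset from the interval start, BED6 carries no summit at all and the
interval midpoint is used instead).

Tables are plain TSV with a single header line and required columns
addressed by name; unrecognized columns are carried along untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from .errors import ParseError, SchemaError, ValidationError

__all__ = [
    "Peak",
    "GeneAnchor",
    "PeakCountRecord",
    "ExpressionRecord",
    "read_peaks",
    "write_peaks",
    "read_counts",
    "write_counts",
    "read_tss",
    "write_tss",
    "read_expression",
    "write_expression",
]


@dataclass(frozen=True, order=True)
class Peak:
    """A genomic interval with a summit, the unit being classified.

    ``start``/``end`` are 0-based half-open; ``summit`` is an absolute
    0-based coordinate inside the interval.
    """

    chrom: str
    start: int
    end: int
    name: str
    summit: int
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"peak {self.name!r}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if not (self.start <= self.summit < self.end):
            raise ValidationError(
                f"peak {self.name!r}: summit {self.summit} outside "
                f"[{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneAnchor:
    """A gene reduced to its transcription start site.

    For '+' strand genes the TSS is the annotated start; for '-' strand
    genes it is ``end - 1`` of the annotated interval (the last covered
    base), the standard regulatory-genomics convention.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValidationError(f"gene {self.gene_id!r}: negative TSS {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )


@dataclass(frozen=True)
class PeakCountRecord:
    """Per-peak read counts for the two conditions.

    ``t1`` is the untreated/reference condition, ``t2`` the treated
    comparison; ``lib1``/``lib2`` are the corresponding library sizes.
    """

    peak_name: str
    t1: int
    t2: int
    lib1: int
    lib2: int
    extra: tuple = field(default_factory=tuple, compare=False)

    def __post_init__(self) -> None:
        if self.t1 < 0 or self.t2 < 0:
            raise ValidationError(
                f"counts for {self.peak_name!r}: negative count "
                f"(t1={self.t1}, t2={self.t2})"
            )
        if self.lib1 <= 0 or self.lib2 <= 0:
            raise ValidationError(
                f"counts for {self.peak_name!r}: library sizes must be positive"
            )
        if self.t1 > self.lib1 or self.t2 > self.lib2:
            raise ValidationError(
                f"counts for {self.peak_name!r}: count exceeds library size"
            )


@dataclass(frozen=True)
class ExpressionRecord:
    """Gene-level log2 fold change versus the untreated control."""

    gene_id: str
    log2fc: float
    qvalue: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.log2fc):
            raise ValidationError(f"gene {self.gene_id!r}: non-finite log2fc")
        if self.qvalue is not None and not (0.0 <= self.qvalue <= 1.0):
            raise ValidationError(
                f"gene {self.gene_id!r}: qvalue {self.qvalue} outside [0, 1]"
            )


PeakFormat = Literal["bed", "narrowPeak"]


def _check_unique_names(peaks: Iterable[Peak]) -> None:
    seen: set[str] = set()
    for p in peaks:
        if p.name in seen:
            raise ValidationError(f"duplicate peak name {p.name!r}")
        seen.add(p.name)


def read_peaks(path: str | Path, format: PeakFormat = "narrowPeak") -> list[Peak]:
    """Read a BED6 or ENCODE narrowPeak file into a list of peaks.

    narrowPeak column 10 (summit offset from start) is converted to an
    absolute coordinate; an offset of -1, or a plain BED file, yields the
    interval midpoint (floor). Malformed lines raise :class:`ParseError`
    naming the 1-based line number.
    """
    if format not in ("bed", "narrowPeak"):
        raise ParseError(f"unknown peak format {format!r}")
    min_cols = 10 if format == "narrowPeak" else 4
    peaks: list[Peak] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise ParseError(
                    f"{path.name}:{lineno}: expected >= {min_cols} columns "
                    f"for {format}, found {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path.name}:{lineno}: non-integer coordinate"
                ) from exc
            if end <= start:
                raise ParseError(
                    f"{path.name}:{lineno}: end ({end}) <= start ({start})"
                )
            name = fields[3]
            score: float | None = None
            if len(fields) >= 5 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(
                        f"{path.name}:{lineno}: non-numeric score {fields[4]!r}"
                    ) from exc
            if format == "narrowPeak":
                try:
                    offset = int(fields[9])
                except ValueError as exc:
                    raise ParseError(
                        f"{path.name}:{lineno}: non-integer summit offset"
                    ) from exc
                summit = start + offset if offset >= 0 else (start + end) // 2
                if not (start <= summit < end):
                    raise ParseError(
                        f"{path.name}:{lineno}: summit offset {offset} places "
                        f"summit outside the interval"
                    )
            else:
                summit = (start + end) // 2
            try:
                peaks.append(
                    Peak(chrom=chrom, start=start, end=end, name=name,
                         summit=summit, score=score)
                )
            except ValidationError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from exc
    _check_unique_names(peaks)
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | Path,
                format: PeakFormat = "narrowPeak") -> None:
    """Write peaks as BED6 or 10-column narrowPeak (summit as offset)."""
    path = Path(path)
    with path.open("w") as fh:
        for p in peaks:
            score = 0 if p.score is None else p.score
            if format == "bed":
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{score:g}\t.\n")
            elif format == "narrowPeak":
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{score:g}\t.\t"
                    f"0\t-1\t-1\t{p.summit - p.start}\n"
                )
            else:
                raise ParseError(f"unknown peak format {format!r}")


def _read_table(path: str | Path, required: tuple[str, ...]):
    """Yield (lineno, dict) rows of a headered TSV, checking the schema."""
    path = Path(path)
    with path.open() as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise SchemaError(f"{path.name}: empty file, expected a header line")
        header = header_line.split("\t")
        missing = [c for c in required if c not in header]
        if missing:
            raise SchemaError(
                f"{path.name}: missing required column(s) {', '.join(missing)}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ParseError(
                    f"{path.name}:{lineno}: expected {len(header)} columns, "
                    f"found {len(fields)}"
                )
            yield lineno, dict(zip(header, fields)), header


def read_counts(path: str | Path) -> list[PeakCountRecord]:
    """Read the per-peak two-condition count table.

    Required columns: peak_name, t1, t2, lib1, lib2. Extra columns are
    preserved in ``record.extra`` as (column, value) pairs.
    """
    required = ("peak_name", "t1", "t2", "lib1", "lib2")
    records: list[PeakCountRecord] = []
    for lineno, row, header in _read_table(path, required):
        try:
            ints = {c: int(row[c]) for c in ("t1", "t2", "lib1", "lib2")}
        except ValueError as exc:
            raise ParseError(f"{Path(path).name}:{lineno}: non-integer count") from exc
        extra = tuple((c, row[c]) for c in header if c not in required)
        records.append(PeakCountRecord(peak_name=row["peak_name"], extra=extra, **ints))
    return records


def write_counts(records: Iterable[PeakCountRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("peak_name\tt1\tt2\tlib1\tlib2\n")
        for r in records:
            fh.write(f"{r.peak_name}\t{r.t1}\t{r.t2}\t{r.lib1}\t{r.lib2}\n")


def read_tss(path: str | Path) -> list[GeneAnchor]:
    """Read the TSS table (gene_id, chrom, tss, strand)."""
    genes: list[GeneAnchor] = []
    seen: set[str] = set()
    for lineno, row, _ in _read_table(path, ("gene_id", "chrom", "tss", "strand")):
        try:
            tss = int(row["tss"])
        except ValueError as exc:
            raise ParseError(f"{Path(path).name}:{lineno}: non-integer tss") from exc
        if row["gene_id"] in seen:
            raise ValidationError(f"duplicate gene_id {row['gene_id']!r}")
        seen.add(row["gene_id"])
        genes.append(GeneAnchor(gene_id=row["gene_id"], chrom=row["chrom"],
                                tss=tss, strand=row["strand"]))
    return genes


def write_tss(genes: Iterable[GeneAnchor], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\n")


def read_expression(path: str | Path) -> list[ExpressionRecord]:
    """Read the expression table (gene_id, log2fc, optional qvalue)."""
    records: list[ExpressionRecord] = []
    for lineno, row, header in _read_table(path, ("gene_id", "log2fc")):
        try:
            log2fc = float(row["log2fc"])
        except ValueError as exc:
            raise ParseError(f"{Path(path).name}:{lineno}: non-numeric log2fc") from exc
        qvalue: float | None = None
        if "qvalue" in header and row["qvalue"] not in ("", "NA", "."):
            try:
                qvalue = float(row["qvalue"])
            except ValueError as exc:
                raise ParseError(
                    f"{Path(path).name}:{lineno}: non-numeric qvalue"
                ) from exc
        records.append(ExpressionRecord(gene_id=row["gene_id"], log2fc=log2fc,
                                        qvalue=qvalue))
    return records


def write_expression(records: Iterable[ExpressionRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_id\tlog2fc\tqvalue\n")
        for r in records:
            q = "NA" if r.qvalue is None else f"{r.qvalue:.6g}"
            fh.write(f"{r.gene_id}\t{r.log2fc:.6f}\t{q}\n")
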