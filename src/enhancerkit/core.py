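"""Genomic domain types, coordinate conventions, and plain-text readers/writers.

All coordinates are 0-based half-open (BED convention). Any 1-based input
dialect must be converted at the reader boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GenomicInterval",
    "Peak",
    "TssRecord",
    "ChromSizes",
    "read_intervals",
    "write_intervals",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_tss_table",
    "write_tss_table",
    "distance_to_nearest_tss",
]

STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """Malformed line in a BED-like file; message names the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded); ``name`` is an
    optional label carried through to BED output.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start

    def validate_against(self, sizes: "ChromSizes") -> "GenomicInterval":
        """Check the interval fits its chromosome; returns self for chaining."""
        length = sizes.get(self.chrom)
        if length is None:
            raise ValueError(f"chromosome {self.chrom!r} absent from sizes table")
        if self.end > length:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {length}"
            )
        return self

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass(frozen=True)
class Peak:
    """An enriched region with a summit (absolute bp) and a normalized score."""

    interval: GenomicInterval
    summit: int
    score: float

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside "
                f"[{self.interval.start},{self.interval.end})"
            )
        if self.score < 0:
            raise ValueError("score must be >= 0")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class TssRecord:
    """A gene anchored at its transcription start site.

    For ``+`` genes ``tss < gene_end``; for ``-`` genes ``tss > gene_end``
    (the TSS is the rightmost genomic position of the gene).
    """

    gene: str
    chrom: str
    tss: int
    strand: str
    gene_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"TSS strand must be + or -, got {self.strand!r}")
        if self.strand == "+" and not self.tss < self.gene_end:
            raise ValueError(f"gene {self.gene}: + strand requires tss < gene_end")
        if self.strand == "-" and not self.tss > self.gene_end:
            raise ValueError(f"gene {self.gene}: - strand requires tss > gene_end")

    @property
    def length(self) -> int:
        return abs(self.gene_end - self.tss)

    @property
    def span(self) -> GenomicInterval:
        """Genomic footprint of the gene as a half-open interval."""
        lo, hi = sorted((self.tss, self.gene_end))
        return GenomicInterval(self.chrom, lo, hi + (1 if self.strand == "-" else 0), self.strand, self.gene)


class ChromSizes(dict):
    """Mapping chromosome name -> length in bp; lengths must be positive."""

    def __init__(self, sizes: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        super().__init__(sizes)
        for name, length in self.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def genome_length(self) -> int:
        return sum(self.values())


# ---------------------------------------------------------------------------
# Readers / writers


def read_intervals(path: str | Path, sizes: ChromSizes | None = None) -> list[GenomicInterval]:
    """Read BED3/BED6 into validated intervals, preserving input order.

    Lines with fewer than 3 tab-separated columns, non-integer coordinates,
    or start >= end raise :class:`BedParseError` naming the line number.
    When ``sizes`` is given each interval is validated against it.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 else "."
            try:
                iv = GenomicInterval(fields[0], start, end, strand=strand, name=name)
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            if sizes is not None:
                iv.validate_against(sizes)
            out.append(iv)
    return out


def write_intervals(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    """Write BED6 when any interval carries a name or strand, else BED3."""
    bed6 = any(iv.name is not None or iv.strand != "." for iv in intervals)
    with open(path, "w") as fh:
        for iv in intervals:
            if bed6:
                name = iv.name if iv.name is not None else "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 2 columns")
            name, length = fields[0], int(fields[1])
            if name in sizes:
                raise BedParseError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            sizes[name] = length
    return ChromSizes(sizes)


def write_chrom_sizes(sizes: ChromSizes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def read_tss_table(path: str | Path) -> list[TssRecord]:
    """Read a 5-column TSV: gene, chrom, tss, strand, gene_end (no header)."""
    out: list[TssRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise BedParseError(f"{path}:{lineno}: expected 5 columns")
            try:
                rec = TssRecord(fields[0], fields[1], int(fields[2]), fields[3], int(fields[4]))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            out.append(rec)
    return out


def write_tss_table(records: Sequence[TssRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.gene}\t{r.chrom}\t{r.tss}\t{r.strand}\t{r.gene_end}\n")


# ---------------------------------------------------------------------------
# TSS distance


def distance_to_nearest_tss(
    region: GenomicInterval, tss_set: Sequence[TssRecord]
) -> float:
    """Center-to-TSS distance to the nearest same-chromosome TSS, strand-agnostic.

    Returns ``math.inf`` when no TSS shares the region's chromosome; raises on
    an empty ``tss_set``.
    """
    if not tss_set:
        raise ValueError("tss_set must be non-empty")
    center = region.center
    best = math.inf
    for rec in tss_set:
        if rec.chrom != region.chrom:
            continue
        d = abs(center - rec.tss)
        if d < best:
            best = d
    return best
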