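"""Genomic coordinate model and interval arithmetic.

All coordinates inside the package are 0-based half-open ``[start, end)``.
External text formats differ: BED is already 0-based half-open, while
PennCNV-style ``chrN:start-end`` locus strings are 1-based inclusive and are
converted at the parse boundary (``start_internal = start_input - 1``,
``end_internal = end_input``).

Chromosome labels are normalized to the ``chrN`` dialect at parse time, so
``"4"`` and ``"chr4"`` refer to the same chromosome everywhere downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "normalize_chrom",
    "parse_region",
    "overlap_bp",
    "merge_intervals",
    "subtract_intervals",
    "read_bed",
    "write_bed",
]

_REGION_RE = re.compile(r"^(?P<chrom>[\w.]+):(?P<start>[\d,]+)-(?P<end>[\d,]+)$")


def normalize_chrom(chrom: str) -> str:
    """Normalize a chromosome label to the ``chrN`` dialect.

    Accepts ``"4"``, ``"chr4"``, ``"X"``, ``"chrX"`` (case-insensitive
    prefix) and returns ``"chr4"`` / ``"chrX"``.
    """
    c = chrom.strip()
    if not c:
        raise ValueError("empty chromosome label")
    if c.lower().startswith("chr"):
        c = c[3:]
    return f"chr{c}"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def expand(self, pad: int) -> "GenomicInterval":
        """Return the interval padded by ``pad`` bp on both sides (clamped at 0)."""
        return GenomicInterval(self.chrom, max(0, self.start - pad), self.end + pad)

    def to_region_string(self) -> str:
        """Render as a 1-based inclusive ``chrN:start-end`` locus string."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"

    def __str__(self) -> str:  # pragma: no cover - display helper
        return f"{self.chrom}:[{self.start},{self.end})"


def parse_region(text: str) -> GenomicInterval:
    """Parse a 1-based inclusive ``chrN:start-end`` string (commas tolerated)."""
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise ValueError(f"malformed region string: {text!r}")
    start = int(m.group("start").replace(",", ""))
    end = int(m.group("end").replace(",", ""))
    if start < 1 or end < start:
        raise ValueError(f"invalid 1-based coordinates in {text!r}")
    return GenomicInterval(normalize_chrom(m.group("chrom")), start - 1, end)


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Base pairs shared by two intervals; 0 when on different chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Minimal sorted set of disjoint intervals covering the same bases.

    Abutting half-open intervals (``end == next.start``) merge. Invalid
    entries are rejected with their position in the input.
    """
    items: list[GenomicInterval] = []
    for i, iv in enumerate(intervals):
        if not isinstance(iv, GenomicInterval):
            raise TypeError(f"invalid interval at index {i}: {iv!r}")
        items.append(iv)
    items.sort()
    merged: list[GenomicInterval] = []
    for iv in items:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def subtract_intervals(
    minuend: Sequence[GenomicInterval], subtrahend: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Bases covered by ``minuend`` but by no interval of ``subtrahend``."""
    result: list[GenomicInterval] = []
    sub = merge_intervals(subtrahend)
    for iv in merge_intervals(minuend):
        cursor = iv.start
        for s in sub:
            if s.chrom != iv.chrom or s.end <= cursor or s.start >= iv.end:
                continue
            if s.start > cursor:
                result.append(GenomicInterval(iv.chrom, cursor, s.start))
            cursor = max(cursor, s.end)
            if cursor >= iv.end:
                break
        if cursor < iv.end:
            result.append(GenomicInterval(iv.chrom, cursor, iv.end))
    return result


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file (0-based half-open); extra columns are ignored."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: expected >= 3 BED columns")
            try:
                out.append(
                    GenomicInterval(
                        normalize_chrom(fields[0]), int(fields[1]), int(fields[2])
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
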