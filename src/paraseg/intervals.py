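"""Genomic intervals, 1-based inclusive.

All coordinates in this package are 1-based and inclusive on both ends,
matching the interval notation used in plant methylome reports
(e.g. ``ch08:54487325-54487842``).  Conversion to 0-based half-open
happens only when writing BED.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed genomic interval [start, end] on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 1 <= start <= end"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @classmethod
    def parse(cls, text: str) -> "GenomicInterval":
        """Parse ``chrom:start-end`` (commas in numbers tolerated)."""
        m = re.fullmatch(r"([^:]+):([\d,]+)-([\d,]+)", text.strip())
        if m is None:
            raise ValueError(f"cannot parse interval {text!r}")
        return cls(m.group(1), int(m.group(2).replace(",", "")),
                   int(m.group(3).replace(",", "")))


def merge_overlapping(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge intervals sharing >= 1 bp (transitive closure).

    Touching-but-not-overlapping intervals (end + 1 == start) are NOT merged.
    Output is sorted by (chrom, start).
    """
    out: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def any_overlap(iv: GenomicInterval, others: Sequence[GenomicInterval]) -> bool:
    return any(iv.overlaps(o) for o in others)


def to_bed_fields(iv: GenomicInterval) -> tuple[str, int, int]:
    """1-based inclusive -> BED 0-based half-open."""
    return iv.chrom, iv.start - 1, iv.end
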