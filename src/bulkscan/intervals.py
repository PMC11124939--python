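"""Genomic interval primitives shared across the scan, fine-mapping and report stages.

Coordinates are 1-based and inclusive on both ends (VCF convention); BED
exports convert to 0-based half-open. Lengths in megabases are reported at
two decimals, matching how candidate intervals are conventionally quoted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

__all__ = ["Region", "merge_regions", "union_regions", "intersect_regions", "regions_to_frame"]


@dataclass(frozen=True)
class Region:
    """A chromosome interval tagged with the method that produced it."""

    chrom: str
    start: int
    end: int
    method: str = ""
    n_sites: int = 0
    peak: float = math.nan

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError("regions are 1-based; start must be >= 1")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def length_mb(self) -> float:
        return round(self.length_bp / 1e6, 2)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def overlaps(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def to_bed_fields(self) -> tuple[str, int, int]:
        """0-based half-open triple for BED export."""
        return (self.chrom, self.start - 1, self.end)


def _sorted(regions: Iterable[Region]) -> list[Region]:
    return sorted(regions, key=lambda r: (r.chrom, r.start, r.end))


def merge_regions(regions: Sequence[Region], gap_bp: int = 0, method: str | None = None) -> list[Region]:
    """Merge regions on the same chromosome separated by less than ``gap_bp``.

    ``gap_bp=0`` merges only overlapping/adjacent intervals. Site counts are
    summed and the peak statistic is the max over merged members.
    """
    out: list[Region] = []
    for reg in _sorted(regions):
        if out and reg.chrom == out[-1].chrom and reg.start - out[-1].end - 1 < max(gap_bp, 1):
            prev = out[-1]
            peak = prev.peak
            if math.isnan(peak) or (not math.isnan(reg.peak) and reg.peak > peak):
                peak = reg.peak
            out[-1] = replace(
                prev,
                end=max(prev.end, reg.end),
                n_sites=prev.n_sites + reg.n_sites,
                peak=peak,
            )
        else:
            out.append(reg)
    if method is not None:
        out = [replace(r, method=method) for r in out]
    return out


def union_regions(regions: Sequence[Region], method: str | None = None) -> list[Region]:
    """Union (merge of overlapping/adjacent intervals) of a region list."""
    return merge_regions(regions, gap_bp=0, method=method)


def intersect_regions(
    a: Sequence[Region], b: Sequence[Region], method: str = "intersection"
) -> tuple[list[Region], float]:
    """Pairwise interval intersection of two region lists.

    Returns the intersected regions (1-based inclusive) and their total
    length in Mb rounded to two decimals.
    """
    out: list[Region] = []
    for ra in union_regions(a):
        for rb in union_regions(b):
            if ra.overlaps(rb):
                out.append(
                    Region(
                        chrom=ra.chrom,
                        start=max(ra.start, rb.start),
                        end=min(ra.end, rb.end),
                        method=method,
                        n_sites=min(ra.n_sites, rb.n_sites),
                        peak=math.nan,
                    )
                )
    out = union_regions(out, method=method)
    total_mb = round(sum(r.length_bp for r in out) / 1e6, 2)
    return out, total_mb


def regions_to_frame(regions: Sequence[Region]) -> pd.DataFrame:
    """Tabulate regions (1-based inclusive) with Mb lengths at 2 decimals."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "method": [r.method for r in regions],
            "n_sites": [r.n_sites for r in regions],
            "peak": [r.peak for r in regions],
            "length_mb": [r.length_mb for r in regions],
        }
    )
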