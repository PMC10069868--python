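"""Genomic interval primitives and BED-style I/O.

Coordinates are 0-based, half-open (BED convention) throughout the
package.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass(frozen=True)
class GenomicInterval:
    """A chrom/start/end(/strand) region, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def clipped(self, chrom_length: int) -> "GenomicInterval":
        return replace(
            self, start=max(0, self.start), end=min(self.end, chrom_length)
        )


def read_bed(path) -> pd.DataFrame:
    """Read a BED3/BED6 file into a DataFrame with BED6 columns.

    Missing name/score/strand columns are filled with defaults.
    Raises ValueError naming the offending line for malformed rows.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval {start}-{end}"
                )
            name = fields[3] if len(fields) > 3 else f"region_{lineno}"
            score = fields[4] if len(fields) > 4 else "0"
            strand = fields[5] if len(fields) > 5 else "."
            rows.append((fields[0], start, end, name, score, strand))
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


def write_bed(df: pd.DataFrame, path) -> None:
    """Write a DataFrame (BED6 columns or a subset) as BED."""
    cols = [c for c in BED6_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def intervals_to_frame(intervals, names=None) -> pd.DataFrame:
    recs = []
    for i, iv in enumerate(intervals):
        name = names[i] if names is not None else f"region_{i}"
        recs.append((iv.chrom, iv.start, iv.end, name, 0, iv.strand))
    return pd.DataFrame(recs, columns=BED6_COLUMNS)


def frame_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end),
                        getattr(r, "strand", "."))
        for r in df.itertuples(index=False)
    ]


def overlap_mask(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: does it overlap any subject interval?"""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for r in subject.itertuples(index=False):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    out = np.zeros(len(query), dtype=bool)
    for i, r in enumerate(query.itertuples(index=False)):
        tree = trees.get(r.chrom)
        if tree is not None and tree.overlap(r.start, r.end):
            out[i] = True
    return out
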