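"""Genomic interval containers, BED I/O and interval arithmetic.

All coordinates are 0-based half-open throughout: an interval covers
``start .. end-1`` and ``[0, 10)`` does not touch ``[10, 20)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic span."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


class PeakSet:
    """An ordered collection of intervals with optional per-peak tag density.

    Backed by a DataFrame with BED6 columns plus an optional ``tag_density``
    column (reads per 10 million within the peak). Rows are kept sorted by
    (chrom, start, end).
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"PeakSet requires column {col!r}")
        if "name" not in df.columns:
            df["name"] = [f"peak_{i}" for i in range(len(df))]
        if "score" not in df.columns:
            df["score"] = 0.0
        if "strand" not in df.columns:
            df["strand"] = "."
        bad = (df["start"] < 0) | (df["start"] >= df["end"])
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"invalid interval at row {i}: start >= end or start < 0")
        if "tag_density" in df.columns and (df["tag_density"] < 0).any():
            raise ValueError("tag_density must be >= 0")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for row in self.df.itertuples(index=False):
            yield GenomicInterval(
                chrom=row.chrom, start=int(row.start), end=int(row.end),
                strand=row.strand, name=row.name, score=float(row.score),
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        a = self.df[BED_COLUMNS].reset_index(drop=True)
        b = other.df[BED_COLUMNS].reset_index(drop=True)
        return a.equals(b)

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "PeakSet":
        rows = [
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end,
             "name": iv.name or f"peak_{i}", "score": iv.score or 0.0,
             "strand": iv.strand}
            for i, iv in enumerate(intervals)
        ]
        return cls(pd.DataFrame(rows, columns=BED_COLUMNS))

    def centers(self) -> np.ndarray:
        return ((self.df["start"].to_numpy() + self.df["end"].to_numpy()) // 2)


def read_bed(path) -> PeakSet:
    """Read a BED3-BED6 file into a PeakSet.

    Malformed coordinates raise a ValueError naming the offending line.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: expected >= 3 BED fields")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinate") from exc
            if start < 0 or start >= end:
                raise ValueError(
                    f"line {lineno}: invalid interval [{start}, {end})"
                )
            name = parts[3] if len(parts) > 3 else f"peak_{lineno}"
            try:
                score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            except ValueError:
                score = 0.0
            strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "."
            rows.append({"chrom": chrom, "start": start, "end": end,
                         "name": name, "score": score, "strand": strand})
    return PeakSet(pd.DataFrame(rows, columns=BED_COLUMNS))


def write_bed(peaks: PeakSet, path) -> None:
    """Write a PeakSet as BED6; round-trips through read_bed unchanged."""
    with open(path, "w") as fh:
        for row in peaks.df.itertuples(index=False):
            score = row.score
            score_str = f"{score:g}"
            fh.write(
                f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{row.name}"
                f"\t{score_str}\t{row.strand}\n"
            )


def overlap(a: PeakSet, b: PeakSet, min_bp: int = 1) -> pd.DataFrame:
    """All pairs of intervals from a and b overlapping by >= min_bp bases.

    Returns a DataFrame with columns (a_index, b_index, overlap_bp) indexing
    rows of ``a.df`` and ``b.df``. Half-open semantics: adjacent intervals
    do not overlap. Sorted-sweep per chromosome, O((n+m) log + pairs).
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    out_a, out_b, out_len = [], [], []
    bdf = b.df
    for chrom, adf in a.df.groupby("chrom", sort=False):
        bc = bdf[bdf["chrom"] == chrom]
        if bc.empty:
            continue
        b_start = bc["start"].to_numpy()
        b_end = bc["end"].to_numpy()
        b_idx = bc.index.to_numpy()
        # b is sorted by start; for each a-interval find candidate window
        max_b_len = int((b_end - b_start).max())
        for ai, a_start, a_end in zip(adf.index, adf["start"], adf["end"]):
            lo = np.searchsorted(b_start, a_start - max_b_len, side="left")
            hi = np.searchsorted(b_start, a_end, side="left")
            for j in range(lo, hi):
                ov = min(a_end, b_end[j]) - max(a_start, b_start[j])
                if ov >= min_bp:
                    out_a.append(ai)
                    out_b.append(b_idx[j])
                    out_len.append(ov)
    return pd.DataFrame({"a_index": out_a, "b_index": out_b, "overlap_bp": out_len})


def distance_to_nearest_tss(peaks: PeakSet, tss: pd.DataFrame) -> pd.DataFrame:
    """Signed distance from each peak center to its nearest TSS.

    ``tss`` needs columns (chrom, position). Distance is
    ``peak_center - tss_position`` for the TSS minimizing the absolute
    distance; ties break toward the smaller TSS coordinate. Peaks on
    chromosomes with no TSS get distance NaN and defined=False.
    """
    if len(tss) == 0:
        raise ValueError("TSS set is empty")
    dist = np.full(len(peaks), np.nan)
    defined = np.zeros(len(peaks), dtype=bool)
    centers = peaks.centers()
    chroms = peaks.df["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        pos = np.sort(tss.loc[tss["chrom"] == chrom, "position"].to_numpy())
        mask = chroms == chrom
        if pos.size == 0:
            continue
        c = centers[mask]
        right = np.searchsorted(pos, c, side="left")
        left = np.clip(right - 1, 0, pos.size - 1)
        right = np.clip(right, 0, pos.size - 1)
        d_left = np.abs(c - pos[left])
        d_right = np.abs(c - pos[right])
        # tie toward the smaller coordinate: strict < keeps the left one
        use_right = d_right < d_left
        nearest = np.where(use_right, pos[right], pos[left])
        dist[mask] = c - nearest
        defined[mask] = True
    out = peaks.df[["chrom", "name"]].copy()
    out["center"] = centers
    out["distance"] = dist
    out["defined"] = defined
    return out


def window_around_center(interval: GenomicInterval, width: int) -> GenomicInterval:
    """Fixed-width window centered on the interval center, clipped at 0.

    Width must be even and positive. Clipping at the chromosome start can
    shorten the window below ``width``.
    """
    if width <= 0 or width % 2:
        raise ValueError("width must be even and positive")
    center = interval.center
    half = width // 2
    start = max(0, center - half)
    end = center + half
    return GenomicInterval(chrom=interval.chrom, start=start, end=end,
                           strand=interval.strand, name=interval.name)
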