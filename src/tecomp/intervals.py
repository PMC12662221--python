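"""Genomic-interval data model, BED I/O, overlap engine and fold-change arithmetic.

All coordinates are 0-based, half-open (BED convention): an interval covers
bases ``start .. end-1`` and two intervals overlap iff
``max(starts) < min(ends)``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "read_bed",
    "write_bed",
    "overlap_table",
    "merge_intervals",
    "assign_to_locus",
    "log2_fold_change",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    ``name`` is an optional unique identifier (BED column 4); ``score`` an
    optional numeric (BED column 5).
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2

    @property
    def id(self) -> str:
        """Identifier: the name when present, else ``chrom:start-end``."""
        return self.name if self.name is not None else f"{self.chrom}:{self.start}-{self.end}"

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class RegionSet:
    """An ordered collection of :class:`GenomicInterval`, sorted by
    (chrom, start, end), with unique identifiers.

    Parameters
    ----------
    intervals
        Any iterable of intervals; sorted on construction.
    label
        Provenance string, e.g. ``"CEBPa_24hpi_peaks"``.
    """

    def __init__(self, intervals: Iterable[GenomicInterval], label: str = "") -> None:
        self.intervals: list[GenomicInterval] = sorted(intervals, key=GenomicInterval.sort_key)
        self.label = label
        ids = [iv.id for iv in self.intervals]
        if len(set(ids)) != len(ids):
            dupes = pd.Series(ids).loc[lambda s: s.duplicated()].unique()
            raise ValueError(f"duplicate interval identifiers in set: {list(dupes)[:5]}")
        self._by_id = {iv.id: iv for iv in self.intervals}

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, key: int | str) -> GenomicInterval:
        if isinstance(key, str):
            return self._by_id[key]
        return self.intervals[key]

    def __contains__(self, region_id: str) -> bool:
        return region_id in self._by_id

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"RegionSet({len(self)} intervals, label={self.label!r})"

    @property
    def ids(self) -> list[str]:
        return [iv.id for iv in self.intervals]

    def subset(self, region_ids: Iterable[str], label: str | None = None) -> "RegionSet":
        wanted = set(region_ids)
        return RegionSet(
            (iv for iv in self.intervals if iv.id in wanted),
            label=label if label is not None else self.label,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "name": [iv.name for iv in self.intervals],
                "score": [iv.score for iv in self.intervals],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "") -> "RegionSet":
        ivs = []
        for row in df.itertuples(index=False):
            name = getattr(row, "name", None)
            score = getattr(row, "score", None)
            ivs.append(
                GenomicInterval(
                    str(row.chrom),
                    int(row.start),
                    int(row.end),
                    None if name is None or (isinstance(name, float) and np.isnan(name)) else str(name),
                    None if score is None or (isinstance(score, float) and np.isnan(score)) else float(score),
                )
            )
        return cls(ivs, label=label)


class BedParseError(ValueError):
    """Raised for malformed BED lines; carries the 1-based line number."""


_SKIP_PREFIXES = ("#", "track", "browser")


def read_bed(path: str | Path, label: str | None = None) -> RegionSet:
    """Read a BED3/BED6 file into a sorted :class:`RegionSet`.

    Track/browser/comment lines are skipped.  Name (column 4) and score
    (column 5) are preserved when present; ``.`` placeholders are treated
    as absent.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: non-numeric score") from exc
            try:
                intervals.append(GenomicInterval(chrom, start, end, name, score))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return RegionSet(intervals, label=label if label is not None else path.stem)


def write_bed(regions: RegionSet, path: str | Path) -> None:
    """Write a RegionSet as BED; emits 6 columns when any name/score present."""
    has_extra = any(iv.name is not None or iv.score is not None for iv in regions)
    with open(path, "w") as fh:
        for iv in regions:
            if has_extra:
                score = "." if iv.score is None else format(iv.score, "g")
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t.\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def _by_chrom(regions: RegionSet) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in regions:
        out.setdefault(iv.chrom, []).append(iv)
    return out


def overlap_table(
    query: RegionSet, subject: RegionSet, min_overlap_bp: int = 1
) -> dict[str, list[str]]:
    """Map each query id to the subject ids it overlaps by ``>= min_overlap_bp``.

    Half-open semantics: touching intervals (``q.end == s.start``) do not
    overlap.  Output ordering is deterministic: queries in set order,
    subjects in coordinate order.
    """
    if min_overlap_bp < 1:
        raise ValueError(f"min_overlap_bp must be >= 1, got {min_overlap_bp}")
    subj_chrom = _by_chrom(subject)
    # per-chromosome arrays sorted by start (RegionSet is already sorted)
    arrays = {
        chrom: (
            np.array([iv.start for iv in ivs]),
            np.array([iv.end for iv in ivs]),
            [iv.id for iv in ivs],
        )
        for chrom, ivs in subj_chrom.items()
    }
    result: dict[str, list[str]] = {}
    for q in query:
        hits: list[str] = []
        entry = arrays.get(q.chrom)
        if entry is not None:
            starts, ends, ids = entry
            # candidates: subjects starting before q.end
            hi = int(np.searchsorted(starts, q.end, side="left"))
            ov = np.minimum(ends[:hi], q.end) - np.maximum(starts[:hi], q.start)
            idx = np.nonzero(ov >= min_overlap_bp)[0]
            hits = [ids[i] for i in idx]
        result[q.id] = hits
    return result


def merge_intervals(regions: RegionSet, gap: int = 0) -> RegionSet:
    """Merge same-chromosome intervals within ``gap`` bp of each other.

    Abutting intervals (``end == start``) merge at ``gap=0``, matching
    ``bedtools merge``.  Names and scores are dropped from merged output.
    """
    if gap < 0:
        raise ValueError(f"gap must be >= 0, got {gap}")
    merged: list[GenomicInterval] = []
    cur: list[int | str] | None = None
    for iv in regions:
        if cur is not None and iv.chrom == cur[0] and iv.start <= cur[2] + gap:
            cur[2] = max(cur[2], iv.end)
        else:
            if cur is not None:
                merged.append(GenomicInterval(cur[0], cur[1], cur[2]))
            cur = [iv.chrom, iv.start, iv.end]
    if cur is not None:
        merged.append(GenomicInterval(cur[0], cur[1], cur[2]))
    return RegionSet(merged, label=regions.label)


def assign_to_locus(
    regions: RegionSet,
    gene_anchors: pd.DataFrame,
    window_kb: float = 300,
) -> dict[str, list[str]]:
    """Assign regions to gene loci: windows of total width ``window_kb``
    centered on each TSS (strand-agnostic).

    ``gene_anchors`` needs columns ``gene``, ``chrom``, ``tss`` (and
    optionally ``strand``, unused here).  A region may land in several
    gene windows.
    """
    if window_kb <= 0:
        raise ValueError(f"window_kb must be > 0, got {window_kb}")
    half = int(round(window_kb * 1000 / 2))
    out: dict[str, list[str]] = {}
    for row in gene_anchors.itertuples(index=False):
        win_start = max(0, int(row.tss) - half)
        win_end = int(row.tss) + half
        hits = [
            iv.id
            for iv in regions
            if iv.chrom == row.chrom and iv.start < win_end and iv.end > win_start
        ]
        out[str(row.gene)] = hits
    return out


def log2_fold_change(a: float, b: float, pseudocount: float = 0.5) -> float:
    """``log2((a + pseudocount) / (b + pseudocount))``; antisymmetric in (a, b)."""
    if a < 0 or b < 0:
        raise ValueError("signal values must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    # difference of logs keeps f(a,b) == -f(b,a) exact in floating point
    return float(np.log2(a + pseudocount) - np.log2(b + pseudocount))
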