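"""Genomic interval containers, BED/bedGraph I/O and the interval algebra.

All coordinates are BED-style: 0-based, half-open ``[start, end)``.  Touching
intervals (``end == start`` of the next) do NOT overlap.  Overlap semantics
everywhere downstream are "any >= 1 bp" unless stated otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BedFormatError",
    "GenomicInterval",
    "IntervalSet",
    "FragmentSet",
    "CoverageTrack",
    "read_bed",
    "read_fragments",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_tss",
    "coverage",
    "subsample",
    "count_overlapping_fragments",
]

_BED_DIALECT_COLS = {
    "bed3": ["chrom", "start", "end"],
    "bed4": ["chrom", "start", "end", "name"],
    "bed5": ["chrom", "start", "end", "name", "score"],
    "bed6": ["chrom", "start", "end", "name", "score", "strand"],
}

_VALID_STRANDS = {"+", "-", "."}


class BedFormatError(ValueError):
    """Raised when a BED file violates the coordinate invariants."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic region."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise BedFormatError("chrom must be non-empty")
        if not 0 <= self.start < self.end:
            raise BedFormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in _VALID_STRANDS:
            raise BedFormatError(f"unknown strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start


class IntervalSet:
    """An ordered collection of genomic intervals backed by a DataFrame.

    The frame always carries ``chrom``, ``start``, ``end``; ``name``,
    ``score`` and ``strand`` are optional, and extra columns (peak scores
    etc.) are preserved by the algebra where meaningful.
    """

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame({"chrom": pd.Series(dtype=str),
                               "start": pd.Series(dtype=np.int64),
                               "end": pd.Series(dtype=np.int64)})
        df = df.reset_index(drop=True).copy()
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"IntervalSet frame missing column {col!r}")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if len(df):
            bad = (df["start"] < 0) | (df["start"] >= df["end"])
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                row = df.iloc[i]
                raise BedFormatError(
                    f"invalid interval {row.chrom}:{row.start}-{row.end} at row {i}"
                )
        self.df = df

    # -- construction ------------------------------------------------------
    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple]) -> "IntervalSet":
        rows = list(tuples)
        if not rows:
            return cls()
        ncol = len(rows[0])
        cols = ["chrom", "start", "end", "name", "score", "strand"][:ncol]
        return cls(pd.DataFrame(rows, columns=cols))

    @classmethod
    def from_intervals(cls, ivs: Iterable[GenomicInterval]) -> "IntervalSet":
        return cls.from_tuples(
            (iv.chrom, iv.start, iv.end, iv.name, iv.score, iv.strand) for iv in ivs
        )

    # -- basics ------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        has_name = "name" in self.df.columns
        has_strand = "strand" in self.df.columns
        for row in self.df.itertuples(index=False):
            yield GenomicInterval(
                row.chrom, int(row.start), int(row.end),
                name=str(row.name) if has_name and row.name is not None else None,
                strand=str(row.strand) if has_strand else ".",
            )

    def chroms(self) -> list[str]:
        return sorted(self.df["chrom"].unique())

    def sort(self) -> "IntervalSet":
        out = self.df.sort_values(
            ["chrom", "start", "end"], kind="mergesort"
        ).reset_index(drop=True)
        return type(self)._wrap(out, self)

    def total_bases(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())

    @classmethod
    def _wrap(cls, df: pd.DataFrame, like: "IntervalSet") -> "IntervalSet":
        obj = IntervalSet.__new__(IntervalSet)
        obj.df = df.reset_index(drop=True)
        return obj

    def _by_chrom(self):
        for chrom, sub in self.df.groupby("chrom", sort=True):
            yield chrom, sub

    # -- algebra -----------------------------------------------------------
    def merge(self, min_gap: int = 0) -> "IntervalSet":
        """Union of intervals, bridging gaps of up to ``min_gap`` bases.

        Output is sorted and non-overlapping; covered bases never shrink.
        """
        pieces = []
        for chrom, sub in self._by_chrom():
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            order = np.argsort(s, kind="mergesort")
            s, e = s[order], np.maximum.accumulate(e[order])
            # a new block starts where start > running max end + gap
            new_block = np.ones(len(s), dtype=bool)
            if len(s) > 1:
                new_block[1:] = s[1:] > e[:-1] + min_gap
            block = np.cumsum(new_block) - 1
            starts = s[new_block]
            ends = np.maximum.reduceat(e, np.flatnonzero(new_block))
            pieces.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        if not pieces:
            return IntervalSet()
        return IntervalSet(pd.concat(pieces, ignore_index=True))

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Per overlapping pair, the overlap segment (>= 1 bp)."""
        pieces = []
        other_by_chrom = {c: sub for c, sub in other._by_chrom()}
        for chrom, sub in self._by_chrom():
            osub = other_by_chrom.get(chrom)
            if osub is None:
                continue
            a_s = np.sort(sub["start"].to_numpy())
            a_e = sub["end"].to_numpy()[np.argsort(sub["start"].to_numpy(),
                                                   kind="mergesort")]
            b_s = np.sort(osub["start"].to_numpy())
            b_e = osub["end"].to_numpy()[np.argsort(osub["start"].to_numpy(),
                                                    kind="mergesort")]
            starts, ends = [], []
            i = 0
            for bs, be in zip(b_s, b_e):
                while i < len(a_s) and a_e[i] <= bs:
                    i += 1
                k = i
                while k < len(a_s) and a_s[k] < be:
                    if a_e[k] > bs:
                        starts.append(max(a_s[k], bs))
                        ends.append(min(a_e[k], be))
                    k += 1
            if starts:
                pieces.append(pd.DataFrame(
                    {"chrom": chrom, "start": starts, "end": ends}))
        if not pieces:
            return IntervalSet()
        return IntervalSet(pd.concat(pieces, ignore_index=True)).sort()

    def overlaps_any(self, subject: "IntervalSet") -> np.ndarray:
        """Boolean per query interval: does it overlap any subject by >=1 bp?"""
        merged = {c: sub for c, sub in subject.merge()._by_chrom()}
        out = np.zeros(len(self.df), dtype=bool)
        for chrom, sub in self.df.groupby("chrom", sort=False):
            msub = merged.get(chrom)
            if msub is None:
                continue
            ms = msub["start"].to_numpy()
            me = msub["end"].to_numpy()
            qs = sub["start"].to_numpy()
            qe = sub["end"].to_numpy()
            # overlap iff some merged block with block.start < q.end
            # and block.end > q.start; blocks are disjoint and sorted
            lo = np.searchsorted(me, qs, side="right")
            hi = np.searchsorted(ms, qe, side="left")
            out[sub.index.to_numpy()] = hi > lo
        return out

    def count_overlaps(self, subject: "IntervalSet") -> np.ndarray:
        """Per query interval, the number of subject intervals overlapping it."""
        out = np.zeros(len(self.df), dtype=np.int64)
        for chrom, sub in subject._by_chrom():
            ss = np.sort(sub["start"].to_numpy())
            se = np.sort(sub["end"].to_numpy())
            mask = self.df["chrom"] == chrom
            qs = self.df.loc[mask, "start"].to_numpy()
            qe = self.df.loc[mask, "end"].to_numpy()
            # #(subject.start < q.end) - #(subject.end <= q.start)
            n = np.searchsorted(ss, qe, side="left") - np.searchsorted(
                se, qs, side="right")
            out[mask.to_numpy()] = n
        return out


class FragmentSet(IntervalSet):
    """Sequenced fragment intervals for one sample.

    ``library_size`` is the total number of fragments, by construction equal
    to ``len(self)``.
    """

    def __init__(self, df: pd.DataFrame | None = None, sample_id: str = ""):
        super().__init__(df)
        self.sample_id = sample_id

    @property
    def library_size(self) -> int:
        return len(self.df)


@dataclass
class CoverageTrack:
    """Binned per-chromosome fragment counts (or CPM/bp after scaling)."""

    bin_width: int
    data: dict[str, np.ndarray] = field(default_factory=dict)
    library_size: int = 0

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def cpm_per_bp(self) -> "CoverageTrack":
        scale = 1e6 / max(self.library_size, 1) / self.bin_width
        return CoverageTrack(
            self.bin_width,
            {c: v * scale for c, v in self.data.items()},
            self.library_size,
        )

    def write_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.data):
                v = self.data[chrom]
                # collapse runs of identical values
                change = np.flatnonzero(np.diff(v)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(v)]))
                for s, e in zip(starts, ends):
                    val = v[s]
                    if val == 0:
                        continue
                    fh.write(f"{chrom}\t{s * self.bin_width}"
                             f"\t{e * self.bin_width}\t{val:.6g}\n")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_bed_frame(path: str | Path, dialect: str) -> pd.DataFrame:
    cols = _BED_DIALECT_COLS.get(dialect.lower())
    if cols is None:
        raise ValueError(f"unknown BED dialect {dialect!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if (not line or line.startswith("#")
                    or line.startswith(("track", "browser"))):
                continue
            fields = line.split("\t")
            if len(fields) < len(cols):
                raise BedFormatError(
                    f"{path}:{lineno}: expected >= {len(cols)} columns, "
                    f"got {len(fields)}")
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise BedFormatError(
                    f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise BedFormatError(
                    f"{path}:{lineno}: invalid interval "
                    f"{fields[0]}:{start}-{end} (require 0 <= start < end)")
            row = [fields[0], start, end] + fields[3:len(cols)]
            if dialect == "bed6" and row[5] not in _VALID_STRANDS:
                raise BedFormatError(
                    f"{path}:{lineno}: unknown strand {row[5]!r}")
            rows.append(row)
    df = pd.DataFrame(rows, columns=cols)
    if df.empty:
        df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in
                           zip(cols, [str, np.int64, np.int64, str, object, str])})
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return df


def read_bed(path: str | Path, dialect: str = "bed3") -> IntervalSet:
    """Read a BED file into an :class:`IntervalSet`.

    Coordinates are taken as written (0-based half-open).  Comment, track
    and browser lines are skipped; malformed lines raise
    :class:`BedFormatError` naming the line number.
    """
    return IntervalSet(_read_bed_frame(path, dialect))


def read_fragments(path: str | Path, sample_id: str | None = None) -> FragmentSet:
    """Read a BED3 fragment file as a :class:`FragmentSet`."""
    df = _read_bed_frame(path, "bed3")
    return FragmentSet(df, sample_id=sample_id or Path(path).stem)


def write_bed(intervals: IntervalSet, path: str | Path,
              columns: Sequence[str] | None = None) -> None:
    """Write a BED file, sorted by (chrom, start); round-trips read_bed."""
    df = intervals.sort().df
    cols = ["chrom", "start", "end"]
    if columns:
        cols += [c for c in columns if c in df.columns]
    else:
        cols += [c for c in ("name", "score", "strand") if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise BedFormatError(f"{path}:{lineno}: expected 2 columns")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def read_tss(path: str | Path) -> IntervalSet:
    """Read a BED6 TSS table (single-bp records, unique gene names).

    Duplicate gene names are resolved by keeping the first occurrence.
    """
    df = _read_bed_frame(path, "bed6")
    if len(df) and ((df["end"] - df["start"]) != 1).any():
        bad = df[(df["end"] - df["start"]) != 1].iloc[0]
        raise BedFormatError(
            f"TSS record {bad['name']} is not single-bp "
            f"({bad.chrom}:{bad.start}-{bad.end})")
    df = df.drop_duplicates(subset="name", keep="first").reset_index(drop=True)
    return IntervalSet(df)


# ---------------------------------------------------------------------------
# Coverage / sampling
# ---------------------------------------------------------------------------

def coverage(frags: FragmentSet, bin_width: int,
             chrom_sizes: Mapping[str, int],
             extend_to: int | None = None) -> CoverageTrack:
    """Bin fragments by midpoint into fixed-width bins.

    With ``extend_to`` each record is first replaced by an ``extend_to``-long
    interval anchored at its 5' end (strand-aware if a strand column is
    present, else leftmost).  Each fragment lands in exactly one bin, so the
    sum over all bins equals the library size; fragments whose midpoint falls
    beyond the chromosome end are clipped into the last bin and logged.
    """
    track = CoverageTrack(bin_width, {}, frags.library_size)
    for chrom, size in chrom_sizes.items():
        nbins = int(np.ceil(size / bin_width))
        track.data[chrom] = np.zeros(nbins, dtype=np.float64)
    unknown = set(frags.df["chrom"].unique()) - set(chrom_sizes)
    if unknown:
        raise ValueError(f"fragments on chromosomes missing from sizes: {unknown}")
    n_clipped = 0
    for chrom, sub in frags.df.groupby("chrom", sort=False):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        if extend_to is not None:
            if "strand" in sub.columns:
                minus = (sub["strand"] == "-").to_numpy()
            else:
                minus = np.zeros(len(sub), dtype=bool)
            new_s = np.where(minus, e - extend_to, s)
            new_e = new_s + extend_to
            s, e = np.maximum(new_s, 0), new_e
        mid = (s + e) // 2
        size = chrom_sizes[chrom]
        n_clipped += int((mid >= size).sum())
        mid = np.clip(mid, 0, size - 1)
        track.data[chrom] += np.bincount(mid // bin_width,
                                         minlength=len(track.data[chrom]))
    if n_clipped:
        logger.warning("%d fragment midpoints beyond chromosome end were clipped",
                       n_clipped)
    return track


def subsample(frags: FragmentSet, fraction: float, seed: int) -> FragmentSet:
    """Seeded sampling of ``round(fraction * n)`` fragments without replacement."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    n = len(frags)
    k = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return FragmentSet(frags.df.iloc[idx], sample_id=frags.sample_id)


def count_overlapping_fragments(regions: IntervalSet,
                                frags: FragmentSet) -> np.ndarray:
    """Number of fragments overlapping (>= 1 bp) each region."""
    return regions.count_overlaps(frags)


def fragments_in_regions(frags: FragmentSet, regions: IntervalSet) -> np.ndarray:
    """Boolean per fragment: overlaps at least one region (counted once)."""
    return frags.overlaps_any(regions)
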