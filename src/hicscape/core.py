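"""Genome coordinate system, interval algebra, and tabular genomic I/O.

All coordinates are 0-based, half-open (BED convention): an interval
``[start, end)`` covers base pairs ``start .. end-1``, and bin ``k`` at
resolution ``r`` covers ``[k*r, (k+1)*r)``.  Touching intervals do not
overlap.  Interval algebra is strand-blind; strand matters only when
resolving a gene's transcription start site (TSS).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "GenomicInterval",
    "PeakSet",
    "GeneTable",
    "read_bed",
    "write_bed",
    "merge_intervals",
    "intersect",
    "overlap_fraction",
    "nearest_tss_distance",
    "NoTSSError",
]


class NoTSSError(ValueError):
    """Raised when a TSS distance is requested on a chromosome with no genes."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths (bp)."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        if len(self.lengths) == 0:
            raise ValueError("layout needs at least one chromosome")
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return list(self.lengths)

    def n_bins(self, chrom: str, resolution: int) -> int:
        return -(-self.lengths[chrom] // resolution)

    @classmethod
    def read(cls, path: str | Path) -> "GenomeLayout":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
        return cls(dict(zip(df["chrom"].astype(str), df["length"].astype(int))))

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self.lengths.items():
                fh.write(f"{name}\t{length}\n")


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


_BED_COLUMNS = ["chrom", "start", "end"]


@dataclass
class PeakSet:
    """A sorted set of peaks for one mark (e.g. H3K27ac, CTCF, ATAC).

    ``df`` holds columns chrom, start, end, signal; rows are sorted by
    (chrom, start, end) and signals are non-negative.
    """

    mark: str
    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end", "signal"]))

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in _BED_COLUMNS + ["signal"]:
            if col not in df.columns:
                raise ValueError(f"PeakSet frame missing column {col!r}")
        if len(df):
            if (df["start"] >= df["end"]).any():
                bad = df[df["start"] >= df["end"]].iloc[0]
                raise ValueError(f"peak with start >= end: {bad['chrom']}:{bad['start']}-{bad['end']}")
            if (df["signal"] < 0).any():
                raise ValueError("peak signals must be non-negative")
        self.df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def intervals(self, chrom: str | None = None) -> list[GenomicInterval]:
        df = self.df if chrom is None else self.df[self.df["chrom"] == chrom]
        return [GenomicInterval(c, s, e) for c, s, e in zip(df["chrom"], df["start"], df["end"])]

    def spans(self, chrom: str) -> np.ndarray:
        """(n, 2) array of [start, end) for one chromosome."""
        df = self.df[self.df["chrom"] == chrom]
        return df[["start", "end"]].to_numpy(dtype=np.int64).reshape(-1, 2)

    def top_signal(self, quantile: float) -> "PeakSet":
        """Peaks whose signal is in the top ``quantile`` fraction (ties included)."""
        if not 0 < quantile <= 1:
            raise ValueError("quantile must be in (0, 1]")
        if len(self.df) == 0:
            return PeakSet(self.mark, self.df.copy())
        threshold = float(np.quantile(self.df["signal"].to_numpy(), 1 - quantile))
        return PeakSet(self.mark, self.df[self.df["signal"] >= threshold].copy())


def read_bed(path: str | Path | io.TextIOBase, signal_column: int | None = None,
             mark: str = "", layout: GenomeLayout | None = None) -> PeakSet:
    """Read a BED3+ file into a :class:`PeakSet`.

    ``signal_column`` is a 1-based column index; when absent every peak gets
    signal 1.0.  Malformed lines raise with the offending line number.
    """
    rows = []
    fh = open(path) if isinstance(path, (str, Path)) else path
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: expected >= 3 tab-separated fields")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"line {lineno}: start >= end ({start} >= {end})")
            if layout is not None:
                if chrom not in layout.lengths or end > layout.lengths[chrom]:
                    raise ValueError(f"line {lineno}: interval outside genome layout")
            signal = 1.0
            if signal_column is not None:
                if len(parts) < signal_column:
                    raise ValueError(f"line {lineno}: missing signal column {signal_column}")
                try:
                    signal = float(parts[signal_column - 1])
                except ValueError as exc:
                    raise ValueError(f"line {lineno}: non-numeric signal") from exc
            rows.append((chrom, start, end, signal))
    finally:
        if isinstance(path, (str, Path)):
            fh.close()
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "signal"])
    return PeakSet(mark, df)


def write_bed(peaks: PeakSet, path: str | Path, with_signal: bool = True) -> None:
    """Write a PeakSet as BED5 (name '.'; score = signal) or BED3."""
    df = peaks.df
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            if with_signal:
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t.\t{row.signal:g}\n")
            else:
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")


# ---------------------------------------------------------------------------
# interval algebra (all half-open, strand-blind)

def _as_spans(intervals: Iterable[GenomicInterval] | np.ndarray) -> np.ndarray:
    if isinstance(intervals, np.ndarray):
        return intervals.reshape(-1, 2).astype(np.int64)
    arr = np.array([(iv.start, iv.end) for iv in intervals], dtype=np.int64)
    return arr.reshape(-1, 2)


def merge_intervals(spans: np.ndarray) -> np.ndarray:
    """Union of half-open spans as a sorted, disjoint (n, 2) array."""
    spans = _as_spans(spans)
    if len(spans) == 0:
        return spans
    spans = spans[np.lexsort((spans[:, 1], spans[:, 0]))]
    out = [spans[0].tolist()]
    for s, e in spans[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)


def intersect(a: Sequence[GenomicInterval] | np.ndarray,
              b: Sequence[GenomicInterval] | np.ndarray) -> np.ndarray:
    """Maximal half-open spans covered by both inputs (single chromosome).

    Touching intervals ([100,200) vs [200,300)) do not intersect.
    """
    sa, sb = merge_intervals(_as_spans(a)), merge_intervals(_as_spans(b))
    out = []
    i = j = 0
    while i < len(sa) and j < len(sb):
        lo = max(sa[i, 0], sb[j, 0])
        hi = min(sa[i, 1], sb[j, 1])
        if lo < hi:
            out.append((lo, hi))
        if sa[i, 1] <= sb[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def overlap_fraction(a: GenomicInterval, b: GenomicInterval) -> tuple[float, float]:
    """(|a∩b|/|a|, |a∩b|/|b|); (0, 0) on different chromosomes."""
    if a.chrom != b.chrom:
        return (0.0, 0.0)
    ov = max(0, min(a.end, b.end) - max(a.start, b.start))
    return (ov / len(a), ov / len(b))


# ---------------------------------------------------------------------------
# gene tables

@dataclass
class GeneTable:
    """Gene models with strand-resolved TSS and per-sample expressed flags.

    ``df`` columns: gene_id, chrom, start, end, strand.  TSS = start on '+',
    end on '-'.  ``expressed`` maps sample name -> boolean Series indexed by
    gene_id (typically mean FPKM > 1 in that sample).
    """

    df: pd.DataFrame
    expressed: dict[str, pd.Series] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = ["gene_id", "chrom", "start", "end", "strand"]
        for col in required:
            if col not in self.df.columns:
                raise ValueError(f"GeneTable missing column {col!r}")
        if self.df["gene_id"].duplicated().any():
            dup = self.df.loc[self.df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene id {dup!r}")
        bad = ~self.df["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError(
                f"gene {self.df.loc[bad, 'gene_id'].iloc[0]!r} has no strand")
        df = self.df.copy()
        df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"])
        self.df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def tss_positions(self, chrom: str) -> np.ndarray:
        return self.df.loc[self.df["chrom"] == chrom, "tss"].to_numpy(dtype=np.int64)

    def expressed_ids(self, sample: str) -> set[str]:
        flags = self.expressed.get(sample)
        if flags is None:
            return set(self.df["gene_id"])
        return set(flags.index[flags.astype(bool)])

    @classmethod
    def read(cls, path: str | Path) -> "GeneTable":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
        return cls(df[["gene_id", "chrom", "start", "end", "strand"]])

    def write(self, path: str | Path) -> None:
        self.df[["gene_id", "chrom", "start", "end", "strand"]].to_csv(
            path, sep="\t", index=False)


def nearest_tss_distance(interval: GenomicInterval, genes: GeneTable) -> int:
    """Edge-to-point gap (bp) from an interval to the closest TSS on its chromosome.

    0 when a TSS lies inside the interval.  Raises :class:`NoTSSError` when
    the chromosome carries no genes, so "no TSS" is distinct from any number.
    """
    tss = genes.tss_positions(interval.chrom)
    if len(tss) == 0:
        raise NoTSSError(f"no TSS on chromosome {interval.chrom!r}")
    inside = (tss >= interval.start) & (tss < interval.end)
    if inside.any():
        return 0
    gaps = np.where(tss < interval.start, interval.start - tss, tss - interval.end)
    return int(gaps.min())
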