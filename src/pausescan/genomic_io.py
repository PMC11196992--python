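"""Genomic file formats and coverage arithmetic.

All coordinates are 0-based, half-open (BED convention) throughout the
package: an interval ``[start, end)`` covers bases ``start .. end-1``.
Gene models are stranded; reads are treated as unstranded, since Pol II
ChIP fragments carry no strand information about the gene they decorate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


class BedFormatError(ValueError):
    """A BED line violates the format; the message names the 1-based line."""


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene span; the TSS is the strand-dependent 5' end."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"{self.gene_id}: negative start {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"{self.gene_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")

    @property
    def tss(self) -> int:
        """Transcription start site: `start` on +, `end` on - strand."""
        return self.start if self.strand == "+" else self.end

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Read:
    """An unstranded mapped-read interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative read start {self.start}")
        if self.start >= self.end:
            raise ValueError(f"read start {self.start} >= end {self.end}")


class ReadSet:
    """Mapped reads stored per chromosome as parallel start/end arrays.

    Arrays are sorted by start; an end-sorted copy is cached lazily for
    the interval-overlap counting queries in :mod:`pausescan.stalling`.
    """

    def __init__(self, by_chrom: Mapping[str, tuple[np.ndarray, np.ndarray]] | None = None):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._ends_sorted: dict[str, np.ndarray] = {}
        if by_chrom:
            for chrom, (starts, ends) in by_chrom.items():
                self._add_arrays(chrom, np.asarray(starts), np.asarray(ends))

    def _add_arrays(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if starts.shape != ends.shape:
            raise ValueError("starts and ends must have equal length")
        if starts.size and (starts.min() < 0 or (starts >= ends).any()):
            raise ValueError(f"{chrom}: invalid read intervals")
        order = np.argsort(starts, kind="stable")
        self._by_chrom[chrom] = (starts[order], ends[order])

    @classmethod
    def from_reads(cls, reads: Iterable[Read]) -> "ReadSet":
        grouped: dict[str, list[tuple[int, int]]] = {}
        for r in reads:
            grouped.setdefault(r.chrom, []).append((r.start, r.end))
        rs = cls()
        for chrom, ivals in grouped.items():
            arr = np.asarray(ivals, dtype=np.int64)
            rs._add_arrays(chrom, arr[:, 0], arr[:, 1])
        return rs

    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) sorted by start; empty arrays for an absent chrom."""
        if chrom not in self._by_chrom:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty
        return self._by_chrom[chrom]

    def ends_sorted(self, chrom: str) -> np.ndarray:
        if chrom not in self._ends_sorted:
            self._ends_sorted[chrom] = np.sort(self.arrays(chrom)[1])
        return self._ends_sorted[chrom]

    def slice_overlapping(self, chrom: str, lo: int, hi: int) -> tuple[np.ndarray, np.ndarray]:
        """Reads overlapping ``[lo, hi)``, using the start-sorted order.

        The longest read length per chromosome is cached so the left
        boundary of the candidate slice can be found by bisection.
        """
        starts, ends = self.arrays(chrom)
        if starts.size == 0:
            return starts, ends
        if not hasattr(self, "_max_len"):
            self._max_len: dict[str, int] = {}
        if chrom not in self._max_len:
            self._max_len[chrom] = int((ends - starts).max())
        i0 = np.searchsorted(starts, lo - self._max_len[chrom], side="left")
        i1 = np.searchsorted(starts, hi, side="left")
        s, e = starts[i0:i1], ends[i0:i1]
        keep = e > lo
        return s[keep], e[keep]

    def __len__(self) -> int:
        return sum(s.size for s, _ in self._by_chrom.values())

    def __iter__(self) -> Iterator[Read]:
        for chrom in self.chroms():
            starts, ends = self._by_chrom[chrom]
            for s, e in zip(starts.tolist(), ends.tolist()):
                yield Read(chrom, s, e)

    def total_bases(self) -> int:
        """Sum of read lengths, the conserved mass of the coverage track."""
        return int(sum((e - s).sum() for s, e in self._by_chrom.values()))


class CoverageTrack:
    """Per-base read depth as sorted, non-overlapping (start, end, depth) runs.

    Zero-depth runs are omitted, matching the bedgraph ``-bg`` convention
    of genomeCoverageBed.
    """

    def __init__(self, runs_by_chrom: Mapping[str, Sequence[tuple[int, int, int]]] | None = None):
        self.runs: dict[str, list[tuple[int, int, int]]] = {}
        if runs_by_chrom:
            for chrom, runs in runs_by_chrom.items():
                self.runs[chrom] = [(int(s), int(e), int(d)) for s, e, d in runs]
                self._validate(chrom)

    def _validate(self, chrom: str) -> None:
        prev_end = -1
        for s, e, d in self.runs[chrom]:
            if s >= e or d < 0 or s < prev_end:
                raise ValueError(f"{chrom}: invalid coverage run ({s},{e},{d})")
            prev_end = e

    def chroms(self) -> list[str]:
        return sorted(self.runs)

    def total_area(self) -> int:
        return sum((e - s) * d for runs in self.runs.values() for s, e, d in runs)

    def depth_at(self, chrom: str, pos: int) -> int:
        for s, e, d in self.runs.get(chrom, []):
            if s <= pos < e:
                return d
        return 0

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CoverageTrack) and self.runs == other.runs


def _read_bed_frame(path, min_cols: int) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str,
                     skip_blank_lines=True)
    if df.shape[1] < min_cols:
        raise BedFormatError(f"{path}: expected >= {min_cols} tab-separated columns")
    return df


def read_gene_bed(path, default_strand: str | None = None) -> list[GeneModel]:
    """Parse a BED6 (or BED3 + ``default_strand``) gene file.

    Malformed lines raise :class:`BedFormatError` naming the 1-based line
    number. Strand must come from column 6 or ``default_strand``.
    """
    df = _read_bed_frame(path, 3)
    has_strand = df.shape[1] >= 6
    if not has_strand and default_strand is None:
        raise BedFormatError(
            f"{path}: no strand column and no default strand given"
        )
    genes: list[GeneModel] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        chrom = row[0]
        try:
            start, end = int(row[1]), int(row[2])
        except (TypeError, ValueError):
            raise BedFormatError(f"{path} line {idx}: non-integer coordinates") from None
        gene_id = str(row[3]) if df.shape[1] >= 4 and not pd.isna(row[3]) else f"gene_{idx}"
        strand = str(row[5]) if has_strand else default_strand
        try:
            genes.append(GeneModel(gene_id, str(chrom), start, end, strand))
        except ValueError as exc:
            raise BedFormatError(f"{path} line {idx}: {exc}") from None
    return genes


def collapse_genes(genes: Iterable[GeneModel]) -> list[GeneModel]:
    """Collapse models sharing a gene_id to one union span per symbol.

    The union span on a given strand automatically carries the most
    upstream TSS (min start on +, max end on -), so each gene symbol gets
    a single stalling index. Models with the same id on different
    chromosomes or strands are rejected.
    """
    grouped: dict[str, list[GeneModel]] = {}
    order: list[str] = []
    for g in genes:
        if g.gene_id not in grouped:
            order.append(g.gene_id)
        grouped.setdefault(g.gene_id, []).append(g)
    out = []
    for gid in order:
        models = grouped[gid]
        chroms = {m.chrom for m in models}
        strands = {m.strand for m in models}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"gene {gid}: models on multiple chromosomes/strands cannot be collapsed"
            )
        out.append(GeneModel(gid, models[0].chrom,
                             min(m.start for m in models),
                             max(m.end for m in models),
                             models[0].strand))
    return out


def read_reads_bed(path) -> ReadSet:
    """Parse a BED3+ file of mapped reads, sorted by (chrom, start)."""
    try:
        df = _read_bed_frame(path, 3)
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty read file, returning empty ReadSet", path)
        return ReadSet()
    rs = ReadSet()
    try:
        starts = df[1].astype(np.int64).to_numpy()
        ends = df[2].astype(np.int64).to_numpy()
    except (TypeError, ValueError):
        raise BedFormatError(f"{path}: non-integer read coordinates") from None
    bad = np.flatnonzero((starts < 0) | (starts >= ends))
    if bad.size:
        raise BedFormatError(
            f"{path} line {bad[0] + 1}: invalid read interval "
            f"[{starts[bad[0]]}, {ends[bad[0]]})"
        )
    for chrom, sub in df.groupby(0, sort=False):
        rs._add_arrays(str(chrom),
                       sub[1].astype(np.int64).to_numpy(),
                       sub[2].astype(np.int64).to_numpy())
    return rs


def write_reads_bed(reads: ReadSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in reads:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def write_gene_bed(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def coverage_from_reads(reads: ReadSet) -> CoverageTrack:
    """Per-base depth track: depth(b) = number of reads overlapping base b.

    Event-sweep per chromosome: +1 at each read start, -1 at each end,
    cumulative sum between distinct breakpoints; zero-depth runs dropped.
    """
    track = CoverageTrack()
    for chrom in reads.chroms():
        starts, ends = reads.arrays(chrom)
        if starts.size == 0:
            continue
        pos = np.concatenate([starts, ends])
        delta = np.concatenate([np.ones_like(starts), -np.ones_like(ends)])
        uniq, inv = np.unique(pos, return_inverse=True)
        net = np.zeros(uniq.size, dtype=np.int64)
        np.add.at(net, inv, delta)
        depth = np.cumsum(net)[:-1]  # depth on [uniq[i], uniq[i+1])
        runs = [
            (int(uniq[i]), int(uniq[i + 1]), int(depth[i]))
            for i in range(uniq.size - 1)
            if depth[i] > 0
        ]
        # merge adjacent runs of equal depth (unique breakpoints can split them)
        merged: list[tuple[int, int, int]] = []
        for s, e, d in runs:
            if merged and merged[-1][1] == s and merged[-1][2] == d:
                merged[-1] = (merged[-1][0], e, d)
            else:
                merged.append((s, e, d))
        track.runs[chrom] = merged
    return track


def write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for chrom in track.chroms():
            for s, e, d in track.runs[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\t{d}\n")


def read_bedgraph(path) -> CoverageTrack:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return CoverageTrack()
    runs: dict[str, list[tuple[int, int, int]]] = {}
    for row in df.itertuples(index=False):
        runs.setdefault(str(row[0]), []).append((int(row[1]), int(row[2]), int(row[3])))
    return CoverageTrack(runs)


def write_tsv(df: pd.DataFrame, path) -> None:
    """Write a tabular result: tab-separated, header line, UTF-8, '.' decimal."""
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
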