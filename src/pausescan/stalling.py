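"""Per-gene stalling index (SI) from Pol II ChIP-seq read positions.

The SI contrasts Pol II occupancy at the promoter with occupancy across
the gene body:

* promoter signal ``P``: the maximum read count over 600 bp sliding
  windows within a 5 kb region centred on the TSS;
* body signal ``B``: the median read count over non-overlapping 600 bp
  windows tiling the gene body (the gene model minus the 600 bp
  TSS-centred 5' proximal region, "5PRG");
* ``SI = log2((P + c) / (B + c))`` with pseudocount ``c`` (default 1).

Taking the body *median* per fixed-width window makes the ratio
independent of gene length; a high SI marks promoter-proximal Pol II
accumulation (pausing), SI near 0 marks uniform occupancy or silence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_io import GeneModel, ReadSet, collapse_genes

logger = logging.getLogger(__name__)

WINDOW = 600          # bp, width of the 5PRG and of every counting window
PROMOTER_FLANK = 2500  # bp, half-width of the TSS-centred promoter scan region

FLAG_OK = "ok"
FLAG_SHORT_GENE = "short_gene"
FLAG_ZERO_BODY = "zero_body"


@dataclass(frozen=True)
class RegionPair:
    """5PRG window and gene-body intervals derived from one gene model."""

    gene_id: str
    tss: int
    prg5: tuple[int, int]
    gene_body: tuple[tuple[int, int], ...]

    @property
    def body_width(self) -> int:
        return sum(e - s for s, e in self.gene_body)


def derive_regions(gene: GeneModel, window: int = WINDOW) -> RegionPair:
    """Split a gene into its TSS-centred 5PRG and the remaining gene body.

    The 5PRG is ``[tss - window/2, tss + window/2)``, clipped at position
    0; the gene body is the gene span minus the 5PRG (two intervals when
    the 5PRG falls inside the span, one when the TSS sits at an edge).
    """
    half = window // 2
    tss = gene.tss
    p_start = max(0, tss - half)
    p_end = tss + half
    if p_start == 0 and tss - half < 0:
        logger.warning("%s: 5PRG clipped at chromosome start", gene.gene_id)
    body = []
    if gene.start < p_start:
        body.append((gene.start, min(gene.end, p_start)))
    if gene.end > p_end:
        body.append((max(gene.start, p_end), gene.end))
    return RegionPair(gene.gene_id, tss, (p_start, p_end), tuple(body))


def _count_in_windows(reads: ReadSet, chrom: str, win_starts: np.ndarray,
                      win_ends: np.ndarray) -> np.ndarray:
    """Number of reads overlapping each window by >= 1 bp (any-overlap rule)."""
    starts, _ = reads.arrays(chrom)
    ends_sorted = reads.ends_sorted(chrom)
    # overlap([s,e)) = #{read start < e} - #{read end <= s}
    lt_end = np.searchsorted(starts, win_ends, side="left")
    le_start = np.searchsorted(ends_sorted, win_starts, side="right")
    return lt_end - le_start


def promoter_window_max(reads: ReadSet, chrom: str, tss: int,
                        step: int = 1, window: int = WINDOW,
                        flank: int = PROMOTER_FLANK) -> int:
    """Maximum sliding-window read count in the TSS-centred scan region.

    Windows are ``[s, s + window)`` for ``s`` in ``tss - flank, tss -
    flank + step, ...`` with ``s + window <= tss + flank``; a read counts
    toward a window when it overlaps it by at least one base. The scan
    region is clipped at position 0.

    With ``step=1`` the exact answer comes from an event sweep over the
    window-start axis (each read admits starts in a contiguous run), so
    no window enumeration is needed.
    """
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    lo = max(0, tss - flank)
    hi = tss + flank
    s_min, s_max = lo, max(lo, hi - window)
    # only reads overlapping the scan span can touch any window
    starts, ends = reads.slice_overlapping(chrom, s_min, s_max + window)
    if starts.size == 0:
        return 0
    if step == 1:
        # read [r0, r1) overlaps window [s, s+window) iff r0-window < s < r1,
        # i.e. integer s in [r0-window+1, r1-1]
        a = np.maximum(starts - window + 1, s_min)
        b = np.minimum(ends - 1, s_max)
        keep = a <= b
        if not keep.any():
            return 0
        # -1 events precede +1 events at equal positions (stable sort keeps
        # array order), so abutting start-runs are never double-counted
        pos = np.concatenate([b[keep] + 1, a[keep]])
        delta = np.concatenate(
            [-np.ones(int(keep.sum()), dtype=np.int64),
             np.ones(int(keep.sum()), dtype=np.int64)]
        )
        order = np.argsort(pos, kind="stable")
        running = np.cumsum(delta[order])
        return int(running.max())
    win_starts = np.arange(s_min, s_max + 1, step, dtype=np.int64)
    counts = _count_in_windows(reads, chrom, win_starts, win_starts + window)
    return int(counts.max())


def body_median(reads: ReadSet, chrom: str,
                gene_body: tuple[tuple[int, int], ...],
                window: int = WINDOW) -> tuple[float, int]:
    """Median read count over non-overlapping windows tiling the gene body.

    Each body interval is tiled left to right with ``window``-wide
    windows; a trailing fragment shorter than ``window`` is dropped.
    Returns ``(median, n_windows)``; with an even window count the median
    is the mean of the two central values. ``(nan, 0)`` when no interval
    admits a full window (short gene).
    """
    win_starts: list[np.ndarray] = []
    for b_start, b_end in gene_body:
        n = (b_end - b_start) // window
        if n > 0:
            win_starts.append(b_start + window * np.arange(n, dtype=np.int64))
    if not win_starts:
        return math.nan, 0
    ws = np.concatenate(win_starts)
    counts = _count_in_windows(reads, chrom, ws, ws + window)
    return float(np.median(counts)), int(ws.size)


def stalling_index(promoter_max: float, body_median: float,
                   pseudocount: float = 1.0) -> float:
    """``log2((P + c) / (B + c))``; finite for all non-negative inputs."""
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
    if promoter_max < 0 or body_median < 0:
        raise ValueError(
            f"counts must be non-negative, got P={promoter_max}, B={body_median}"
        )
    return math.log2((promoter_max + pseudocount) / (body_median + pseudocount))


def si_table(genes, reads: ReadSet, step: int = 1, window: int = WINDOW,
             flank: int = PROMOTER_FLANK, pseudocount: float = 1.0,
             collapse: bool = True) -> pd.DataFrame:
    """Compute one StallingRecord per (collapsed) gene.

    Columns: gene_id, promoter_max, body_median, n_body_windows, si,
    flag. Flags: ``short_gene`` (no full body window; SI computed with
    B=0 but the record should be excluded from distribution analysis),
    ``zero_body`` (body median 0; SI finite via the pseudocount), else
    ``ok``.
    """
    if collapse:
        genes = collapse_genes(genes)
    rows = []
    for gene in genes:
        regions = derive_regions(gene, window=window)
        p = promoter_window_max(reads, gene.chrom, regions.tss,
                                step=step, window=window, flank=flank)
        b, n_win = body_median(reads, gene.chrom, regions.gene_body, window=window)
        if n_win == 0:
            flag, b_for_si = FLAG_SHORT_GENE, 0.0
        else:
            flag = FLAG_ZERO_BODY if b == 0 else FLAG_OK
            b_for_si = b
        rows.append(
            {
                "gene_id": gene.gene_id,
                "promoter_max": p,
                "body_median": 0.0 if n_win == 0 else b,
                "n_body_windows": n_win,
                "si": stalling_index(p, b_for_si, pseudocount),
                "flag": flag,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "promoter_max", "body_median",
                 "n_body_windows", "si", "flag"],
    )


def distribution_si(table: pd.DataFrame) -> np.ndarray:
    """SI values entering the distribution: short-gene records excluded."""
    keep = table["flag"] != FLAG_SHORT_GENE
    return table.loc[keep, "si"].to_numpy(dtype=float)
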