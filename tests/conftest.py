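import numpy as np
import pytest

from pausescan.genomic_io import GeneModel, Read, ReadSet
from pausescan.simulate import SimConfig


@pytest.fixture
def small_config() -> SimConfig:
    """A desk-sized simulation: 60 genes on a 2 Mb chromosome."""
    return SimConfig(n_genes=60, chrom_length=2_000_000, seed=11)


@pytest.fixture
def toy_gene() -> GeneModel:
    return GeneModel("GeneA", "chr1", 1000, 5000, "+")


def make_readset(intervals, chrom="chr1") -> ReadSet:
    return ReadSet.from_reads(Read(chrom, s, e) for s, e in intervals)


def naive_depth(intervals, length):
    """Per-base oracle: depth by direct counting over every base."""
    depth = np.zeros(length, dtype=int)
    for s, e in intervals:
        depth[s:e] += 1
    return depth


def naive_window_max(intervals, s_min, s_max, window):
    """Exhaustive oracle: count overlapping reads at every window start.

    Enumerates all starts explicitly (a (starts x reads) overlap matrix),
    independent of the event-sweep implementation it checks.
    """
    if not intervals:
        return 0
    starts = np.arange(s_min, s_max + 1)[:, None]
    r0 = np.array([i[0] for i in intervals])[None, :]
    r1 = np.array([i[1] for i in intervals])[None, :]
    overlaps = (r0 < starts + window) & (r1 > starts)
    return int(overlaps.sum(axis=1).max())
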