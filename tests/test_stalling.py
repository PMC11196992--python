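import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pausescan.genomic_io import GeneModel, Read, ReadSet
from pausescan.stalling import (
    FLAG_OK,
    FLAG_SHORT_GENE,
    FLAG_ZERO_BODY,
    body_median,
    derive_regions,
    distribution_si,
    promoter_window_max,
    si_table,
    stalling_index,
)

from conftest import make_readset, naive_window_max


class TestDeriveRegions:
    @pytest.mark.parametrize(
        "gene, tss, prg5, body",
        [
            (GeneModel("a", "chr1", 1000, 5000, "+"), 1000, (700, 1300),
             ((1300, 5000),)),
            (GeneModel("b", "chr1", 1000, 5000, "-"), 5000, (4700, 5300),
             ((1000, 4700),)),
            # TSS near the chromosome start: 5PRG clipped at 0
            (GeneModel("c", "chr1", 0, 400, "+"), 0, (0, 300), ((300, 400),)),
            # interior TSS never happens for a 5'-anchored model, but a minus
            # gene's 5PRG protrudes downstream: body stays within the span
            (GeneModel("d", "chr1", 100, 700, "-"), 700, (400, 1000),
             ((100, 400),)),
        ],
    )
    def test_prg5_and_body(self, gene, tss, prg5, body):
        r = derive_regions(gene)
        assert (r.tss, r.prg5, r.gene_body) == (tss, prg5, body)

    def test_body_disjoint_from_prg5_and_within_span(self):
        g = GeneModel("g", "chr1", 2000, 9000, "-")
        r = derive_regions(g)
        p0, p1 = r.prg5
        for s, e in r.gene_body:
            assert g.start <= s < e <= g.end
            assert e <= p0 or s >= p1


window_starts = st.integers(0, 4964)  # reads inside a [0, 5000) region


class TestPromoterWindowMax:
    def test_no_reads_is_zero(self):
        assert promoter_window_max(ReadSet(), "chr1", 2500) == 0

    def test_tight_cluster_counts_all(self):
        rs = make_readset([(2400 + i, 2404 + i) for i in range(10)])
        assert promoter_window_max(rs, "chr1", 2500) == 10

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.tuples(window_starts, st.integers(1, 36)), min_size=1,
                    max_size=60))
    def test_sweep_equals_exhaustive_enumeration(self, raw):
        """The step=1 event sweep equals brute force over every window start."""
        intervals = [(s, s + L) for s, L in raw]
        rs = make_readset(intervals)
        tss = 2500
        got = promoter_window_max(rs, "chr1", tss, step=1)
        assert got == naive_window_max(intervals, 0, tss + 2500 - 600, 600)

    def test_coarse_step_bounded_by_exact(self):
        rng = np.random.default_rng(3)
        intervals = [(int(s), int(s) + 36) for s in rng.integers(0, 4900, 50)]
        rs = make_readset(intervals)
        exact = promoter_window_max(rs, "chr1", 2500, step=1)
        coarse = promoter_window_max(rs, "chr1", 2500, step=50)
        assert 0 < coarse <= exact


class TestBodyMedian:
    def test_median_of_enumerated_windows(self):
        # 5 windows over [1300, 4300); plant counts {0,1,2,3,10}
        intervals = []
        planted = [0, 1, 2, 3, 10]
        for w, n in enumerate(planted):
            lo = 1300 + 600 * w + 10
            intervals += [(lo + i, lo + i + 30) for i in range(n)]
        rs = make_readset(intervals)
        med, n_win = body_median(rs, "chr1", ((1300, 4300),))
        assert (med, n_win) == (2, 5)

    def test_zero_reads_zero_median(self):
        med, n_win = body_median(ReadSet(), "chr1", ((1300, 4300),))
        assert (med, n_win) == (0, 5)

    def test_trailing_fragment_dropped(self):
        med, n_win = body_median(ReadSet(), "chr1", ((0, 900),))
        assert n_win == 1

    def test_short_body_no_windows(self):
        med, n_win = body_median(ReadSet(), "chr1", ((0, 500),))
        assert n_win == 0 and math.isnan(med)

    def test_even_window_count_uses_midpoint(self):
        intervals = [(10, 40)] * 3  # window 0 count 3, window 1 count 0
        med, n_win = body_median(make_readset(intervals), "chr1", ((0, 1200),))
        assert (med, n_win) == (1.5, 2)


class TestStallingIndex:
    @pytest.mark.parametrize(
        "p, b, expected",
        [
            (5, 5, 0.0),
            (10, 1, math.log2(11 / 2)),
            (0, 7, -3.0),
        ],
    )
    def test_closed_form(self, p, b, expected):
        assert stalling_index(p, b) == pytest.approx(expected, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            stalling_index(-1, 2)
        with pytest.raises(ValueError):
            stalling_index(1, 2, pseudocount=0)


def _paused_like_gene():
    """A gene with a planted promoter peak and faint body."""
    gene = GeneModel("g", "chr1", 10_000, 16_000, "+")
    peak = [(9_900 + 2 * i, 9_936 + 2 * i) for i in range(40)]
    body = [(10_400 + 600 * w, 10_436 + 600 * w) for w in range(9)]
    return gene, peak + body


class TestSiTable:
    def test_composes_per_gene_manual_computation(self):
        genes = [
            GeneModel("pk", "chr1", 10_000, 16_000, "+"),
            GeneModel("mid", "chr1", 40_000, 46_000, "-"),
            GeneModel("empty", "chr1", 80_000, 86_000, "+"),
        ]
        _, pk_reads = _paused_like_gene()
        mid_reads = [(40_100 + 600 * w + i, 40_130 + 600 * w + i)
                     for w in range(9) for i in range(5)]
        rs = make_readset(pk_reads + mid_reads)
        table = si_table(genes, rs).set_index("gene_id")
        for gid, gene in zip(["pk", "mid", "empty"], genes):
            regions = derive_regions(gene)
            p = promoter_window_max(rs, "chr1", regions.tss)
            b, n = body_median(rs, "chr1", regions.gene_body)
            assert table.loc[gid, "promoter_max"] == p
            assert table.loc[gid, "si"] == pytest.approx(
                stalling_index(p, b), abs=1e-12)
        assert table.loc["empty", "flag"] == FLAG_ZERO_BODY
        assert table.loc["pk", "flag"] == FLAG_OK

    def test_empty_readset_all_zero(self, toy_gene):
        table = si_table([toy_gene], ReadSet())
        row = table.iloc[0]
        assert (row.promoter_max, row.body_median, row.si) == (0, 0, 0)

    def test_short_gene_flagged_and_excluded(self):
        genes = [GeneModel("short", "chr1", 1000, 1500, "+"),
                 GeneModel("ok", "chr1", 50_000, 56_000, "+")]
        table = si_table(genes, ReadSet())
        assert table.set_index("gene_id").loc["short", "flag"] == FLAG_SHORT_GENE
        assert len(distribution_si(table)) == 1


class TestSiProperties:
    def test_adding_peak_read_never_decreases_si(self):
        gene, intervals = _paused_like_gene()
        base = si_table([gene], make_readset(intervals))["si"][0]
        more = si_table([gene], make_readset(intervals + [(9_990, 10_026)]))["si"][0]
        assert more >= base

    def test_adding_read_to_every_body_window_never_increases_si(self):
        gene, intervals = _paused_like_gene()
        base = si_table([gene], make_readset(intervals))["si"][0]
        extra = [(10_500 + 600 * w, 10_530 + 600 * w) for w in range(9)]
        more = si_table([gene], make_readset(intervals + extra))["si"][0]
        assert more <= base

    def test_si_independent_of_gene_size(self):
        """Duplicating the body with identical per-window counts keeps SI."""
        gene, intervals = _paused_like_gene()
        long_gene = GeneModel("g", "chr1", gene.start, gene.end + 5400, "+")
        dup = [(s + 5400, e + 5400) for s, e in intervals
               if s >= 10_400]  # copy the 9 body windows once more
        si_short = si_table([gene], make_readset(intervals))["si"][0]
        si_long = si_table([long_gene], make_readset(intervals + dup))["si"][0]
        assert si_long == pytest.approx(si_short, abs=1e-12)

    def test_translation_invariance(self):
        gene, intervals = _paused_like_gene()
        shift = 123_456
        g2 = GeneModel("g", "chr1", gene.start + shift, gene.end + shift, "+")
        s1 = si_table([gene], make_readset(intervals))["si"][0]
        s2 = si_table([g2], make_readset([(s + shift, e + shift)
                                          for s, e in intervals]))["si"][0]
        assert s1 == s2
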