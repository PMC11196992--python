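# Methods

## Stalling index

Each gene model contributes one record. The TSS is `start` on the plus
strand, `end` on the minus strand. The 5′ proximal region (5PRG) is
`[tss − 300, tss + 300)`, clipped at position 0 (a clipped 5PRG is used
as-is with a logged warning). The gene body is the gene span minus the
5PRG — two intervals when the 5PRG is interior to the span, one when
the TSS sits at an edge.

**Promoter signal P.** All 600 bp windows `[s, s + 600)` with `s`
stepping through the 5 kb region centred on the TSS (`s + 600 ≤ tss +
2500`, region clipped at 0) are scored by the number of reads
overlapping the window by at least one base; P is the maximum. The
default step is 1 bp, computed exactly by an event sweep on the
window-start axis: each read admits a contiguous run of window starts,
so the maximum overlap of those runs is the answer without enumerating
windows. Decrement events are processed before increment events at
equal coordinates so abutting runs are not double-counted. Larger steps
(a speed/resolution trade-off) enumerate window starts and count reads
by binary search; a coarse step can only underestimate P.

**Body signal B.** Each body interval is tiled left-to-right with
non-overlapping 600 bp windows; trailing fragments shorter than 600 bp
are dropped. B is the median of the per-window read counts, with the
even-count median taken as the mean of the two central values. Genes
with zero full body windows are flagged `short_gene` and excluded from
distribution analysis.

**Index.** `SI = log2((P + c)/(B + c))` with pseudocount `c = 1`
(configurable, must be positive). The pseudocount keeps SI finite when
the body median is zero; such records are flagged `zero_body` but
retained in the distribution, since a silent gene's SI ≈ 0 is
informative — excluding them would delete the low mode's silent
component. Negative SI is possible (body denser than the promoter
scan's best window).

The per-window median makes SI independent of gene length: duplicating
a gene body with identical per-window counts leaves the median, and
hence SI, unchanged. SI is also invariant to translating all
coordinates by a constant. Both properties are asserted in the test
suite.

Counting reads (any-overlap rule, matching intersectBed defaults)
rather than summing per-base coverage is the primary mode; the coverage
track produced by `coverage_from_reads` is provided for visualisation
and export, not for SI.

## Cutoff detection

The genome-wide SI sample (short-gene records removed) is summarized by
a Gaussian KDE evaluated on a 512-point grid spanning the data range.
Bandwidth defaults to Silverman's rule; an absolute bandwidth in SI
units may be supplied (internally converted to scipy's sample-sd
factor). Local maxima of the gridded density are found; the two with
highest density are the modes, and the cutoff is the grid point of
minimum density strictly between them, taking the leftmost point on
ties (conservative: does not inflate the paused call set at equal
evidence). If fewer than two interior maxima exist the result is an
explicit no-cutoff outcome — the method never fabricates a threshold
for a unimodal sample. Identical inputs and bandwidth give bit-identical
cutoffs. The detected cutoff depends on the bandwidth (oversmoothing
merges the modes), which is why both the bandwidth and the histogram
bin width (default 0.2 SI units) are exposed on the command line.

The pause cutoff (a distributional valley) and the stringent selection
threshold SI ≥ 3.7 are deliberately independent parameters: one
describes the genome-wide occupancy distribution, the other is a fixed
bar for candidate calling.

## Candidate selection and ΔΔCt

A gene is a candidate paused IEG when `log2FC(1h) ≥ 2.5`, `log2FC(1h) ≥
log2FC(2h) + 1` (transient induction: at least a 2-fold drop-off by
2 h), and `SI ≥ 3.7` (stringent) or `SI ≥ 2.5` (relaxed). All
comparisons are inclusive, so boundary values pass; stringent passes
are a subset of relaxed passes by construction. Gene ids are matched
case-insensitively after trimming; ids present in only one table are
logged and skipped, never silently dropped, and the result is invariant
to row order. The differential-expression helper uses `|log2FC| ≥ 2`
per time point by default; the threshold is a parameter.

ΔΔCt: replicate Ct values are averaged on the Ct scale (arithmetic
mean), ΔCt = Ct(target) − Ct(reference) within each condition, and the
reported fold change is `2^−(ΔCt_treated − ΔCt_control)`. The result is
invariant to any common shift of all four Ct values.

## Synthetic data

The generator emulates the two occupancy archetypes the SI separates —
a paused gene (sharp TSS peak over a faint body) and a constitutively
elongating gene (reads along the whole body) — plus silent genes and a
post-stimulus expression time course. It does **not** model read
mappability, GC bias, fragment-size distributions, replicate libraries,
input/control tracks, or isoform structure; passing tests demonstrate
the correctness and statistical behaviour of the pipeline's
calculations, not robustness to those real-data artefacts.

Defaults (one 40 Mb chromosome, single global seed driving independent
derived streams per sub-generator):

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2000 | genes, ≥ 6 kb apart so 5 kb promoter scans never collide |
| `gene_length_range` | 3–8 kb | uniform gene lengths |
| `proportions` | 0.3 / 0.5 / 0.2 | paused / elongating / silent |
| `lambda_peak` | 200 | mean reads in the paused TSS peak (Poisson) |
| `peak_spread` | 100 bp | sd of Gaussian peak-read starts around the TSS |
| `lambda_body_low` | 2 | paused-gene body reads per 600 bp window |
| `lambda_body_high` | 40 | elongating-gene body reads per 600 bp window |
| `background_per_kb` | 0.05 | uniform background reads per kb |
| `read_length` | 36 bp | fixed, typical of early short-read ChIP-seq |
| `iegs_among_paused` | 0.05 | fraction of paused genes planted as IEGs |
| `fc_profiles` | IEG (3.5, 1.0) ± 0.3; late (1.0, 2.5) ± 0.3; flat (0, 0) ± 0.2 | class means/sds of (log2FC 1 h, log2FC 2 h) |
| `ct_sigma` | 0.15 cycles | qPCR Ct noise; 0 gives exact ΔΔCt inversion |

The peak/body rates put the paused mode near `log2(201/3) ≈ 6` and the
elongating mode near 0 (the sliding-window max over a Poisson body
introduces a small positive bias), reproducing a clearly bimodal SI
distribution at the default scale. IEGs are planted only among paused
genes — the design under study is release from pausing — at 5% of the
paused class (~30 of 600), the same order as the handful of candidates
expected among ~2000 high-occupancy genes in a real tissue; non-IEG
genes split evenly between late-rising and flat expression. Elongating
genes receive body reads only (no synthetic 5PRG pile-up), silent genes
only background. The trailing sub-600 bp fragment of a body is
simulated at a proportionally reduced Poisson rate so coverage has no
artificial gap, even though SI ignores that fragment.

The Ct generator shifts the treated-condition target Ct by the gene's
drawn `−log2FC(1h)` against a constant housekeeping reference, so with
`ct_sigma = 0` the ΔΔCt module inverts the planted fold change exactly
(verified to ~1e-15 in the reproducibility script).

## Numerical and design choices

* Coordinates: 0-based half-open throughout; BED6 in, TSV/bedgraph out.
* Gene models sharing an id are collapsed to the union span (one SI per
  symbol); the union automatically carries the most upstream TSS for
  the strand. Same-id models on different chromosomes or strands are an
  error, since no single span represents them.
* Reads are unstranded for all counting.
* Histogram bins are half-open with the top edge one bin beyond the
  maximum, so bin counts always sum to n.
* The replicate-recovery analysis in `scripts/acceptance.py` uses ten
  derived seeds per invocation and the default 2000-gene configuration;
  each full pass takes well under a second, and the whole script a few
  seconds.

## Known limitations

* A single fixed 600 bp / 5 kb window geometry; no per-gene adaptation
  for very short genes beyond the `short_gene` flag.
* KDE valley detection assumes two dominant modes; heavily skewed or
  three-mode SI distributions will return the valley between the two
  strongest modes only.
* No ChIP input normalization or peak calling; SI is a within-gene
  contrast and assumes roughly uniform background across the gene.
* The expression module consumes a precomputed fold-change table;
  microarray normalization and differential testing are upstream of
  this package.
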