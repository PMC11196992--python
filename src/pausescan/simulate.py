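"""Synthetic Pol II ChIP-seq and expression data with planted truth.

The generator emulates the two occupancy archetypes the stalling index
is built to separate — a paused gene with a sharp TSS-proximal read
pile-up over a faint gene body, and a constitutively elongating gene
with reads spread along the whole body — plus silent genes, uniform
genomic background, and the expression dynamics of a post-stimulus time
course (transient immediate-early induction, late rise, flat).

Every gene carries two planted labels (:class:`SimTruth` rows): a Pol II
class in {paused, elongating, silent} and an expression class in
{IEG, late, flat}. Read counts are Poisson; paused-peak read starts are
Gaussian around the TSS. One global seed drives independent derived
streams per sub-generator, so gene models, reads, fold changes and Ct
tables can each be regenerated separately and reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .genomic_io import GeneModel, ReadSet
from .stalling import derive_regions

POL2_CLASSES = ("paused", "elongating", "silent")
EXPR_CLASSES = ("IEG", "late", "flat")

# sub-stream indices for the derived per-module generators
_STREAM_GENES, _STREAM_READS, _STREAM_FC, _STREAM_CT = range(4)


def _default_proportions() -> dict[str, float]:
    return {"paused": 0.3, "elongating": 0.5, "silent": 0.2}


def _default_fc_profiles() -> dict[str, dict[str, tuple[float, float]]]:
    # mean and sd of (log2fc_1h, log2fc_2h) per expression class
    return {
        "IEG": {"mean": (3.5, 1.0), "sd": (0.3, 0.3)},
        "late": {"mean": (1.0, 2.5), "sd": (0.3, 0.3)},
        "flat": {"mean": (0.0, 0.0), "sd": (0.2, 0.2)},
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Rates are per 600 bp counting window unless stated otherwise. The
    defaults describe a liver-sized but single-chromosome design: 2000
    well-separated genes, a 200-read average paused peak over a 2-read
    body, a 40-read elongating body, and sparse background.
    """

    n_genes: int = 2000
    chrom: str = "chrS"
    chrom_length: int = 40_000_000
    gene_length_range: tuple[int, int] = (3000, 8000)
    min_gene_gap: int = 6000          # keeps 5 kb promoter scans from colliding
    proportions: dict[str, float] = field(default_factory=_default_proportions)
    lambda_peak: float = 200.0        # mean reads in the paused TSS peak
    lambda_body_low: float = 2.0      # paused-gene body reads / 600 bp window
    lambda_body_high: float = 40.0    # elongating-gene body reads / 600 bp window
    peak_spread: float = 100.0        # sd (bp) of peak read starts around the TSS
    background_per_kb: float = 0.05   # uniform background reads per kb
    read_length: int = 36
    iegs_among_paused: float = 0.05   # fraction of paused genes planted as IEGs
    fc_profiles: dict = field(default_factory=_default_fc_profiles)
    ct_sigma: float = 0.15            # sd (cycles) of qPCR Ct noise
    ct_reference_level: float = 20.0  # baseline Ct of the housekeeping reference
    ct_target_level: float = 26.0     # baseline Ct of targets in the control
    n_ct_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.gene_length_range = tuple(self.gene_length_range)
        self.fc_profiles = {
            cls: {"mean": tuple(p["mean"]), "sd": tuple(p["sd"])}
            for cls, p in self.fc_profiles.items()
        }
        props = self.proportions
        if set(props) != set(POL2_CLASSES):
            raise ValueError(f"proportions must have keys {POL2_CLASSES}")
        if any(p < 0 for p in props.values()) or abs(sum(props.values()) - 1) > 1e-9:
            raise ValueError("class proportions must be in [0,1] and sum to 1")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError(f"bad gene_length_range {self.gene_length_range}")
        for name in ("lambda_peak", "lambda_body_low", "lambda_body_high",
                     "background_per_kb", "peak_spread", "ct_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.iegs_among_paused <= 1:
            raise ValueError("iegs_among_paused must be in [0,1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one sub-module, derived from the seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream,)))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "gene_length_range" in raw:
            raw["gene_length_range"] = tuple(raw["gene_length_range"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        def listify(obj):
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return [listify(v) for v in obj]
            return obj

        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(listify(asdict(self)), fh, sort_keys=False)


def _class_counts(n: int, proportions: dict[str, float], order) -> list[int]:
    counts = [int(round(proportions[c] * n)) for c in order]
    counts[-1] += n - sum(counts)  # absorb rounding in the last class
    return counts


def simulate_genes(config: SimConfig) -> tuple[list[GeneModel], pd.DataFrame]:
    """Place non-overlapping genes and assign both planted class labels.

    Genes are separated by at least ``min_gene_gap`` so neighbouring
    promoter scans never overlap. Returns the gene models and the
    SimTruth table (gene_id, pol2_class, expr_class).
    """
    rng = config.rng(_STREAM_GENES)
    n = config.n_genes
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    required = int(lengths.sum()) + (n + 1) * config.min_gene_gap
    if required > config.chrom_length:
        raise ValueError(
            f"{n} genes need >= {required} bp but chrom_length is "
            f"{config.chrom_length}; increase chrom_length"
        )
    slack = config.chrom_length - required
    extra = rng.integers(0, slack // (n + 1) + 1, size=n + 1)
    gaps = config.min_gene_gap + extra
    starts = np.cumsum(gaps)[:-1] + np.concatenate([[0], np.cumsum(lengths[:-1])])
    strands = rng.choice(np.array(["+", "-"]), size=n)

    pol2 = np.repeat(POL2_CLASSES,
                     _class_counts(n, config.proportions, POL2_CLASSES))
    pol2 = pol2[rng.permutation(n)]

    expr = np.empty(n, dtype=object)
    paused_idx = np.flatnonzero(pol2 == "paused")
    n_ieg = int(round(config.iegs_among_paused * paused_idx.size))
    ieg_idx = rng.permutation(paused_idx)[:n_ieg]
    expr[ieg_idx] = "IEG"
    rest = np.setdiff1d(np.arange(n), ieg_idx)
    rest = rest[rng.permutation(rest.size)]
    expr[rest[: rest.size // 2]] = "late"
    expr[rest[rest.size // 2:]] = "flat"

    genes = [
        GeneModel(f"g{i:05d}", config.chrom, int(s), int(s + L), str(st))
        for i, (s, L, st) in enumerate(zip(starts, lengths, strands))
    ]
    truth = pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes],
         "pol2_class": pol2, "expr_class": expr}
    )
    return genes, truth


def simulate_reads(genes, truth: pd.DataFrame, config: SimConfig) -> ReadSet:
    """Draw Pol II read placements according to each gene's planted class.

    paused: Poisson(lambda_peak) reads with Gaussian starts around the
    TSS plus Poisson(lambda_body_low) per body window; elongating:
    Poisson(lambda_body_high) per body window only; silent: nothing.
    Uniform background covers the whole chromosome. Fixed read length.
    """
    rng = config.rng(_STREAM_READS)
    L = config.read_length
    class_of = dict(zip(truth["gene_id"], truth["pol2_class"]))
    starts_out: list[np.ndarray] = []

    for gene in genes:
        cls = class_of[gene.gene_id]
        if cls == "silent":
            continue
        regions = derive_regions(gene)
        if cls == "paused":
            n_peak = rng.poisson(config.lambda_peak)
            peak = np.rint(rng.normal(regions.tss, config.peak_spread, n_peak))
            starts_out.append(np.clip(peak, 0, config.chrom_length - L))
            body_rate = config.lambda_body_low
        else:
            body_rate = config.lambda_body_high
        for b_start, b_end in regions.gene_body:
            width = b_end - b_start
            n_full, frac = divmod(width, 600)
            lam = np.full(n_full + (frac > 0), body_rate)
            if frac:
                lam[-1] *= frac / 600  # trailing fragment at proportional rate
            counts = rng.poisson(lam)
            for k, c in enumerate(counts):
                if c == 0:
                    continue
                w_lo = b_start + 600 * k
                w_hi = min(b_end, w_lo + 600)
                starts_out.append(rng.integers(w_lo, w_hi, size=c))

    n_bg = rng.poisson(config.background_per_kb * config.chrom_length / 1000)
    if n_bg:
        starts_out.append(rng.integers(0, config.chrom_length - L, size=n_bg))

    if starts_out:
        starts = np.concatenate(starts_out).astype(np.int64)
    else:
        starts = np.empty(0, dtype=np.int64)
    return ReadSet({config.chrom: (starts, starts + L)})


def simulate_fc_table(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Per-gene log2 fold changes at 1 h and 2 h from the class profiles."""
    rng = config.rng(_STREAM_FC)
    rows = []
    for row in truth.itertuples(index=False):
        prof = config.fc_profiles[row.expr_class]
        (m1, m2), (s1, s2) = prof["mean"], prof["sd"]
        rows.append({
            "gene_id": row.gene_id,
            "log2fc_1h": rng.normal(m1, s1) if s1 > 0 else m1,
            "log2fc_2h": rng.normal(m2, s2) if s2 > 0 else m2,
        })
    return pd.DataFrame(rows, columns=["gene_id", "log2fc_1h", "log2fc_2h"])


def simulate_ct_table(fc_table: pd.DataFrame, config: SimConfig,
                      control: str = "prePH",
                      treated: str = "PH1h") -> pd.DataFrame:
    """qPCR Ct tables whose ΔΔCt inverts the planted 1 h fold change.

    The housekeeping reference Ct is constant across conditions; the
    target Ct in the treated condition is shifted by -log2fc_1h relative
    to the control, plus Normal(0, ct_sigma) noise per well. With
    ct_sigma=0, :func:`pausescan.expression.ddct_table` recovers
    2^log2fc_1h exactly.
    """
    rng = config.rng(_STREAM_CT)
    sigma = config.ct_sigma
    rows = []

    def noise() -> float:
        return float(rng.normal(0, sigma)) if sigma > 0 else 0.0

    for row in fc_table.itertuples(index=False):
        for rep in range(1, config.n_ct_replicates + 1):
            rows.append({
                "gene_id": row.gene_id, "condition": control,
                "ct_target": config.ct_target_level + noise(),
                "ct_reference": config.ct_reference_level + noise(),
                "replicate": rep,
            })
            rows.append({
                "gene_id": row.gene_id, "condition": treated,
                "ct_target": config.ct_target_level - row.log2fc_1h + noise(),
                "ct_reference": config.ct_reference_level + noise(),
                "replicate": rep,
            })
    return pd.DataFrame(rows, columns=["gene_id", "condition", "ct_target",
                                       "ct_reference", "replicate"])
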