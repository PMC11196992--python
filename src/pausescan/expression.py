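"""Expression dynamics: DE calls, paused-IEG candidate selection, ΔΔCt.

An immediate-early gene (IEG) candidate is a gene that is both strongly
and transiently induced at 1 h post-stimulus and carries a high stalling
index. All threshold comparisons are inclusive (``>=``).

Selection criteria (defaults):

* ``log2FC(1h) >= 2.5``                (strong early induction)
* ``log2FC(1h) >= log2FC(2h) + 1``     (transient: down by 2-fold at 2 h)
* ``SI >= 3.7`` (stringent) or ``SI >= 2.5`` (relaxed)

ΔΔCt follows the standard 2^-ΔΔCt relative quantification: the target
gene's cycle threshold is normalized to a housekeeping reference within
each condition, and the normalized difference between conditions is
exponentiated.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FC1_MIN = 2.5
DELTA_MIN = 1.0
SI_STRINGENT = 3.7
SI_RELAXED = 2.5
DE_THRESHOLD = 2.0

EXPR_COLUMNS = ("gene_id", "log2fc_1h", "log2fc_2h")
CT_COLUMNS = ("gene_id", "condition", "ct_target", "ct_reference", "replicate")


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing column(s) {missing}")


def classify_de(records: pd.DataFrame,
                fc_threshold: float = DE_THRESHOLD) -> dict[str, set[str]]:
    """Differentially expressed gene sets per time point and their union.

    A gene is DE at a time point iff ``|log2FC| >= fc_threshold`` there.
    """
    if fc_threshold <= 0:
        raise ValueError(f"fc_threshold must be > 0, got {fc_threshold}")
    _require_columns(records, EXPR_COLUMNS, "expression table")
    de_1h = set(records.loc[records["log2fc_1h"].abs() >= fc_threshold, "gene_id"])
    de_2h = set(records.loc[records["log2fc_2h"].abs() >= fc_threshold, "gene_id"])
    return {"1h": de_1h, "2h": de_2h, "union": de_1h | de_2h}


def _norm_id(s: pd.Series) -> pd.Series:
    return s.astype(str).str.strip().str.casefold()


def select_candidates(si_table: pd.DataFrame, expr_table: pd.DataFrame,
                      mode: str = "stringent", fc1_min: float = FC1_MIN,
                      delta_min: float = DELTA_MIN,
                      si_stringent: float = SI_STRINGENT,
                      si_relaxed: float = SI_RELAXED) -> pd.DataFrame:
    """Call candidate paused IEGs by intersecting SI and induction criteria.

    Gene ids are matched case-insensitively after trimming; genes present
    in only one table are logged and skipped. Returns the genes passing
    the requested mode, sorted by descending SI, with both
    ``passes_stringent`` and ``passes_relaxed`` flags (stringent passes
    are always a subset of relaxed passes).
    """
    if mode not in ("stringent", "relaxed"):
        raise ValueError(f"mode must be 'stringent' or 'relaxed', got {mode!r}")
    _require_columns(si_table, ("gene_id", "si"), "SI table")
    _require_columns(expr_table, EXPR_COLUMNS, "expression table")

    si = si_table.assign(_key=_norm_id(si_table["gene_id"]))
    expr = expr_table.assign(_key=_norm_id(expr_table["gene_id"]))
    merged = si.merge(expr[["_key", "log2fc_1h", "log2fc_2h"]], on="_key", how="inner")
    unmatched_si = set(si["_key"]) - set(expr["_key"])
    unmatched_expr = set(expr["_key"]) - set(si["_key"])
    if unmatched_si:
        logger.info("%d gene(s) in SI table without expression data", len(unmatched_si))
    if unmatched_expr:
        logger.info("%d gene(s) in expression table without SI", len(unmatched_expr))
    if len(si) and len(expr) and merged.empty:
        raise ValueError("no gene ids shared between SI and expression tables")

    induced = (merged["log2fc_1h"] >= fc1_min) & (
        merged["log2fc_1h"] >= merged["log2fc_2h"] + delta_min
    )
    out = merged.assign(
        passes_stringent=induced & (merged["si"] >= si_stringent),
        passes_relaxed=induced & (merged["si"] >= si_relaxed),
    )
    keep = out["passes_stringent"] if mode == "stringent" else out["passes_relaxed"]
    cols = ["gene_id", "si", "log2fc_1h", "log2fc_2h",
            "passes_stringent", "passes_relaxed"]
    return (
        out.loc[keep, cols]
        .sort_values("si", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def ddct_fold_change(ct_target_treated: float, ct_ref_treated: float,
                     ct_target_control: float, ct_ref_control: float) -> float:
    """Linear fold change by the 2^-ΔΔCt method.

    ΔCt = Ct(target) - Ct(reference) within each condition; ΔΔCt =
    ΔCt(treated) - ΔCt(control); fold change = 2^-ΔΔCt.
    """
    cts = (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control)
    if not all(np.isfinite(cts)):
        raise ValueError(f"Ct values must be finite, got {cts}")
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-ddct))


def ddct_table(ct: pd.DataFrame, control: str) -> pd.DataFrame:
    """Per-gene fold change of every condition against ``control``.

    Replicate Ct values are averaged (arithmetic mean on the Ct scale)
    before the ΔΔCt computation. Returns columns gene_id, condition,
    fold_change, log2_fold_change.
    """
    _require_columns(ct, CT_COLUMNS[:4], "Ct table")
    mean_ct = (
        ct.groupby(["gene_id", "condition"], sort=False)[["ct_target", "ct_reference"]]
        .mean()
        .reset_index()
    )
    if control not in set(mean_ct["condition"]):
        raise ValueError(f"control condition {control!r} absent from Ct table")
    ctrl = mean_ct[mean_ct["condition"] == control].set_index("gene_id")
    rows = []
    for row in mean_ct[mean_ct["condition"] != control].itertuples(index=False):
        if row.gene_id not in ctrl.index:
            logger.info("%s: no control-condition Ct, skipped", row.gene_id)
            continue
        c = ctrl.loc[row.gene_id]
        fc = ddct_fold_change(row.ct_target, row.ct_reference,
                              float(c["ct_target"]), float(c["ct_reference"]))
        rows.append({"gene_id": row.gene_id, "condition": row.condition,
                     "fold_change": fc, "log2_fold_change": float(np.log2(fc))})
    return pd.DataFrame(rows, columns=["gene_id", "condition",
                                       "fold_change", "log2_fold_change"])
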