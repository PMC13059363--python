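"""Expression count filtering, stand-in differential-expression test,
DEG thresholding and the two-group set algebra.

The DE test is a documented stand-in for a negative-binomial GLM fit:
median-of-ratios size factors, fold change from pseudocounted normalized
means and a Welch test on log2-normalized counts, BH-corrected. Precomputed
DE tables (gene_id, log2fc, pvalue, padj) slot straight into
:func:`filter_degs`.

Study thresholds, kept as strict defaults: total counts below 10 dropped;
DEG iff p_adj < 0.05 and |log2FC| > 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust

__all__ = [
    "filter_low_counts",
    "size_factors",
    "standin_de_test",
    "filter_degs",
    "deg_set_algebra",
]


def filter_low_counts(matrix: pd.DataFrame, min_total: int = 10) -> pd.DataFrame:
    """Drop genes whose total count across all samples is below ``min_total``."""
    keep = matrix.sum(axis=1) >= min_total
    return matrix[keep]


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over genes expressed in every sample."""
    counts = matrix.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene expressed in every sample; cannot normalise")
    log_geo = np.log(counts[positive]).mean(axis=1)
    sf = np.exp(np.median(np.log(counts[positive]) - log_geo[:, None], axis=0))
    return pd.Series(sf, index=matrix.columns, name="size_factor")


def standin_de_test(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    group: str,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Two-condition differential expression for one phenotype group.

    Uses the group's control vs drought samples: size-factor-normalised
    counts, ``log2fc = log2((mean_drought + pc) / (mean_control + pc))``,
    Welch's test on log2(normalised + pc) and BH adjustment.

    Returns a frame ``gene_id, log2fc, p_value, p_adj, direction`` with
    direction up iff log2fc > 0.
    """
    sub = samples[(samples["group"] == group) & samples["sample_id"].isin(matrix.columns)]
    ctrl_ids = sub.loc[sub["treatment"] == "control", "sample_id"].to_list()
    drt_ids = sub.loc[sub["treatment"] == "drought", "sample_id"].to_list()
    if len(ctrl_ids) < 2 or len(drt_ids) < 2:
        raise ValueError(
            f"group {group!r} needs >= 2 samples per condition "
            f"(got {len(ctrl_ids)} control, {len(drt_ids)} drought)"
        )
    both = ctrl_ids + drt_ids
    sf = size_factors(matrix[both])
    norm = matrix[both].to_numpy(dtype=float) / sf.to_numpy()[None, :]
    nc = len(ctrl_ids)
    ctrl = norm[:, :nc]
    drt = norm[:, nc:]

    mean_c = ctrl.mean(axis=1)
    mean_d = drt.mean(axis=1)
    log2fc = np.log2(mean_d + pseudocount) - np.log2(mean_c + pseudocount)

    log_ctrl = np.log2(ctrl + pseudocount)
    log_drt = np.log2(drt + pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(log_drt, log_ctrl, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    padj = bh_adjust(p)
    return pd.DataFrame(
        {
            "gene_id": matrix.index,
            "log2fc": log2fc,
            "p_value": p,
            "p_adj": padj,
            "direction": np.where(log2fc > 0, "up", "down"),
        }
    ).reset_index(drop=True)


def filter_degs(records: pd.DataFrame, padj_max: float = 0.05, lfc_min: float = 1.0) -> pd.DataFrame:
    """Keep genes with ``p_adj < padj_max`` and ``|log2fc| > lfc_min`` (both strict)."""
    if "p_adj" not in records.columns or records["p_adj"].isna().any():
        raise ValueError("records must carry a complete p_adj column")
    keep = (records["p_adj"] < padj_max) & (records["log2fc"].abs() > lfc_min)
    return records[keep].reset_index(drop=True)


def deg_set_algebra(sensitive: pd.DataFrame, tolerant: pd.DataFrame) -> dict:
    """Two-group DEG bookkeeping: totals, intersection, specifics, fold
    ratio of sensitive over tolerant (1 dp) and per-group up/down
    proportions (percent, 1 dp; only when direction columns are present).

    Inputs are DEG frames with a ``gene_id`` column (and optionally
    ``direction``), or plain iterables of gene ids.
    """
    def as_frame(x):
        if isinstance(x, pd.DataFrame):
            return x
        return pd.DataFrame({"gene_id": list(x)})

    s, t = as_frame(sensitive), as_frame(tolerant)
    s_ids, t_ids = set(s["gene_id"]), set(t["gene_id"])
    if len(t_ids) == 0:
        raise ValueError("empty tolerant DEG set: fold ratio undefined")
    common = s_ids & t_ids
    out = {
        "total_sensitive": len(s_ids),
        "total_tolerant": len(t_ids),
        "common": len(common),
        "specific_sensitive": len(s_ids - t_ids),
        "specific_tolerant": len(t_ids - s_ids),
        "fold_ratio": round(len(s_ids) / len(t_ids), 1),
    }
    for name, frame in (("sensitive", s), ("tolerant", t)):
        if "direction" in frame.columns and len(frame) > 0:
            up = int((frame["direction"] == "up").sum())
            out[f"up_pct_{name}"] = round(100.0 * up / len(frame), 1)
            out[f"down_pct_{name}"] = round(100.0 * (len(frame) - up) / len(frame), 1)
    return out
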