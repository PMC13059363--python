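"""Per-context methylation levels, global summaries, metagene profiles and
window-level sample correlation.

Levels are *weighted* methylation levels — sum of methylated read counts over
sum of total read counts across a region's cytosines of one context — which
is the standard for count-based bisulfite data. Positions in the record
frames are 1-based (CX convention); intervals are 0-based half-open, so a
site at position ``p`` falls in ``[start, end)`` iff ``start < p <= end``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CONTEXTS

__all__ = [
    "EXPRESSION_GROUPS",
    "weighted_methylation",
    "global_context_summary",
    "metagene_profile",
    "expression_sextiles",
    "window_correlation_matrix",
]

#: Six expression strata, from silent to highest quintile of expressed genes.
EXPRESSION_GROUPS = ("none", "low", "medium-low", "medium", "medium-high", "high")


def weighted_methylation(records, region, context, min_coverage: int = 4):
    """Weighted methylation level of one context over one region.

    ``region`` is ``(chrom, start, end)`` with 0-based half-open coordinates.
    Only cytosines with ``n_total >= min_coverage`` enter the sums; if none
    are present the result is ``nan`` (a no-data marker, deliberately not 0).
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    chrom, start, end = region
    m = (
        (records["chrom"] == chrom)
        & (records["pos"] > start)
        & (records["pos"] <= end)
        & (records["context"] == context)
        & (records["n_total"] >= min_coverage)
    )
    tot = int(records.loc[m, "n_total"].sum())
    if tot == 0:
        return float("nan")
    return float(records.loc[m, "n_meth"].sum()) / tot


def global_context_summary(records, min_coverage: int = 4) -> pd.DataFrame:
    """Genome-wide per-context summary: mean weighted level (percent) and the
    share of all methylated-cytosine calls attributed to each context.

    The ``pct_of_total_mC`` column sums to 100 across the three contexts.
    Raises on an empty record set or when no methylated calls exist at all.
    """
    if len(records) == 0:
        raise ValueError("empty record set")
    covered = records[records["n_total"] >= min_coverage]
    meth_by_ctx = covered.groupby("context", observed=True)["n_meth"].sum()
    total_by_ctx = covered.groupby("context", observed=True)["n_total"].sum()
    all_meth = float(meth_by_ctx.sum())
    if all_meth == 0:
        raise ValueError("no methylated cytosine calls: percentage of total mC undefined")
    rows = []
    for ctx in CONTEXTS:
        tot = float(total_by_ctx.get(ctx, 0))
        mc = float(meth_by_ctx.get(ctx, 0))
        level = float("nan") if tot == 0 else 100.0 * mc / tot
        rows.append((ctx, level, 100.0 * mc / all_meth))
    return pd.DataFrame(rows, columns=["context", "mean_level", "pct_of_total_mC"])


def _bin_edges(start: float, end: float, n: int) -> np.ndarray:
    # fractional edges handle genes shorter than the bin count
    return np.linspace(start, end, n + 1)


def metagene_profile(
    genes: pd.DataFrame,
    records: pd.DataFrame,
    expression_groups,
    flank: int = 2000,
    bins_per_segment: int = 50,
    contexts=CONTEXTS,
    min_coverage: int = 1,
) -> pd.DataFrame:
    """Binned metagene methylation profiles by expression stratum.

    Each gene contributes three segments — ``flank`` bp upstream of the TSS,
    the gene body, and ``flank`` bp downstream of the TES — each divided into
    ``bins_per_segment`` bins (150 total by default). Minus-strand genes are
    coordinate-reflected so bin 0 is always most-5'. The value of a bin is
    the gene's weighted level over the cytosines falling in it, averaged
    across the genes of the stratum (no-data bins are skipped in the mean).

    ``expression_groups`` maps gene_id -> stratum label.

    Returns a long frame ``(context, expression_group, bin_index, value)``.
    """
    nb = bins_per_segment
    acc_sum: dict[tuple[str, str], np.ndarray] = {}
    acc_n: dict[tuple[str, str], np.ndarray] = {}
    rec_by_chrom = {c: df for c, df in records.groupby("chrom", observed=True)}

    for grow in genes.itertuples(index=False):
        label = expression_groups.get(grow.gene_id) if hasattr(expression_groups, "get") \
            else expression_groups[grow.gene_id]
        if label is None:
            continue
        chrom_rec = rec_by_chrom.get(grow.chrom)
        if chrom_rec is None:
            continue
        lo, hi = grow.start - flank, grow.end + flank
        window = chrom_rec[(chrom_rec["pos"] > lo) & (chrom_rec["pos"] <= hi)]
        for ctx in contexts:
            sub = window[(window["context"] == ctx) & (window["n_total"] >= min_coverage)]
            key = (ctx, label)
            if key not in acc_sum:
                acc_sum[key] = np.zeros(3 * nb)
                acc_n[key] = np.zeros(3 * nb)
            if len(sub) == 0:
                continue
            # map 1-based positions to the 0-based axis: x = pos - 1 + 0.5
            x = sub["pos"].to_numpy(dtype=float) - 0.5
            edges = np.concatenate(
                [
                    _bin_edges(grow.start - flank, grow.start, nb)[:-1],
                    _bin_edges(grow.start, grow.end, nb)[:-1],
                    _bin_edges(grow.end, grow.end + flank, nb),
                ]
            )
            idx = np.searchsorted(edges, x, side="right") - 1
            ok = (idx >= 0) & (idx < 3 * nb)
            idx = idx[ok]
            mc = sub["n_meth"].to_numpy(dtype=float)[ok]
            tc = sub["n_total"].to_numpy(dtype=float)[ok]
            msum = np.bincount(idx, weights=mc, minlength=3 * nb)
            tsum = np.bincount(idx, weights=tc, minlength=3 * nb)
            if grow.strand == "-":
                msum = msum[::-1]
                tsum = tsum[::-1]
            has = tsum > 0
            level = np.zeros(3 * nb)
            level[has] = msum[has] / tsum[has]
            acc_sum[key][has] += level[has]
            acc_n[key][has] += 1

    rows = []
    for (ctx, label), s in sorted(acc_sum.items()):
        n = acc_n[(ctx, label)]
        vals = np.where(n > 0, s / np.maximum(n, 1), np.nan)
        for b in range(3 * nb):
            rows.append((ctx, label, b, vals[b]))
    return pd.DataFrame(rows, columns=["context", "expression_group", "bin_index", "value"])


def expression_sextiles(mean_expression: pd.Series) -> pd.Series:
    """Assign each gene to one of six expression strata.

    Genes with mean expression exactly 0 form the ``none`` stratum; the
    remaining genes are split into five equal-size quantile groups of
    increasing expression. Ties are broken by stable gene-id order, so group
    membership is invariant under any monotone transform of the values.
    """
    if len(mean_expression) == 0:
        raise ValueError("empty expression input")
    if (mean_expression < 0).any():
        raise ValueError("mean expression must be non-negative")
    labels = pd.Series("none", index=mean_expression.index, dtype=object)
    nz = mean_expression[mean_expression > 0]
    if len(nz) > 0:
        # stable sort: by value, then by gene id
        idx_sorted = sorted(nz.index, key=lambda g: (nz[g], str(g)))
        chunks = np.array_split(np.asarray(idx_sorted, dtype=object), 5)
        for chunk, lab in zip(chunks, EXPRESSION_GROUPS[1:]):
            labels.loc[list(chunk)] = lab
    return labels


def window_correlation_matrix(
    sample_records: dict[str, pd.DataFrame],
    window: int = 2000,
    context: str = "CHH",
    min_coverage: int = 1,
) -> pd.DataFrame:
    """Pearson correlation between samples over fixed genomic windows.

    Each sample is reduced to its weighted methylation level per ``window``-bp
    tile of the genome (one context); pairs correlate over the tiles where
    both have data. Entries with fewer than 2 usable windows are ``nan``.
    """
    ids = list(sample_records)
    if len(ids) < 2:
        raise ValueError("need at least two samples")
    profiles = {}
    keys = None
    for sid, rec in sample_records.items():
        sub = rec[(rec["context"] == context) & (rec["n_total"] >= min_coverage)].copy()
        sub["win"] = (sub["pos"] - 1) // window
        g = sub.groupby(["chrom", "win"], observed=True)[["n_meth", "n_total"]].sum()
        lvl = g["n_meth"] / g["n_total"]
        profiles[sid] = lvl
        keys = lvl.index if keys is None else keys.union(lvl.index)
    mat = pd.DataFrame(index=ids, columns=ids, dtype=float)
    aligned = {sid: profiles[sid].reindex(keys) for sid in ids}
    for i, a in enumerate(ids):
        mat.loc[a, a] = 1.0
        for b in ids[i + 1:]:
            x, y = aligned[a], aligned[b]
            ok = x.notna() & y.notna()
            if ok.sum() < 2 or x[ok].std() == 0 or y[ok].std() == 0:
                r = float("nan")
            else:
                r = float(np.corrcoef(x[ok], y[ok])[0, 1])
            mat.loc[a, b] = r
            mat.loc[b, a] = r
    return mat
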