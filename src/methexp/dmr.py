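"""DMR calling, context-threshold filtering, conserved-region merging,
genotype support, feature annotation and summary bookkeeping.

Per-genotype candidate regions come from a sliding-window two-proportion
test on pooled cytosine counts (control vs drought), a documented stand-in
for smoothing-based DMR callers; precomputed DMR tables with deltas and
p-values can be fed straight into :func:`filter_significant` instead.

Sign convention throughout: ``delta = meth_drought - meth_control``, so
hyper-methylation means a drought-induced gain.

The study thresholds, kept as defaults:

* significance per context, strict: CG |Δ| > 0.20, CHG |Δ| > 0.15,
  CHH |Δ| > 0.25;
* conserved merging within a phenotype group at a maximum gap of 100 bp
  (gap <= 100 merges);
* a conserved DMR needs support from at least 3 genotypes of its group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import CONTEXTS, subgenome_of

__all__ = [
    "CONTEXT_DELTA_THRESHOLDS",
    "call_candidate_dmrs",
    "filter_significant",
    "merge_conserved",
    "support_filter",
    "annotate_feature",
    "dmr_count_table",
    "chromosome_density",
]

#: Strict per-context |delta| thresholds (fraction scale) for significant DMRs.
CONTEXT_DELTA_THRESHOLDS = {"CG": 0.20, "CHG": 0.15, "CHH": 0.25}

DMR_COLUMNS = [
    "chrom", "start", "end", "context", "meth_control", "meth_drought",
    "delta", "p_value", "genotype_id", "group",
]


def _two_proportion_p(mc, tc, md, td):
    """Vectorised two-sided two-proportion score test on pooled counts."""
    mc, tc, md, td = (np.asarray(a, dtype=float) for a in (mc, tc, md, td))
    p1 = np.divide(mc, tc, out=np.zeros_like(mc), where=tc > 0)
    p2 = np.divide(md, td, out=np.zeros_like(md), where=td > 0)
    pp = np.divide(mc + md, tc + td, out=np.zeros_like(mc), where=(tc + td) > 0)
    var = pp * (1.0 - pp) * (1.0 / np.maximum(tc, 1) + 1.0 / np.maximum(td, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (p2 - p1) / np.sqrt(var), 0.0)
    return 2.0 * stats.norm.sf(np.abs(z))


def _refine_boundaries(p, mc, tc, md, td, start, end, step, window):
    """Trim a merged candidate region to the bins that carry its signal.

    A significant window only localises signal to somewhere within it, so
    the union of overlapping windows overhangs the true region and dilutes
    its recomputed delta. Leading/trailing ``step``-bp elementary bins whose
    level difference is below half the region's peak bin difference (or that
    lack coverage) are eroded from both ends.
    """
    edges = np.arange(start, end + step, step)
    nb = len(edges) - 1
    if nb <= 1:
        return start, end
    m = (p > start) & (p <= end)
    if not m.any():
        return start, end
    idx = np.minimum((p[m] - 1 - start) // step, nb - 1)
    bmc = np.bincount(idx, weights=mc[m], minlength=nb)
    btc = np.bincount(idx, weights=tc[m], minlength=nb)
    bmd = np.bincount(idx, weights=md[m], minlength=nb)
    btd = np.bincount(idx, weights=td[m], minlength=nb)
    covered = (btc > 0) & (btd > 0)
    if not covered.any():
        return start, end
    bdelta = np.zeros(nb)
    bdelta[covered] = bmd[covered] / np.maximum(btd[covered], 1) - bmc[covered] / np.maximum(
        btc[covered], 1
    )
    peak = np.abs(bdelta[covered]).max()
    if peak == 0:
        return start, end
    keep = covered & (np.abs(bdelta) >= 0.5 * peak)
    lo, hi = np.flatnonzero(keep)[[0, -1]]
    new_start, new_end = int(edges[lo]), int(min(edges[hi + 1], end))
    # never trim below one window: that is the caller's localisation limit,
    # and recomputing a delta over peak bins alone would inflate it
    if new_end - new_start < window:
        pad = window - (new_end - new_start)
        new_start = max(start, new_start - pad // 2)
        new_end = min(end, new_start + window)
        new_start = max(start, new_end - window)
    return new_start, new_end


def call_candidate_dmrs(
    control: pd.DataFrame,
    drought: pd.DataFrame,
    window: int = 200,
    step: int = 50,
    min_cytosines: int = 4,
    alpha: float = 0.05,
    contexts=CONTEXTS,
    genotype_id: str = "",
    group: str = "",
    return_window_stats: bool = False,
):
    """Call candidate DMRs for one genotype from per-cytosine count frames.

    Counts are pooled within sliding windows (``window`` bp, ``step`` bp
    step); windows with at least ``min_cytosines`` covered in-context
    cytosines in *both* conditions are tested with a two-proportion test.
    Overlapping or adjacent significant windows with the same delta sign are
    unioned, and each merged region's levels and delta are recomputed from
    its site counts (its p-value is the smallest member-window p).

    With ``return_window_stats=True`` also returns a per-tested-window frame
    (chrom, context, start, delta, p_value) for calibration checks.
    """
    if window < step:
        raise ValueError("window must be >= step")
    win_rows = []
    if len(control) == 0 or len(drought) == 0:
        empty = pd.DataFrame(columns=DMR_COLUMNS)
        if return_window_stats:
            return empty, pd.DataFrame(columns=["chrom", "context", "start", "delta", "p_value"])
        return empty

    same_grid = len(control) == len(drought) and np.array_equal(
        control["pos"].to_numpy(), drought["pos"].to_numpy()
    ) and np.array_equal(control["chrom"].to_numpy(), drought["chrom"].to_numpy())
    if same_grid:
        merged = pd.DataFrame(
            {
                "chrom": control["chrom"].to_numpy(),
                "pos": control["pos"].to_numpy(),
                "context": control["context"].to_numpy(),
                "mc": control["n_meth"].to_numpy(),
                "tc": control["n_total"].to_numpy(),
                "md": drought["n_meth"].to_numpy(),
                "td": drought["n_total"].to_numpy(),
            }
        )
    else:
        a = control[["chrom", "pos", "context", "n_meth", "n_total"]].rename(
            columns={"n_meth": "mc", "n_total": "tc"}
        )
        b = drought[["chrom", "pos", "context", "n_meth", "n_total"]].rename(
            columns={"n_meth": "md", "n_total": "td"}
        )
        merged = a.merge(b, on=["chrom", "pos", "context"], how="outer").fillna(0)

    w = window // step  # elementary step-bins per window
    out_rows = []
    for (chrom, ctx), sub in merged.groupby(["chrom", "context"], observed=True):
        if ctx not in contexts:
            continue
        p = sub["pos"].to_numpy()
        mc = sub["mc"].to_numpy(dtype=np.int64)
        tc = sub["tc"].to_numpy(dtype=np.int64)
        md = sub["md"].to_numpy(dtype=np.int64)
        td = sub["td"].to_numpy(dtype=np.int64)
        bin_idx = (p - 1) // step
        nbins = int(bin_idx.max()) + 1 if len(bin_idx) else 0
        if nbins == 0:
            continue

        def wsum(x):
            per_bin = np.bincount(bin_idx, weights=x, minlength=nbins)
            c = np.concatenate([[0.0], np.cumsum(per_bin)])
            n_windows = max(nbins - w + 1, 1)
            return c[np.minimum(np.arange(n_windows) + w, nbins)] - c[:n_windows]

        W_mc, W_tc, W_md, W_td = wsum(mc), wsum(tc), wsum(md), wsum(td)
        W_nc = wsum((tc > 0).astype(np.int64))
        W_nd = wsum((td > 0).astype(np.int64))
        usable = (W_nc >= min_cytosines) & (W_nd >= min_cytosines) & (W_tc > 0) & (W_td > 0)
        if not usable.any():
            continue
        pvals = np.ones(len(W_mc))
        pvals[usable] = _two_proportion_p(
            W_mc[usable], W_tc[usable], W_md[usable], W_td[usable]
        )
        delta_w = np.zeros(len(W_mc))
        nz = (W_tc > 0) & (W_td > 0)
        delta_w[nz] = W_md[nz] / W_td[nz] - W_mc[nz] / W_tc[nz]
        if return_window_stats:
            for i in np.flatnonzero(usable):
                win_rows.append((chrom, ctx, int(i * step), delta_w[i], pvals[i]))
        sig = usable & (pvals < alpha) & (delta_w != 0)
        if not sig.any():
            continue

        # union overlapping/adjacent significant windows of the same sign
        idxs = np.flatnonzero(sig)
        starts = idxs * step
        ends = starts + window
        signs = np.sign(delta_w[idxs])
        run_start, run_end, run_sign, run_p = starts[0], ends[0], signs[0], pvals[idxs[0]]
        regions = []
        for s, e, sg, pv in zip(starts[1:], ends[1:], signs[1:], pvals[idxs[1:]]):
            if s <= run_end and sg == run_sign:
                run_end = max(run_end, e)
                run_p = min(run_p, pv)
            else:
                regions.append((run_start, run_end, run_p))
                run_start, run_end, run_sign, run_p = s, e, sg, pv
        regions.append((run_start, run_end, run_p))

        for s, e, pv in regions:
            s, e = _refine_boundaries(p, mc, tc, md, td, int(s), int(e), step, window)
            m = (p > s) & (p <= e)
            tci, tdi = tc[m].sum(), td[m].sum()
            if tci == 0 or tdi == 0:
                continue
            lvl_c = mc[m].sum() / tci
            lvl_d = md[m].sum() / tdi
            out_rows.append(
                (chrom, int(s), int(e), ctx, lvl_c, lvl_d, lvl_d - lvl_c, pv,
                 genotype_id, group)
            )
    out = pd.DataFrame(out_rows, columns=DMR_COLUMNS)
    if return_window_stats:
        stats_df = pd.DataFrame(
            win_rows, columns=["chrom", "context", "start", "delta", "p_value"]
        )
        return out, stats_df
    return out


def filter_significant(dmrs: pd.DataFrame, thresholds=None) -> pd.DataFrame:
    """Keep DMRs whose |delta| strictly exceeds the context threshold."""
    if thresholds is None:
        thresholds = CONTEXT_DELTA_THRESHOLDS
    if len(dmrs) == 0:
        return dmrs.copy()
    unknown = set(dmrs["context"]) - set(thresholds)
    if unknown:
        raise ValueError(f"unknown context(s): {sorted(unknown)}")
    thr = dmrs["context"].map(thresholds).to_numpy(dtype=float)
    keep = dmrs["delta"].abs().to_numpy() > thr
    return dmrs[keep].reset_index(drop=True)


CONSERVED_COLUMNS = [
    "chrom", "start", "end", "context", "group", "direction", "n_support",
    "mean_delta", "genotype_ids",
]


def merge_conserved(dmrs: pd.DataFrame, max_gap: int = 100) -> pd.DataFrame:
    """Merge a phenotype group's per-genotype DMRs into conserved DMRs.

    Merging is per (context, chromosome); two regions merge iff the gap
    between them (``start2 - end1``) is <= ``max_gap`` (gap exactly 100
    merges). Each conserved DMR records the distinct supporting genotypes,
    its direction (hyper if every contributing delta > 0, hypo if every
    delta < 0, else mixed) and the mean of its per-genotype mean deltas.
    """
    if len(dmrs) == 0:
        return pd.DataFrame(columns=CONSERVED_COLUMNS)
    groups = set(dmrs["group"].astype(str))
    if len(groups) > 1:
        raise ValueError(f"merge_conserved expects a single phenotype group, got {sorted(groups)}")
    group = next(iter(groups))

    rows = []
    for (ctx, chrom), sub in dmrs.groupby(["context", "chrom"], observed=True):
        sub = sub.sort_values(["start", "end"], kind="mergesort")
        cur = None
        members = []

        def flush():
            mem = pd.DataFrame(members)
            per_geno = mem.groupby("genotype_id")["delta"].mean()
            deltas = mem["delta"].to_numpy()
            if (deltas > 0).all():
                direction = "hyper"
            elif (deltas < 0).all():
                direction = "hypo"
            else:
                direction = "mixed"
            rows.append(
                (chrom, cur[0], cur[1], ctx, group, direction, int(per_geno.size),
                 float(per_geno.mean()), ",".join(sorted(per_geno.index.astype(str))))
            )

        for r in sub.itertuples(index=False):
            if cur is None or r.start - cur[1] > max_gap:
                if cur is not None:
                    flush()
                cur = [int(r.start), int(r.end)]
                members = []
            else:
                cur[1] = max(cur[1], int(r.end))
            members.append({"genotype_id": r.genotype_id, "delta": r.delta})
        if cur is not None:
            flush()
    out = pd.DataFrame(rows, columns=CONSERVED_COLUMNS)
    return out.sort_values(["context", "chrom", "start"], kind="mergesort").reset_index(drop=True)


def support_filter(conserved: pd.DataFrame, min_genotypes: int = 3) -> pd.DataFrame:
    """Keep conserved DMRs identified in at least ``min_genotypes`` genotypes."""
    if len(conserved) == 0:
        return conserved.copy()
    return conserved[conserved["n_support"] >= min_genotypes].reset_index(drop=True)


def annotate_feature(conserved: pd.DataFrame, genes: pd.DataFrame, flank: int = 2000) -> pd.Series:
    """Label each DMR as gene_body / upstream2k / downstream2k / intergenic.

    Flanks are strand-aware; on overlap with several genes the
    highest-precedence label wins (gene_body > upstream2k > downstream2k).
    """
    labels = []
    genes_by_chrom = {c: g for c, g in genes.groupby("chrom", observed=True)}
    for r in conserved.itertuples(index=False):
        g = genes_by_chrom.get(r.chrom)
        label = "intergenic"
        if g is not None:
            gs = g["start"].to_numpy()
            ge = g["end"].to_numpy()
            plus = (g["strand"] == "+").to_numpy()
            body = (r.start < ge) & (r.end > gs)
            up_s = np.where(plus, gs - flank, ge)
            up_e = np.where(plus, gs, ge + flank)
            down_s = np.where(plus, ge, gs - flank)
            down_e = np.where(plus, ge + flank, gs)
            up = (r.start < up_e) & (r.end > up_s)
            down = (r.start < down_e) & (r.end > down_s)
            if body.any():
                label = "gene_body"
            elif up.any():
                label = "upstream2k"
            elif down.any():
                label = "downstream2k"
        labels.append(label)
    return pd.Series(labels, index=conserved.index, name="feature")


def dmr_count_table(counts: pd.DataFrame) -> dict:
    """Summary statistics from per-(group, context) DMR counts at three tiers.

    ``counts`` is indexed by (group, context) with tier columns, e.g.
    ``conserved``, ``significant``, ``associated_genes``. Returns, per tier:
    the CHH share of each group's DMRs (percent, 1 dp) and the percentage
    excess of the sensitive over the tolerant total (2 dp).
    """
    tiers = list(counts.columns)
    chh_fraction: dict[str, dict[str, float]] = {}
    excess: dict[str, float] = {}
    totals: dict[str, dict[str, float]] = {}
    for tier in tiers:
        chh_fraction[tier] = {}
        totals[tier] = {}
        for grp in counts.index.get_level_values(0).unique():
            sub = counts.loc[grp, tier]
            total = float(sub.sum())
            totals[tier][grp] = total
            chh = float(sub.get("CHH", 0))
            chh_fraction[tier][grp] = round(100.0 * chh / total, 1) if total else float("nan")
        if {"tolerant", "sensitive"} <= set(totals[tier]):
            t = totals[tier]["tolerant"]
            if t == 0:
                raise ValueError(f"zero tolerant total in tier {tier!r}: excess undefined")
            excess[tier] = round(100.0 * (totals[tier]["sensitive"] / t - 1.0), 2)
    return {"chh_fraction": chh_fraction, "excess_pct": excess, "totals": totals}


def chromosome_density(conserved: pd.DataFrame, chrom_lengths: dict) -> pd.DataFrame:
    """DMRs per megabase per chromosome, with subgenome attribution."""
    for length in chrom_lengths.values():
        if length <= 0:
            raise ValueError("chromosome lengths must be positive")
    per_chrom = conserved.groupby("chrom", observed=True).size()
    missing = set(per_chrom.index) - set(chrom_lengths)
    if missing:
        raise ValueError(f"missing length for chromosome(s): {sorted(missing)}")
    rows = []
    for chrom, length in chrom_lengths.items():
        n = int(per_chrom.get(chrom, 0))
        rows.append((chrom, subgenome_of(chrom), n, n / (length / 1e6)))
    return pd.DataFrame(rows, columns=["chrom", "subgenome", "n_dmrs", "density_per_mb"])
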