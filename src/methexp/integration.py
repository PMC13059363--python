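"""Methylome-transcriptome integration: DMR-gene association, the
"methylation-expression" negative-regulation screen, priority scoring,
genotype-specificity partition, hub-gene extraction and the genome-wide
methylation/expression scan.

The screen keeps genes that carry a conserved DMR in their body or 2-kb
flank, are DEGs, change methylation by more than 0.05 (fraction scale,
strict) and change methylation and expression in *opposite* directions.
Candidates are ranked by the weighted priority score

    priority = |log2FC| * 1 + |Δmeth| * 5 + phenotype_coverage * 10
               + data_completeness * 5 + log(DMR count) * 2

with phenotype_coverage the number of phenotype groups (1 or 2) in which the
gene passes the screen, data_completeness the fraction of the group's
samples with usable measurements for the gene, and a natural log on the DMR
count (the base is configurable).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "associate_dmrs_to_genes",
    "gene_delta_meth",
    "negative_regulation_screen",
    "correlation_summary",
    "priority_score",
    "rank_candidates",
    "venn_partition",
    "hub_genes",
    "genomewide_meth_expr_scan",
]

_PLACEMENT_PRECEDENCE = ("gene_body", "upstream2k", "downstream2k")


def associate_dmrs_to_genes(
    conserved: pd.DataFrame, genes: pd.DataFrame, flank: int = 2000
) -> pd.DataFrame:
    """Link conserved DMRs to genes they overlap (body or strand-aware 2-kb flank).

    One link per (gene, DMR) pair with >= 1 bp overlap; a DMR spanning both
    a flank and the body takes the higher-precedence ``gene_body`` placement.
    Intergenic DMRs yield no links. Returns
    ``gene_id, dmr_index, placement, context, delta, start, end, chrom``
    where ``dmr_index`` is the row label in ``conserved``.
    """
    rows = []
    genes_by_chrom = {c: g for c, g in genes.groupby("chrom", observed=True)}
    delta_col = "mean_delta" if "mean_delta" in conserved.columns else "delta"
    for idx, r in conserved.iterrows():
        g = genes_by_chrom.get(r["chrom"])
        if g is None:
            continue
        for grow in g.itertuples(index=False):
            if grow.strand == "+":
                up = (grow.start - flank, grow.start)
                down = (grow.end, grow.end + flank)
            else:
                up = (grow.end, grow.end + flank)
                down = (grow.start - flank, grow.start)
            placement = None
            if r["start"] < grow.end and r["end"] > grow.start:
                placement = "gene_body"
            elif r["start"] < up[1] and r["end"] > up[0]:
                placement = "upstream2k"
            elif r["start"] < down[1] and r["end"] > down[0]:
                placement = "downstream2k"
            if placement is not None:
                rows.append(
                    (grow.gene_id, idx, placement, r["context"], float(r[delta_col]),
                     int(r["start"]), int(r["end"]), r["chrom"])
                )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "dmr_index", "placement", "context", "delta", "start", "end", "chrom"],
    )


def gene_delta_meth(links: pd.DataFrame, mode: str = "length_weighted") -> pd.Series:
    """Aggregate each gene's linked DMR deltas into one Δmethylation value.

    Default: per context, the length-weighted mean of linked DMR deltas,
    then the plain mean across contexts present. ``mode="strongest"``
    instead takes the single linked delta of largest magnitude. Genes with a
    single linked DMR return that DMR's delta exactly under either mode.
    """
    if len(links) == 0:
        return pd.Series(dtype=float, name="delta_meth")
    if mode == "strongest":
        def agg(sub):
            return float(sub.loc[sub["delta"].abs().idxmax(), "delta"])
    elif mode == "length_weighted":
        def agg(sub):
            per_ctx = []
            for _, csub in sub.groupby("context", observed=True):
                w = (csub["end"] - csub["start"]).to_numpy(dtype=float)
                per_ctx.append(float(np.average(csub["delta"], weights=w)))
            return float(np.mean(per_ctx))
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    out = links.groupby("gene_id").apply(agg, include_groups=False)
    out.name = "delta_meth"
    return out


def negative_regulation_screen(
    gene_deltas: pd.Series,
    degs: pd.DataFrame,
    min_delta: float = 0.05,
    n_dmrs: pd.Series | None = None,
) -> pd.DataFrame:
    """Screen for the negative-regulation pattern within one phenotype group.

    Keeps genes present in both tables with ``|delta_meth| > min_delta``
    (strict) and opposite-sign methylation and expression changes.
    Returns ``gene_id, delta_meth, log2fc, n_dmrs``.
    """
    deg_lookup = degs.set_index("gene_id")["log2fc"]
    rows = []
    for gid, dm in gene_deltas.items():
        if gid not in deg_lookup.index:
            continue
        lfc = float(deg_lookup[gid])
        if abs(dm) > min_delta and lfc != 0 and np.sign(dm) != np.sign(lfc):
            nd = int(n_dmrs[gid]) if n_dmrs is not None and gid in n_dmrs.index else 1
            rows.append((gid, float(dm), lfc, nd))
    return pd.DataFrame(rows, columns=["gene_id", "delta_meth", "log2fc", "n_dmrs"])


def correlation_summary(candidates: pd.DataFrame) -> dict:
    """Pearson r between Δmethylation and log2FC over a group's candidates.

    Returns ``{"pearson_r": r, "n": n}``; with fewer than 3 pairs or a
    degenerate (constant) axis, ``pearson_r`` is ``nan`` rather than an error.
    """
    n = len(candidates)
    if n < 3:
        return {"pearson_r": float("nan"), "n": n}
    x = candidates["delta_meth"].to_numpy(dtype=float)
    y = candidates["log2fc"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"pearson_r": float("nan"), "n": n}
    r, _ = stats.pearsonr(x, y)
    return {"pearson_r": float(r), "n": n}


def priority_score(
    expr_mag: float,
    meth_mag: float,
    phenotype_coverage: int,
    data_completeness: float,
    dmr_count: int,
    log_base: float = math.e,
) -> float:
    """Weighted priority score of a candidate gene.

    ``expr_mag * 1 + meth_mag * 5 + phenotype_coverage * 10 +
    data_completeness * 5 + log(dmr_count) * 2``, natural log by default.
    """
    if dmr_count < 1:
        raise ValueError("dmr_count must be >= 1")
    if expr_mag < 0 or meth_mag < 0 or data_completeness < 0:
        raise ValueError("score components must be non-negative")
    return (
        expr_mag * 1.0
        + meth_mag * 5.0
        + phenotype_coverage * 10.0
        + data_completeness * 5.0
        + math.log(dmr_count, log_base) * 2.0
    )


def rank_candidates(candidates: pd.DataFrame, top_k: int = 15) -> pd.DataFrame:
    """Order candidates by descending priority score, ties broken by gene id."""
    ordered = candidates.sort_values(
        ["priority_score", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    return ordered.head(top_k).reset_index(drop=True)


def venn_partition(sensitive_candidates, tolerant_candidates) -> dict:
    """Exclusive two-set partition of candidate genes by phenotype group."""
    def ids(x):
        if isinstance(x, pd.DataFrame):
            return set(x["gene_id"])
        return set(x)

    s, t = ids(sensitive_candidates), ids(tolerant_candidates)
    out = {
        "sensitive_specific": len(s - t),
        "tolerant_specific": len(t - s),
        "common": len(s & t),
    }
    out["total"] = out["sensitive_specific"] + out["tolerant_specific"] + out["common"]
    return out


def hub_genes(candidates: pd.DataFrame, core_pathway_genes: dict) -> pd.DataFrame:
    """Intersect candidates with the genes of the core pathways.

    ``core_pathway_genes`` maps core pathway/term id -> iterable of gene ids.
    Returns one row per hub gene with the core pathways it belongs to; empty
    (with all columns) when the core set is empty.
    """
    gene_to_terms: dict[str, list] = {}
    for term, members in core_pathway_genes.items():
        for gid in members:
            gene_to_terms.setdefault(gid, []).append(term)
    rows = []
    for r in candidates.itertuples(index=False):
        terms = gene_to_terms.get(r.gene_id)
        if terms:
            rows.append((r.gene_id, ",".join(sorted(map(str, terms)))))
    out = pd.DataFrame(rows, columns=["gene_id", "core_pathways"])
    if len(out):
        out = out.merge(candidates, on="gene_id", how="left")
    return out


def genomewide_meth_expr_scan(
    gene_deltas: pd.Series,
    de_table: pd.DataFrame,
    min_delta: float = 0.05,
    padj_max: float = 0.05,
) -> dict:
    """Classify every gene with both measurements and fit the pooled line.

    Labels: ``negative`` (opposite signs, |Δmeth| > min_delta and
    p_adj < padj_max), ``positive`` (same signs, both thresholds), ``other``.
    Also reports the R² of the ordinary least-squares fit of log2FC on
    Δmethylation over all measured genes.
    """
    de = de_table.set_index("gene_id")
    shared = [g for g in gene_deltas.index if g in de.index]
    labels = {}
    xs, ys = [], []
    for gid in shared:
        dm = float(gene_deltas[gid])
        lfc = float(de.loc[gid, "log2fc"])
        padj = float(de.loc[gid, "p_adj"])
        xs.append(dm)
        ys.append(lfc)
        passing = abs(dm) > min_delta and padj < padj_max and lfc != 0
        if passing and np.sign(dm) != np.sign(lfc):
            labels[gid] = "negative"
        elif passing and np.sign(dm) == np.sign(lfc):
            labels[gid] = "positive"
        else:
            labels[gid] = "other"
    if len(xs) >= 3 and np.std(xs) > 0 and np.std(ys) > 0:
        r = float(np.corrcoef(xs, ys)[0, 1])
        r2 = r * r
    else:
        r2 = float("nan")
    counts = pd.Series(labels).value_counts().to_dict() if labels else {}
    return {
        "labels": labels,
        "counts": {k: int(counts.get(k, 0)) for k in ("negative", "positive", "other")},
        "r_squared": r2,
        "n": len(shared),
    }
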