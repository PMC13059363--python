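"""End-to-end orchestration over a (simulated or loaded) study, plus
recovery scoring against a truth manifest.

The stage order mirrors the analysis the package implements:

1. per-genotype DMR calling (control vs drought, replicate-pooled counts);
2. context-threshold significance filter, then conserved merging per
   phenotype group and the >= 3-genotype support filter;
3. stand-in differential expression per group and DEG thresholds;
4. DMR-gene association, Δmethylation aggregation and the
   negative-regulation screen with priority scoring.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import dmr as dmod
from . import expression as emod
from . import integration as imod
from .simulate import SimulatedStudy

__all__ = [
    "group_conserved_dmrs",
    "run_group_pipeline",
    "run_integration",
    "evaluate_dmr_recovery",
    "evaluate_negreg_recovery",
]


def group_conserved_dmrs(
    study: SimulatedStudy,
    group: str,
    window: int = 200,
    step: int = 50,
    min_cytosines: int = 4,
    alpha: float = 0.05,
    min_genotypes: int = 3,
    thresholds=None,
    contexts=("CG", "CHG", "CHH"),
):
    """Call, filter and merge DMRs for one phenotype group.

    Returns ``(per_genotype_significant, conserved, supported)``.
    """
    genotypes = sorted(
        study.wgbs_samples.loc[study.wgbs_samples["group"] == group, "genotype_id"].unique()
    )
    per_geno = []
    for g in genotypes:
        cand = dmod.call_candidate_dmrs(
            study.pooled_cx(g, "control"),
            study.pooled_cx(g, "drought"),
            window=window,
            step=step,
            min_cytosines=min_cytosines,
            alpha=alpha,
            contexts=contexts,
            genotype_id=g,
            group=group,
        )
        per_geno.append(dmod.filter_significant(cand, thresholds=thresholds))
    significant = (
        pd.concat(per_geno, ignore_index=True)
        if per_geno
        else pd.DataFrame(columns=dmod.DMR_COLUMNS)
    )
    conserved = dmod.merge_conserved(significant) if len(significant) else pd.DataFrame(
        columns=dmod.CONSERVED_COLUMNS
    )
    supported = dmod.support_filter(conserved, min_genotypes=min_genotypes)
    return significant, conserved, supported


def run_group_pipeline(study: SimulatedStudy, group: str, **dmr_kwargs) -> dict:
    """DMR and DEG stages for one phenotype group."""
    significant, conserved, supported = group_conserved_dmrs(study, group, **dmr_kwargs)
    filtered_counts = emod.filter_low_counts(study.counts)
    de = emod.standin_de_test(filtered_counts, study.samples, group)
    degs = emod.filter_degs(de)
    return {
        "significant_dmrs": significant,
        "conserved_dmrs": conserved,
        "supported_dmrs": supported,
        "de_table": de,
        "degs": degs,
    }


def run_integration(study: SimulatedStudy, group_results: dict, flank: int = 2000) -> dict:
    """Negative-regulation screen and priority scoring for both groups.

    ``group_results`` maps group name -> output of :func:`run_group_pipeline`.
    Returns per-group candidate frames (with priority scores) plus the
    genotype-specificity partition and per-group correlation summaries.
    """
    candidates = {}
    correlations = {}
    for group, res in group_results.items():
        links = imod.associate_dmrs_to_genes(res["supported_dmrs"], study.genes, flank=flank)
        if len(links):
            deltas = imod.gene_delta_meth(links)
            n_dmrs = links.groupby("gene_id")["dmr_index"].nunique()
        else:
            deltas = pd.Series(dtype=float, name="delta_meth")
            n_dmrs = pd.Series(dtype=int)
        cand = imod.negative_regulation_screen(deltas, res["degs"], n_dmrs=n_dmrs)
        candidates[group] = cand
        correlations[group] = imod.correlation_summary(cand)

    groups_of = {}
    for group, cand in candidates.items():
        for gid in cand["gene_id"]:
            groups_of.setdefault(gid, set()).add(group)

    completeness = _data_completeness(study)
    scored = {}
    for group, cand in candidates.items():
        if len(cand) == 0:
            cand = cand.assign(priority_score=pd.Series(dtype=float))
        else:
            cand = cand.copy()
            cand["phenotype_coverage"] = [len(groups_of[g]) for g in cand["gene_id"]]
            cand["data_completeness"] = [
                completeness.get(g, {}).get(group, 1.0) for g in cand["gene_id"]
            ]
            cand["priority_score"] = [
                imod.priority_score(
                    abs(r.log2fc), abs(r.delta_meth), r.phenotype_coverage,
                    r.data_completeness, r.n_dmrs,
                )
                for r in cand.itertuples(index=False)
            ]
        scored[group] = cand

    venn = imod.venn_partition(
        scored.get("sensitive", pd.DataFrame(columns=["gene_id"])),
        scored.get("tolerant", pd.DataFrame(columns=["gene_id"])),
    )
    return {"candidates": scored, "venn": venn, "correlations": correlations}


def _data_completeness(study: SimulatedStudy) -> dict:
    """Fraction of a group's RNA samples with nonzero library for each gene.

    With the generator's deep, complete profiles this is almost always 1.0;
    it matters for sparse real data fed through the same interface.
    """
    out: dict[str, dict[str, float]] = {}
    counts = study.counts
    for group in ("tolerant", "sensitive"):
        ids = study.samples.loc[
            (study.samples["group"] == group)
            & study.samples["sample_id"].isin(counts.columns),
            "sample_id",
        ].to_list()
        if not ids:
            continue
        sub = counts[ids]
        frac = (sub.sum(axis=0) > 0).mean()
        for gid in counts.index:
            out.setdefault(gid, {})[group] = float(frac)
    return out


# ---------------------------------------------------------------------------
# recovery scoring against the truth manifest
# ---------------------------------------------------------------------------

def _overlaps_any(chrom, start, end, truth: pd.DataFrame) -> bool:
    sub = truth[truth["chrom"] == chrom]
    return bool(((sub["start"] < end) & (sub["end"] > start)).any())


def evaluate_dmr_recovery(
    supported: pd.DataFrame, truth_dmrs: pd.DataFrame, group: str, context: str | None = None
) -> dict:
    """Sensitivity and false-discovery proportion of called conserved DMRs.

    A planted region is recovered when a called DMR of the same group (and
    context, if given) overlaps it by >= 1 bp; a called DMR overlapping no
    planted region of its group counts as a false discovery.
    """
    truth = truth_dmrs[truth_dmrs["group"] == group]
    calls = supported[supported["group"] == group]
    if context is not None:
        truth = truth[truth["context"] == context]
        calls = calls[calls["context"] == context]
    n_truth = len(truth)
    recovered = sum(
        1 for t in truth.itertuples(index=False)
        if _overlaps_any(t.chrom, t.start, t.end, calls)
    )
    false_calls = sum(
        1 for c in calls.itertuples(index=False)
        if not _overlaps_any(c.chrom, c.start, c.end, truth)
    )
    n_calls = len(calls)
    return {
        "n_truth": n_truth,
        "n_calls": n_calls,
        "recovered": recovered,
        "sensitivity": recovered / n_truth if n_truth else float("nan"),
        "false_discoveries": false_calls,
        "fdr": false_calls / n_calls if n_calls else 0.0,
    }


def evaluate_negreg_recovery(candidates: dict, truth_negreg: pd.DataFrame) -> dict:
    """Fraction of planted negative-regulation genes present among candidates."""
    n_truth = len(truth_negreg)
    recovered = 0
    for t in truth_negreg.itertuples(index=False):
        cand = candidates.get(t.group)
        if cand is not None and t.gene_id in set(cand["gene_id"]):
            recovered += 1
    return {
        "n_truth": n_truth,
        "recovered": recovered,
        "sensitivity": recovered / n_truth if n_truth else float("nan"),
    }
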