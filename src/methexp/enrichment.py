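"""Hypergeometric term enrichment with Benjamini-Hochberg correction, and
the four-set pathway intersection that extracts core pathways.

Significance threshold kept as the study default: enriched iff
``p_adj < 0.01`` (strict). The enrichment universe is a caller decision —
p-values depend on it — typically all genes surviving the expression
low-count filter (for DEG enrichment) or all genes with covered cytosines
in body/flank (for DMR-associated-gene enrichment).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "hypergeom_enrich",
    "PathwayIntersection",
    "pathway_intersections",
    "categorize_core_pathways",
]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(
    study_genes,
    universe_genes,
    term_map: pd.DataFrame,
    padj_max: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric (upper-tail) term enrichment of a study set.

    For a term with ``K`` genes in a universe of ``N``, and a study set of
    ``n`` genes hitting ``k`` of them, ``p = P[X >= k]`` for
    ``X ~ Hypergeom(N, K, n)``. P-values are BH-corrected across all tested
    terms; a term is significant iff ``p_adj < padj_max`` (strict).

    Raises if the study set is not a subset of the universe.
    """
    study = set(study_genes)
    universe = set(universe_genes)
    stray = study - universe
    if stray:
        raise ValueError(f"study genes outside universe: {sorted(stray)[:10]}")
    N, n = len(universe), len(study)
    tm = term_map[term_map["gene_id"].isin(universe)]
    rows = []
    for (term_id, term_name), sub in tm.groupby(["term_id", "term_name"], sort=True):
        members = set(sub["gene_id"])
        K = len(members)
        k = len(members & study)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term_id, term_name, k, K, n, N, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p_value"])
    if len(out):
        out["p_adj"] = bh_adjust(out["p_value"].to_numpy())
        out["significant"] = out["p_adj"] < padj_max
    else:
        out["p_adj"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out


_DATASETS = ("sensitive_dmr", "sensitive_deg", "tolerant_dmr", "tolerant_deg")


@dataclass
class PathwayIntersection:
    """Exclusive partition of four enriched-term sets.

    ``partitions`` maps each non-empty dataset combination (a tuple of
    dataset names) to the count of terms belonging to exactly those
    datasets; counts sum to the size of the union. ``core`` is the 4-way
    intersection — the pathways enriched at both the epigenetic and the
    transcriptional level in both phenotype groups.
    """

    sets: dict
    partitions: dict
    core: set

    @property
    def unique_counts(self) -> dict:
        return {name: self.partitions.get((name,), 0) for name in self.sets}


def pathway_intersections(sets: dict) -> PathwayIntersection:
    """Exclusive intersection counts of the four enriched-term sets.

    ``sets`` maps dataset name -> set of term ids; the conventional keys are
    ``sensitive_dmr, sensitive_deg, tolerant_dmr, tolerant_deg`` but any
    names work.
    """
    names = list(sets)
    sets = {k: set(v) for k, v in sets.items()}
    partitions: dict[tuple, int] = {}
    membership: dict[str, tuple] = {}
    for term in set().union(*sets.values()) if sets else set():
        combo = tuple(name for name in names if term in sets[name])
        membership[term] = combo
    for combo in (c for r in range(1, len(names) + 1) for c in combinations(names, r)):
        count = sum(1 for m in membership.values() if m == combo)
        if count:
            partitions[combo] = count
    core = set.intersection(*sets.values()) if sets else set()
    return PathwayIntersection(sets=sets, partitions=partitions, core=core)


def categorize_core_pathways(core_terms, category_map: dict) -> pd.Series:
    """Count core pathways per functional category.

    Every core term must map to exactly one category; the counts sum to the
    number of core pathways.
    """
    core = sorted(set(core_terms))
    missing = [t for t in core if t not in category_map]
    if missing:
        raise ValueError(f"unmapped core term(s): {missing[:10]}")
    counts: dict[str, int] = {}
    for t in core:
        counts[category_map[t]] = counts.get(category_map[t], 0) + 1
    return pd.Series(counts, name="pathway_count").sort_index()
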