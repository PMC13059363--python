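"""Hypergeometric pathway enrichment and the four-set core intersection.

Enrichment replaces a web GO tool with an explicit hypergeometric upper-tail
test against a user term map (p_adj < 0.01, BH-corrected); the four
enriched-term sets (DMR-associated genes and DEGs, per phenotype group) are
partitioned UpSet-style and their 4-way intersection is the core module.
"""

from methexp import enrichment as en
from methexp import integration as im
from methexp import pipeline
from methexp.simulate import SimulationConfig, simulate_study

study = simulate_study(SimulationConfig(seed=5))
universe = list(study.counts.index)

sets = {}
for grp in ("sensitive", "tolerant"):
    res = pipeline.run_group_pipeline(study, grp)
    links = im.associate_dmrs_to_genes(res["supported_dmrs"], study.genes)
    dmr_genes = [g for g in set(links["gene_id"]) if g in universe]
    deg_genes = [g for g in res["degs"]["gene_id"] if g in universe]
    for kind, genes in (("dmr", dmr_genes), ("deg", deg_genes)):
        table = en.hypergeom_enrich(genes, universe, study.term_map)
        sig = set(table.loc[table["significant"], "term_id"])
        sets[f"{grp}_{kind}"] = sig
        top = table.sort_values("p_value").iloc[0]
        print(f"{grp}_{kind}: {len(genes):3d} study genes, {len(sig)} enriched terms; "
              f"top term {top.term_id} (k={top.k}/K={top.K}, p_adj={top.p_adj:.2e})")

inter = en.pathway_intersections(sets)
print(f"\nexclusive partitions (UpSet counts): "
      f"{ {'&'.join(k): v for k, v in inter.partitions.items()} }")
print(f"core (enriched in all four datasets): {sorted(inter.core) or 'none at this scale'}")
print("the generator concentrates planted negative-regulation genes in the "
      "T_STRESS pathway, which dominates the DMR-side enrichment")
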