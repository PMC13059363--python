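"""Desk-scale bookkeeping from the study's published summary tables.

The per-(group, context) DMR counts, DEG totals, candidate Venn partition
and core-pathway categories are inputs here; the package recomputes every
derived statistic the study reports from them.
"""

import pandas as pd

from methexp import dmr as dmod
from methexp import enrichment as en
from methexp import expression as emod
from methexp import integration as im

table2 = pd.DataFrame(
    {
        "conserved": [1651, 1100, 5914, 1850, 1099, 6567],
        "significant": [1362, 918, 4894, 1515, 911, 5552],
        "associated_genes": [1311, 867, 4531, 1412, 849, 5078],
    },
    index=pd.MultiIndex.from_product(
        [["tolerant", "sensitive"], ["CG", "CHG", "CHH"]], names=["group", "context"]
    ),
)
out = dmod.dmr_count_table(table2)
print("CHH share of significant DMRs : "
      f"sensitive {out['chh_fraction']['significant']['sensitive']}%, "
      f"tolerant {out['chh_fraction']['significant']['tolerant']}%")
print("sensitive-over-tolerant excess: "
      f"conserved +{out['excess_pct']['conserved']}%, "
      f"significant +{out['excess_pct']['significant']}%, "
      f"associated genes +{out['excess_pct']['associated_genes']}%")

sens = [f"c{i}" for i in range(714)] + [f"s{i}" for i in range(5598)]
tol = [f"c{i}" for i in range(714)] + [f"t{i}" for i in range(447)]
algebra = emod.deg_set_algebra(sens, tol)
print(f"DEG totals {algebra['total_sensitive']} vs {algebra['total_tolerant']}: "
      f"fold {algebra['fold_ratio']}, specifics "
      f"{algebra['specific_sensitive']}/{algebra['specific_tolerant']}, "
      f"common {algebra['common']}")

venn = im.venn_partition(
    [f"s{i}" for i in range(89)] + ["both"], [f"t{i}" for i in range(16)] + ["both"]
)
print(f"candidate-gene Venn 89+16+1 -> total {venn['total']}")

layout = [("Phenylpropanoid Metabolism", 2), ("Jasmonic Acid Signaling", 2),
          ("Reactive Oxygen Species Metabolism", 1), ("Nitrogen Metabolism", 4),
          ("Lipid Metabolism", 4), ("Light Signal Perception", 2),
          ("Carbohydrate Transport", 1), ("Cytokinin Biosynthesis", 1),
          ("Terpenoid Metabolism", 2)]
category_map = {f"p{i}_{j}": cat for i, (cat, n) in enumerate(layout) for j in range(n)}
counts = en.categorize_core_pathways(list(category_map), category_map)
print(f"core pathways by category sum to {counts.sum()}")

print(f"priority score for components (2.0, 0.30, 1, 1.0, 1): "
      f"{im.priority_score(2.0, 0.30, 1, 1.0, 1)}")
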