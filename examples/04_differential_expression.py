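"""Low-count filtering, the stand-in DE test, DEG thresholds and set algebra.

DEGs pass p_adj < 0.05 and |log2FC| > 1 (both strict). The two-group set
algebra reports totals, common and group-specific DEGs, the fold ratio, and
up/down proportions.
"""

from methexp import expression as emod
from methexp import pipeline
from methexp.simulate import SimulationConfig, simulate_study

study = simulate_study(SimulationConfig(seed=4))
filtered = emod.filter_low_counts(study.counts)
print(f"{len(study.counts)} genes -> {len(filtered)} after dropping total counts < 10")

degs = {}
for grp in ("sensitive", "tolerant"):
    de = emod.standin_de_test(filtered, study.samples, grp)
    degs[grp] = emod.filter_degs(de)
    truth = study.truth.degs
    planted = set(truth.loc[truth["group"] == grp, "gene_id"])
    hit = len(planted & set(degs[grp]["gene_id"]))
    print(f"{grp:9s}: {len(degs[grp]):3d} DEGs, planted recovery {hit}/{len(planted)}")

algebra = emod.deg_set_algebra(degs["sensitive"], degs["tolerant"])
print(f"set algebra: common {algebra['common']}, "
      f"specific {algebra['specific_sensitive']}/{algebra['specific_tolerant']}, "
      f"fold ratio {algebra['fold_ratio']}")
print(f"up-regulated share: sensitive {algebra['up_pct_sensitive']}%, "
      f"tolerant {algebra['up_pct_tolerant']}%")
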