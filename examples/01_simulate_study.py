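"""Generate a complete synthetic drought study and write it to disk.

The study emulates a 6-tolerant + 6-sensitive genotype design under control
and drought, with per-cytosine CG/CHG/CHH methylation counts, an RNA count
matrix, a gene->pathway map, and a truth manifest recording every planted
DMR, DEG and negative-regulation gene.
"""

from methexp.simulate import SimulationConfig, simulate_study, water_content

cfg = SimulationConfig(seed=1)
study = simulate_study(cfg, outdir="scratch/example_study")

print(f"chromosomes      : {', '.join(cfg.chrom_names())} ({cfg.chrom_length:,} bp each)")
print(f"genes            : {len(study.genes)}")
print(f"cytosine sites   : {len(study.sites):,} "
      f"({dict(study.sites['context'].value_counts())})")
print(f"WGBS samples     : {len(study.wgbs_samples)}  RNA samples: {study.counts.shape[1]}")
print(f"planted DMRs     : {len(study.truth.dmrs)} "
      f"(incl. {len(study.truth.negreg)} promoter shifts of negative-regulation genes)")
print(f"planted DEGs     : {len(study.truth.degs)}")

# the drought-tolerance index used to pick the extreme genotypes:
# aboveground water content from fresh and dry weight
print(f"water content for fw=3.7 g, dw=1.11 g : {water_content(3.7, 1.11):.2f}")
print("files written under scratch/example_study/ "
      "(CX reports, GFF3, counts, sample sheet, term map, truth tables)")
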