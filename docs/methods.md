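# Methods

This note documents the models, parameter choices and numerical decisions
behind `methexp`, in the spirit of a statistical-software methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design assumed throughout

Two phenotype groups (drought **tolerant**, drought **sensitive**) of six
genotypes each, assayed under **control** and **drought**. WGBS yields
per-cytosine methylated/total read counts in the CG, CHG and CHH contexts;
RNA-seq yields a gene × sample count matrix. All interval arithmetic is
0-based half-open internally; 1-based coordinates appear only at the
CX-report and GFF3 boundaries, and A/C subgenome membership is derived from
chromosome names (`A##` / `C##`; anything else is `other`).

## Methylation levels and profiles

A region's methylation level is the **weighted level**
Σ n_meth / Σ n_total over its in-context cytosines — the standard for
count-based bisulfite data, as opposed to the mean of per-site ratios, which
over-weights low-coverage sites. Sites below a coverage floor
(`min_coverage`, default 4 reads; configurable — no universal cutoff exists
and 3–5 is common practice) are excluded from level computation but retained
by the parsers so that binning sees every position. An empty denominator
yields NaN, deliberately distinct from a level of 0.

Metagene profiles divide 2-kb upstream flank, gene body and 2-kb downstream
flank into 50 bins each (150 total). Minus-strand genes are
coordinate-reflected so bin 1 is always most-5′; genes shorter than 50 bp
are binned with fractional edges rather than rejected. A bin's value is the
per-gene weighted level averaged across the genes of an expression stratum,
skipping no-data bins. The six expression strata are: exactly-zero mean
expression → `none`; the remaining genes split into five equal-size quantile
groups with ties broken by gene id, which makes stratum membership invariant
under monotone transforms of expression.

## DMR calling (stand-in) and post-processing

Smoothing/shrinkage-based DMR testers are out of scope; the caller here is a
transparent stand-in, and precomputed DMR tables (with deltas and p-values)
can enter the chain at the significance filter instead.

Per genotype, replicate-pooled control and drought counts are summed in
sliding windows (200 bp window, 50 bp step). Windows with ≥ 4 covered
in-context cytosines in both conditions are tested with a **two-proportion
score (z) test** on the pooled counts; at the coverage this package targets
(hundreds of reads per window) it is indistinguishable from an exact test
and vectorises over all windows. Its per-window null rejection rate is
calibrated (tested ≤ 1.5 α). Overlapping/adjacent significant windows of the
same delta sign are unioned, and the union is **boundary-refined**: leading
and trailing 50-bp elementary bins whose level difference is below half the
region's peak bin difference (or that lack coverage) are eroded, but never
below one window's width. Refinement matters in both directions: without it,
edge windows overhanging a true region dilute the recomputed region delta
below the per-context thresholds; eroding below the caller's resolution
would instead recompute deltas over selected peak bins and inflate them. The
region's delta is then recomputed from its site counts, with
Δ = m_drought − m_control (hyper = drought-induced gain), and its p-value is
the smallest member-window p.

Post-processing applies, in order:

1. **Significance filter** — strict per-context thresholds, exactly as the
   study states them: |Δ| > 0.20 (CG), > 0.15 (CHG), > 0.25 (CHH). Applied
   to per-genotype regions *before* merging (filter→merge; the alternative
   order is configurable via the thresholds argument).
2. **Conserved merging** — per (context, chromosome) within one phenotype
   group, two regions merge iff the gap start₂ − end₁ ≤ 100 bp (gap exactly
   100 merges, matching common interval-merge semantics). Each conserved DMR
   records distinct supporting genotypes, direction (hyper if all
   contributing deltas > 0, hypo if all < 0, else mixed) and the mean of its
   per-genotype mean deltas.
3. **Support filter** — the final set keeps regions identified in ≥ 3
   genotypes of the group. This rule, not the window test, is what drives
   the pipeline's null behaviour: single-genotype window noise (chiefly
   sparse-site CHG windows near the 4-cytosine floor) survives tiers 1–2 at
   a low rate but essentially never co-locates across three genotypes.

Feature annotation labels each DMR `gene_body`, `upstream2k`, `downstream2k`
or `intergenic` with strand-aware flanks and precedence
body > upstream > downstream when a region overlaps several genes.

## Differential expression (stand-in)

The negative-binomial GLM machinery of dedicated DE packages is out of
scope; the stand-in uses median-of-ratios size factors (computed over genes
expressed in every sample), log₂ fold change from pseudocounted normalised
means (pseudocount 0.5), Welch's t on log₂(normalised + 0.5) counts, and BH
adjustment. Precomputed DE tables slot into the DEG filter directly. The
group contrast pools all control vs all drought samples of the group's six
genotypes (18 vs 18 at the default three replicates); a per-genotype paired
contrast at n = 6 pairs is too poorly calibrated to respect the strict
p_adj < 0.05 & |log₂FC| > 1 thresholds under the null and is not offered.

## Enrichment and core pathways

Term enrichment is the hypergeometric upper tail P[X ≥ k] for a term with K
genes in a universe of N and a study set of n hitting k, BH-corrected across
tested terms, significant at p_adj < 0.01 (strict). The universe is a caller
decision because p-values depend on it; the intended choices are all genes
surviving the low-count filter (DEG side) and all genes with covered
cytosines in body/flank (DMR side). The four significant-term sets are
partitioned into exclusive subset combinations; the 4-way intersection is
the core module, and candidates inside core pathways are hub genes.

## The negative-regulation screen and priority score

Conserved DMRs of the final set are linked to genes on ≥ 1 bp overlap of
body or strand-aware 2-kb flank (one link per gene–DMR pair; a DMR may link
several genes and vice versa). A gene's ΔMeth aggregates its linked deltas:
per context a length-weighted mean, then averaged across contexts present
(a "strongest DMR" mode is offered; single-DMR genes return that delta
exactly under either). The screen keeps genes that are DEGs, have
|ΔMeth| > 0.05 (strict) and opposite-sign ΔMeth and log₂FC. Per group, the
Pearson r between ΔMeth and log₂FC over candidates is reported with its n
(NaN below 3 pairs or for a degenerate axis).

The priority score is the weighted sum
|log₂FC|·1 + |ΔMeth|·5 + phenotype_coverage·10 + data_completeness·5 +
log(DMR count)·2 with a **natural** logarithm by default (the base is
configurable). Operational definitions the formula leaves open were fixed
as: phenotype coverage = number of groups (1 or 2) in which the gene passes
the screen; data completeness = fraction of the group's RNA samples with a
nonzero library for the gene (≈ 1 on complete simulated data; it matters for
sparse real inputs); DMR count = distinct linked conserved DMRs. Ranking is
descending by score with lexicographic gene-id tie-break, top 15 by default.

## The synthetic-study generator

The generator is the package's ground-truth instrument, not a fixture dump.
Defaults are the study conditions: per-context baselines CG 0.92308,
CHG 0.46756, CHH 0.32164 (control-condition global levels), 6 genotypes per
group, mean coverage 30 reads/cytosine, three RNA replicates per
genotype × treatment (the design's biological replication) and one WGBS
profile per genotype × treatment (region-level tests pool counts, so extra
WGBS replicates add little beyond coverage; the count is configurable).

Methylation is hierarchical: per-genotype, per-context baselines drawn
Beta(mean = global baseline, concentration 400), per-site propensities drawn
Beta(mean = genotype baseline, concentration 8), **shared between the
genotype's control and drought samples** so that within-genotype differences
outside planted regions are pure binomial sampling noise — the null the
caller is calibrated against. Between-genotype jitter (sd ≈ 0.02–0.03) keeps
control-vs-control contrasts below the context thresholds. Site positions
follow a Poisson process (mean spacing 8 bp CHH, 15 bp CG/CHG); coverage is
Poisson per site and sample.

Planted effects shift propensities proportionally so the realised Δ is
unbiased by the unit interval: hyper p′ = p + Δ(1−p)/(1−baseline), hypo
p′ = p(1 + Δ/baseline). Plain DMRs occupy reserved intergenic margins so
they never touch gene flanks; negative-regulation genes receive a 400-bp
shift centred in the promoter-side (strand-aware upstream) 2-kb flank plus
an opposite-sign expression effect. Counts are gamma–Poisson (dispersion
0.05) with per-sample library factors in [0.7, 1.3], lognormal gene means
(median 150, σ = 1) and ~8 % silent genes to populate the `none` expression
stratum. Gene-body methylation factors (default 1.0) allow depressing
body CG to reproduce the classic U-shaped metagene profile on demand. The
gene→term map assigns 1–3 random terms per gene plus one shared stress
pathway containing every planted negative-regulation gene, giving
enrichment walkthroughs a signal with known membership. A fixed seed yields
byte-identical output trees.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level artefacts (bisulfite conversion error,
mapping bias), linkage between neighbouring sites beyond the shared
propensity, genotype-specific expression heterogeneity beyond NB dispersion,
transposable-element structure, and any mechanistic coupling between
methylation and expression other than the planted opposite-sign shifts.

## Problem sizes used by tests and the acceptance script

Simulated studies in the test suite and acceptance script use 2 A + 2 C
chromosomes of 60–220 kb and 16–100 genes — large enough for ≥ 10⁵ CHH sites
where a law-of-large-numbers check needs them, and small enough that a full
study simulates in a couple of seconds. Stochastic properties (planted-DMR
recovery, null calibration, screen recovery) aggregate over 20 seeds in the
test suite and 8 seeds per quantity in the acceptance script.

## Known limitations

* The window z-test is anti-conservative for very low-coverage windows; the
  4-cytosine floor bounds but does not remove this, and the support rule is
  what ultimately protects the final set.
* Enrichment at desk scale (tens of genes) has little power at
  p_adj < 0.01; a four-way core module is not generally attainable on a
  100-gene simulation, which is a property of small universes rather than of
  the method, so core-pathway bookkeeping is exercised on published-scale
  inputs and the simulation walkthrough asserts the strongly powered
  DMR-side enrichment only.
* The Pearson r of the screen is computed per group over candidate genes;
  when candidates are few the value is reported with its n and should be
  read accordingly.
* No causal claim connects methylation to expression anywhere in the
  package; the screen is correlational by construction.
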