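"""Desk-scale synthetic study generator with planted ground truth.

Emulates the study design this package analyses: two phenotype groups
(drought *tolerant* and drought *sensitive*) of six genotypes each, assayed
under well-watered (control) and drought conditions, with per-cytosine
methylation counts in the CG / CHG / CHH contexts and a negative-binomial
expression count matrix. Effects are planted on three layers:

* **DMRs** — regions where the drought samples of one group shift their
  per-site methylation propensity by a configured Δ;
* **DEGs** — genes whose drought expression in one group is scaled by a
  configured log2 fold change;
* **negative-regulation genes** — genes receiving both a methylation shift
  in their 2-kb upstream (promoter-side) flank and an opposite-sign
  expression shift, the pattern the integration screen is built to find.

Everything is recorded in a :class:`TruthManifest` so downstream stages can
be scored for recovery. A fixed seed yields byte-identical output trees.

Methylation propensities are hierarchical: a per-genotype, per-context
baseline drawn around the configured global level (Beta, large
concentration), then per-site propensities around that (Beta, small
concentration), shared between the genotype's control and drought samples so
that within-genotype differences are pure sampling noise outside planted
regions. Planted shifts are proportional and bound-respecting —
hyper: ``p + delta*(1-p)/(1-baseline)``; hypo: ``p*(1 + delta/baseline)`` —
so the realised region-level Δ matches the configured Δ in expectation
without clipping bias.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio

__all__ = [
    "PlantedDMR",
    "PlantedDEG",
    "PlantedNegReg",
    "SimulationConfig",
    "TruthManifest",
    "SimulatedStudy",
    "simulate_study",
    "water_content",
]

_TRINUC = {"CG": "CGA", "CHG": "CAG", "CHH": "CAA"}
_GROUPS = ("tolerant", "sensitive")
_FLANK = 2000  # bp; promoter-side flank used for negative-regulation planting


@dataclass(frozen=True)
class PlantedDMR:
    """A batch of planted differentially methylated regions."""

    context: str
    delta: float  # signed fraction-scale shift (drought - control)
    width: int  # bp
    count: int
    group: str  # phenotype group whose drought samples shift


@dataclass(frozen=True)
class PlantedDEG:
    """A batch of planted differentially expressed genes."""

    log2fc: float
    count: int
    group: str


@dataclass(frozen=True)
class PlantedNegReg:
    """Planted negative-regulation genes: promoter methylation shift plus
    an opposite-sign expression shift."""

    group: str
    count: int
    meth_delta: float
    log2fc: float
    context: str = "CHH"


def _default_dmr_spec() -> list[PlantedDMR]:
    # Sensitive group planted with more regions and a hyper-methylation bias,
    # tolerant with fewer, balanced regions — the two response styles the
    # pipeline is meant to distinguish.
    return [
        PlantedDMR("CHH", +0.40, 400, 8, "sensitive"),
        PlantedDMR("CHH", -0.30, 400, 3, "sensitive"),
        PlantedDMR("CG", -0.30, 400, 2, "sensitive"),
        PlantedDMR("CHG", +0.25, 400, 2, "sensitive"),
        PlantedDMR("CHH", +0.40, 400, 4, "tolerant"),
        PlantedDMR("CHH", -0.30, 400, 3, "tolerant"),
        PlantedDMR("CG", -0.30, 400, 1, "tolerant"),
        PlantedDMR("CHG", -0.25, 400, 1, "tolerant"),
    ]


def _default_deg_spec() -> list[PlantedDEG]:
    return [
        PlantedDEG(+2.0, 12, "sensitive"),
        PlantedDEG(-2.0, 12, "sensitive"),
        PlantedDEG(+2.0, 5, "tolerant"),
        PlantedDEG(-2.0, 3, "tolerant"),
    ]


def _default_negreg_spec() -> list[PlantedNegReg]:
    return [
        PlantedNegReg("sensitive", 5, +0.40, -2.0),
        PlantedNegReg("sensitive", 4, -0.30, +2.0),
        PlantedNegReg("tolerant", 2, +0.40, -2.0),
        PlantedNegReg("tolerant", 2, -0.30, +2.0),
    ]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study.

    Defaults are the study conditions: per-context baseline methylation at
    the control-condition global levels (CG 92.3%, CHG 46.8%, CHH 32.2%),
    six genotypes per phenotype group, three RNA replicates per
    genotype x treatment (the study's biological replication) and one WGBS
    profile per genotype x treatment.
    """

    seed: int = 0
    n_chrom_A: int = 2
    n_chrom_C: int = 2
    chrom_length: int = 200_000
    n_genes: int = 100
    gene_length_range: tuple[int, int] = (1000, 2500)
    n_genotypes_per_group: int = 6
    rna_replicates: int = 3
    wgbs_replicates: int = 1
    baseline_meth: dict = field(
        default_factory=lambda: {"CG": 0.92308, "CHG": 0.46756, "CHH": 0.32164}
    )
    site_spacing: dict = field(default_factory=lambda: {"CG": 15, "CHG": 15, "CHH": 8})
    coverage_mean: float = 30.0
    genotype_meth_concentration: float = 400.0
    site_meth_concentration: float = 8.0
    body_meth_factor: dict = field(default_factory=lambda: {"CG": 1.0, "CHG": 1.0, "CHH": 1.0})
    planted_dmr_spec: list = field(default_factory=_default_dmr_spec)
    planted_deg_spec: list = field(default_factory=_default_deg_spec)
    planted_negreg_spec: list = field(default_factory=_default_negreg_spec)
    nb_dispersion: float = 0.05
    library_size_range: tuple[float, float] = (0.7, 1.3)
    mean_expression: float = 150.0
    expression_sigma: float = 1.0
    frac_silent_genes: float = 0.08
    n_terms: int = 30

    # intergenic margin reserved at the start of each gene slot; planted
    # non-promoter DMRs live there so they never collide with gene flanks
    _slot_margin: int = 2500

    @property
    def n_negreg_genes(self) -> int:
        return sum(s.count for s in self.planted_negreg_spec)

    def chrom_names(self) -> list[str]:
        return [f"A{i + 1:02d}" for i in range(self.n_chrom_A)] + [
            f"C{i + 1:02d}" for i in range(self.n_chrom_C)
        ]

    def validate(self) -> None:
        """Raise ValueError on any infeasible setting, before anything is drawn."""
        for ctx, b in self.baseline_meth.items():
            if not 0.0 <= b <= 1.0:
                raise ValueError(f"baseline methylation for {ctx} outside [0,1]: {b}")
        for spec in self.planted_dmr_spec:
            if spec.context not in mio.CONTEXTS:
                raise ValueError(f"unknown planted context {spec.context!r}")
            base = self.baseline_meth[spec.context]
            if not 0.0 <= base + spec.delta <= 1.0:
                raise ValueError(
                    f"planted delta {spec.delta:+g} pushes {spec.context} baseline "
                    f"{base} outside [0,1]"
                )
            if spec.width > self.chrom_length:
                raise ValueError("planted region wider than chromosome")
            if spec.width > self._slot_margin - 100:
                raise ValueError(
                    f"planted width {spec.width} does not fit the {self._slot_margin} bp "
                    "intergenic margin"
                )
            if spec.group not in _GROUPS:
                raise ValueError(f"unknown group {spec.group!r}")
        for spec in self.planted_negreg_spec:
            base = self.baseline_meth[spec.context]
            if not 0.0 <= base + spec.meth_delta <= 1.0:
                raise ValueError("negative-regulation methylation shift outside [0,1]")
        n_chrom = self.n_chrom_A + self.n_chrom_C
        per_chrom = -(-self.n_genes // n_chrom)
        slot = self.chrom_length // per_chrom
        if slot < self._slot_margin + self.gene_length_range[1] + 500:
            raise ValueError(
                f"{self.n_genes} genes do not fit {n_chrom} x {self.chrom_length} bp "
                "chromosomes with 2 kb flanks; enlarge chromosomes or drop genes"
            )
        n_dmr = sum(s.count for s in self.planted_dmr_spec)
        n_deg = sum(s.count for s in self.planted_deg_spec)
        if n_dmr > self.n_genes:
            raise ValueError("more planted DMRs than intergenic slots")
        if n_deg + self.n_negreg_genes > self.n_genes:
            raise ValueError("more planted DEG/negative-regulation genes than genes")


@dataclass
class TruthManifest:
    """Ground truth of every planted feature, for recovery scoring."""

    dmrs: pd.DataFrame  # chrom,start,end,context,delta,group,kind,gene_id
    degs: pd.DataFrame  # gene_id,log2fc,group,kind
    negreg: pd.DataFrame  # gene_id,chrom,start,end,context,meth_delta,log2fc,group


@dataclass
class SimulatedStudy:
    """In-memory synthetic study; per-sample CX frames built on demand."""

    config: SimulationConfig
    genes: pd.DataFrame
    sites: pd.DataFrame
    wgbs_samples: pd.DataFrame
    meth: np.ndarray  # sites x wgbs samples
    total: np.ndarray
    counts: pd.DataFrame
    samples: pd.DataFrame
    term_map: pd.DataFrame
    truth: TruthManifest

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.config.chrom_length for c in self.config.chrom_names()}

    def _wgbs_index(self, sample_id: str) -> int:
        idx = self.wgbs_samples.index[self.wgbs_samples["sample_id"] == sample_id]
        if len(idx) == 0:
            raise KeyError(f"no WGBS sample {sample_id!r}")
        return int(idx[0])

    def cx_report(self, sample_id: str) -> pd.DataFrame:
        """Per-cytosine record frame for one WGBS sample (CX-report schema)."""
        j = self._wgbs_index(sample_id)
        out = self.sites.copy()
        out["n_meth"] = self.meth[:, j]
        out["n_total"] = self.total[:, j]
        return out

    def pooled_cx(self, genotype_id: str, treatment: str) -> pd.DataFrame:
        """Replicate-pooled per-cytosine counts for one genotype x treatment."""
        mask = (self.wgbs_samples["genotype_id"] == genotype_id) & (
            self.wgbs_samples["treatment"] == treatment
        )
        cols = np.flatnonzero(mask.to_numpy())
        if len(cols) == 0:
            raise KeyError(f"no WGBS samples for {genotype_id}/{treatment}")
        out = self.sites.copy()
        out["n_meth"] = self.meth[:, cols].sum(axis=1)
        out["n_total"] = self.total[:, cols].sum(axis=1)
        return out

    def write(self, outdir) -> None:
        """Write the complete study as the plain-text formats the readers accept."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mio.write_gene_annotation(self.genes, outdir / "genes.gff3", format="GFF3")
        mio.write_count_matrix(self.counts, outdir / "counts.tsv")
        mio.write_sample_sheet(self.samples, outdir / "samples.tsv")
        mio.write_term_map(self.term_map, outdir / "term_map.tsv")
        cx_dir = outdir / "cx"
        cx_dir.mkdir(exist_ok=True)
        for sid in self.wgbs_samples["sample_id"]:
            mio.write_cx_report(self.cx_report(sid), cx_dir / f"{sid}.cx.tsv")
        self.truth.dmrs.to_csv(outdir / "truth_dmrs.tsv", sep="\t", index=False)
        self.truth.degs.to_csv(outdir / "truth_degs.tsv", sep="\t", index=False)
        self.truth.negreg.to_csv(outdir / "truth_negreg.tsv", sep="\t", index=False)
        with open(outdir / "config.txt", "w") as fh:
            fh.write(repr(dataclasses.asdict(self.config)) + "\n")


def water_content(fresh_weight: float, dry_weight: float) -> float:
    """Aboveground water content, the study's drought-tolerance index:
    ``(fresh - dry) / fresh``.

    Raises ValueError if ``fresh_weight <= 0`` or ``dry_weight`` outside
    ``[0, fresh_weight]``.
    """
    if fresh_weight <= 0:
        raise ValueError(f"fresh weight must be positive, got {fresh_weight}")
    if not 0 <= dry_weight <= fresh_weight:
        raise ValueError("dry weight must lie in [0, fresh weight]")
    return (fresh_weight - dry_weight) / fresh_weight


# ---------------------------------------------------------------------------
# generation internals
# ---------------------------------------------------------------------------

def _beta_mean_conc(rng, mean, conc, size):
    mean = np.clip(mean, 1e-6, 1 - 1e-6)
    return rng.beta(mean * conc, (1.0 - mean) * conc, size=size)


def _place_genes(cfg: SimulationConfig, rng) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lay genes into per-chromosome slots; return (genes, slots).

    Each slot reserves an intergenic margin at its start where a planted
    non-promoter DMR can live without touching any gene body or 2-kb flank.
    """
    chroms = cfg.chrom_names()
    per_chrom = -(-cfg.n_genes // len(chroms))
    slot = cfg.chrom_length // per_chrom
    gmin, gmax = cfg.gene_length_range
    rows, slots = [], []
    gid = 0
    for chrom in chroms:
        k = min(per_chrom, cfg.n_genes - gid)
        for i in range(k):
            slot_start = i * slot
            length = int(rng.integers(gmin, gmax + 1))
            start = slot_start + cfg._slot_margin
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"GENE{gid:04d}", chrom, start, start + length, strand))
            slots.append((chrom, slot_start))
            gid += 1
        if gid >= cfg.n_genes:
            break
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    genes["subgenome"] = genes["chrom"].map(mio.subgenome_of)
    slots_df = pd.DataFrame(slots, columns=["chrom", "slot_start"])
    return genes, slots_df


def _make_sites(cfg: SimulationConfig, rng) -> pd.DataFrame:
    frames = []
    for chrom in cfg.chrom_names():
        for ctx in mio.CONTEXTS:
            spacing = cfg.site_spacing[ctx]
            n_approx = int(cfg.chrom_length / spacing * 1.3) + 10
            gaps = rng.exponential(spacing, size=n_approx)
            pos = np.cumsum(gaps).astype(np.int64) + 1
            pos = np.unique(pos[pos <= cfg.chrom_length])
            strand = np.where(rng.random(len(pos)) < 0.5, "+", "-")
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "strand": strand,
                        "context": ctx,
                        "trinucleotide": _TRINUC[ctx],
                    }
                )
            )
    sites = pd.concat(frames, ignore_index=True)
    sites = sites.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return sites


def _shift_propensity(p: np.ndarray, delta: float, baseline: float) -> np.ndarray:
    if delta >= 0:
        return p + delta * (1.0 - p) / max(1.0 - baseline, 1e-9)
    return p * (1.0 + delta / max(baseline, 1e-9))


def simulate_study(config: SimulationConfig, outdir=None) -> SimulatedStudy:
    """Generate the complete synthetic study.

    Validates the configuration before drawing anything; with ``outdir``
    given, also writes every table through the package's writers. Fixed
    seed => byte-identical output.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    genes, slots = _place_genes(cfg, rng)
    sites = _make_sites(cfg, rng)
    n_sites = len(sites)
    pos = sites["pos"].to_numpy()
    site_chrom = sites["chrom"].to_numpy()
    site_ctx = sites["context"].to_numpy()

    genotypes = [f"T{i + 1:02d}" for i in range(cfg.n_genotypes_per_group)] + [
        f"S{i + 1:02d}" for i in range(cfg.n_genotypes_per_group)
    ]
    geno_group = {g: ("tolerant" if g.startswith("T") else "sensitive") for g in genotypes}

    # --- sample sheet (union of WGBS and RNA replicate structure) ----------
    n_reps = max(cfg.rna_replicates, cfg.wgbs_replicates)
    sheet_rows = [
        (f"{g}_{t}_{r}", g, geno_group[g], t, r)
        for g in genotypes
        for t in ("control", "drought")
        for r in range(1, n_reps + 1)
    ]
    samples = pd.DataFrame(
        sheet_rows, columns=["sample_id", "genotype_id", "group", "treatment", "replicate"]
    )
    wgbs_samples = samples[samples["replicate"] <= cfg.wgbs_replicates].reset_index(drop=True)
    rna_samples = samples[samples["replicate"] <= cfg.rna_replicates].reset_index(drop=True)

    # --- per-genotype site methylation propensities ------------------------
    in_body = np.zeros(n_sites, dtype=bool)
    for row in genes.itertuples(index=False):
        m = (site_chrom == row.chrom) & (pos > row.start) & (pos <= row.end)
        in_body |= m

    p_control = np.empty((n_sites, len(genotypes)))
    for j, g in enumerate(genotypes):
        for ctx in mio.CONTEXTS:
            m = site_ctx == ctx
            level = _beta_mean_conc(
                rng, cfg.baseline_meth[ctx], cfg.genotype_meth_concentration, None
            )
            p = _beta_mean_conc(rng, level, cfg.site_meth_concentration, int(m.sum()))
            factor = cfg.body_meth_factor.get(ctx, 1.0)
            if factor != 1.0:
                body_here = in_body[m]
                p = np.where(body_here, np.clip(p * factor, 0.0, 1.0), p)
            p_control[m, j] = p
    p_drought = p_control.copy()

    # --- plant DMRs (intergenic slots) -------------------------------------
    free_slots = rng.permutation(len(slots)).tolist()
    truth_dmr_rows = []

    def plant_region(chrom, start, end, ctx, delta, group, kind, gene_id=""):
        m = (site_chrom == chrom) & (pos > start) & (pos <= end) & (site_ctx == ctx)
        cols = [j for j, g in enumerate(genotypes) if geno_group[g] == group]
        base = cfg.baseline_meth[ctx]
        for j in cols:
            p_drought[m, j] = np.clip(
                _shift_propensity(p_control[m, j], delta, base), 0.0, 1.0
            )
        truth_dmr_rows.append((chrom, start, end, ctx, delta, group, kind, gene_id))

    for spec in cfg.planted_dmr_spec:
        for _ in range(spec.count):
            si = free_slots.pop()
            chrom = slots.iloc[si]["chrom"]
            s0 = int(slots.iloc[si]["slot_start"]) + 50
            plant_region(chrom, s0, s0 + spec.width, spec.context, spec.delta, spec.group, "dmr")

    # --- choose genes for negative regulation and plain DEGs ----------------
    gene_order = rng.permutation(len(genes)).tolist()
    negreg_rows = []
    deg_rows = []
    negreg_width = 400
    for spec in cfg.planted_negreg_spec:
        for _ in range(spec.count):
            gi = gene_order.pop()
            grow = genes.iloc[gi]
            if grow.strand == "+":
                r_start = grow.start - 1500
                r_end = r_start + negreg_width
            else:
                r_end = grow.end + 1500
                r_start = r_end - negreg_width
            plant_region(
                grow.chrom, int(r_start), int(r_end), spec.context, spec.meth_delta,
                spec.group, "negreg", grow.gene_id,
            )
            deg_rows.append((grow.gene_id, spec.log2fc, spec.group, "negreg"))
            negreg_rows.append(
                (grow.gene_id, grow.chrom, int(r_start), int(r_end), spec.context,
                 spec.meth_delta, spec.log2fc, spec.group)
            )
    for spec in cfg.planted_deg_spec:
        for _ in range(spec.count):
            gi = gene_order.pop()
            deg_rows.append((genes.iloc[gi].gene_id, spec.log2fc, spec.group, "deg"))

    truth = TruthManifest(
        dmrs=pd.DataFrame(
            truth_dmr_rows,
            columns=["chrom", "start", "end", "context", "delta", "group", "kind", "gene_id"],
        ),
        degs=pd.DataFrame(deg_rows, columns=["gene_id", "log2fc", "group", "kind"]),
        negreg=pd.DataFrame(
            negreg_rows,
            columns=["gene_id", "chrom", "start", "end", "context", "meth_delta",
                     "log2fc", "group"],
        ),
    )

    # --- WGBS read counts ---------------------------------------------------
    geno_index = {g: j for j, g in enumerate(genotypes)}
    n_wgbs = len(wgbs_samples)
    meth = np.empty((n_sites, n_wgbs), dtype=np.int32)
    total = np.empty((n_sites, n_wgbs), dtype=np.int32)
    for j, row in enumerate(wgbs_samples.itertuples(index=False)):
        p = p_control if row.treatment == "control" else p_drought
        cov = rng.poisson(cfg.coverage_mean, size=n_sites).astype(np.int32)
        total[:, j] = cov
        meth[:, j] = rng.binomial(cov, p[:, geno_index[row.genotype_id]])

    # --- expression counts --------------------------------------------------
    n_genes = len(genes)
    silent = rng.random(n_genes) < cfg.frac_silent_genes
    mu = np.exp(rng.normal(np.log(cfg.mean_expression), cfg.expression_sigma, n_genes))
    mu[silent] = 0.0
    lfc = {grp: np.zeros(n_genes) for grp in _GROUPS}
    gene_pos = {gid: i for i, gid in enumerate(genes["gene_id"])}
    for gid, l2, grp, _kind in truth.degs.itertuples(index=False):
        i = gene_pos[gid]
        mu[i] = max(mu[i], cfg.mean_expression)  # planted genes must be expressed
        lfc[grp][i] = l2

    lib = rng.uniform(*cfg.library_size_range, size=len(rna_samples))
    shape = 1.0 / cfg.nb_dispersion
    counts = np.zeros((n_genes, len(rna_samples)), dtype=np.int64)
    for j, row in enumerate(rna_samples.itertuples(index=False)):
        lam = mu * lib[j]
        if row.treatment == "drought":
            lam = lam * np.power(2.0, lfc[row.group])
        lam_g = rng.gamma(shape, lam * cfg.nb_dispersion)
        counts[:, j] = rng.poisson(lam_g)
    counts_df = pd.DataFrame(counts, index=genes["gene_id"].to_numpy(),
                             columns=rna_samples["sample_id"].to_list())
    counts_df.index.name = "gene_id"

    # --- gene -> term map ----------------------------------------------------
    term_ids = [f"T{i:03d}" for i in range(cfg.n_terms)]
    tm_rows = []
    for gid in genes["gene_id"]:
        k = int(rng.integers(1, 4))
        for t in rng.choice(cfg.n_terms, size=k, replace=False):
            tm_rows.append((gid, term_ids[t], f"pathway {term_ids[t]}"))
    # give every planted negative-regulation gene a shared stress pathway so
    # enrichment/hub-gene walkthroughs have signal to find
    for gid in truth.negreg["gene_id"]:
        tm_rows.append((gid, "T_STRESS", "drought stress response"))
    term_map = pd.DataFrame(tm_rows, columns=["gene_id", "term_id", "term_name"])

    study = SimulatedStudy(
        config=cfg,
        genes=genes,
        sites=sites,
        wgbs_samples=wgbs_samples,
        meth=meth,
        total=total,
        counts=counts_df,
        samples=samples,
        term_map=term_map,
        truth=truth,
    )
    if outdir is not None:
        study.write(outdir)
    return study
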