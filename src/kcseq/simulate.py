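"""Synthetic-data generator with planted ground truth.

Emulates the study design the pipeline targets: a 24-sample paired cohort
(4 psoriasis patients contributing lesional PP and uninvolved PN biopsies,
4 controls contributing NN, each grown as a keratinocyte monolayer and
profiled as whole skin), a ~90-sample normal-skin reference matrix with
planted co-expression modules, a GWAS locus table preferentially placed
near planted decreased genes, and promoter sequences with planted motif
occurrences.  Every planted effect is recorded in a :class:`SimTruth` so
downstream stages can be validated without external data.

Counts are negative binomial with variance mu + phi*mu^2.  The per-gene
mean combines a baseline relative abundance, a per-subject lognormal
multiplier shared across that subject's KC and skin samples (this makes
samples cluster by subject before tissue or status, the dominant structure
in real paired cohorts), a tissue effect, and a planted disease effect
applied to the PP and PN samples of the affected tissue.  The default
direction asymmetry plants more KC-decreased than skin-decreased genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import CountMatrix, ExpressionMatrix
from .motifs import PWM, REGION_LENGTH, revcomp

_BASES = np.array(list("ACGT"))

# sub-stream tags so the planted truth is a pure function of the seed
_STREAM = {"counts": 1, "degs": 2, "modules": 3, "reference": 4, "annotation": 5,
           "loci": 6, "promoters": 7, "genome": 8}


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for the generator (defaults = default scenario)."""

    n_patients: int = 4
    n_controls: int = 4
    n_genes: int = 4000
    subject_sd: float = 0.7          # log2-scale SD of the subject multiplier
    tissue_sd: float = 0.5           # log2-scale SD of the KC-vs-skin effect
    disease_lfc: float = 2.0         # planted |log2 FC| of disease effects
    disease_lfc_pn_scale: float = 0.7  # PN effect as a fraction of the PP effect
    frac_deg_kc_down: float = 0.05
    frac_deg_kc_up: float = 0.03
    frac_deg_skin_down: float = 0.01
    frac_deg_skin_up: float = 0.04
    dispersion: float = 0.1          # NB phi
    lib_size_range: tuple[int, int] = (10_000_000, 25_000_000)
    baseline_sd: float = 1.5         # natural-log SD of relative abundances
    frac_silent: float = 0.02        # genes driven below the detection limit
    n_ref_samples: int = 90
    n_modules: int = 90
    module_size_range: tuple[int, int] = (25, 60)
    module_cor: float = 0.8
    ref_base_sd: float = 0.25        # natural-log SD of reference gene levels
    ref_noise_sd: float = 0.4        # natural-log SD of reference noise
    align_modules_with_degs: bool = True
    n_chroms: int = 22
    gene_spacing: int = 60_000
    n_locus_regions: int = 67
    n_loci: int = 129
    locus_near_deg_frac: float = 0.6  # regions placed near planted KC-down genes
    locus_distance: int = 30_000
    gc_background_range: tuple[float, float] = (0.5, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_controls", "n_genes", "n_ref_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        fr_kc = self.frac_deg_kc_down + self.frac_deg_kc_up
        fr_sk = self.frac_deg_skin_down + self.frac_deg_skin_up
        for f in (self.frac_deg_kc_down, self.frac_deg_kc_up,
                  self.frac_deg_skin_down, self.frac_deg_skin_up):
            if not 0.0 <= f <= 1.0:
                raise ValueError("DEG fractions must lie in [0, 1]")
        if fr_kc > 1.0 or fr_sk > 1.0:
            raise ValueError("planted DEG fractions sum to more than 1 within a tissue")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be non-negative")
        if self.n_modules and not 0.0 < self.module_cor < 1.0:
            raise ValueError("module_cor must lie in (0, 1)")
        if self.module_size_range[0] < 25:
            raise ValueError("minimum module size is 25 genes")
        if self.lib_size_range[0] <= 0 or self.lib_size_range[1] < self.lib_size_range[0]:
            raise ValueError("lib_size_range must be a positive, ordered pair")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class SimTruth:
    """Planted ground truth: DEGs, modules, locus-adjacent genes, motif plants."""

    true_deg: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene", "tissue", "direction"])
    )
    true_module_of_gene: pd.Series = field(default_factory=lambda: pd.Series(dtype="Int64"))
    enriched_locus_genes: set[str] = field(default_factory=set)
    motif_plants: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene", "motif", "offset", "strand"])
    )

    def merge(self, other: "SimTruth") -> "SimTruth":
        return SimTruth(
            true_deg=other.true_deg if len(other.true_deg) else self.true_deg,
            true_module_of_gene=(
                other.true_module_of_gene if len(other.true_module_of_gene) else self.true_module_of_gene
            ),
            enriched_locus_genes=self.enriched_locus_genes | other.enriched_locus_genes,
            motif_plants=other.motif_plants if len(other.motif_plants) else self.motif_plants,
        )

    def deg_genes(self, tissue: str, direction: str) -> list[str]:
        t = self.true_deg
        return list(t.loc[(t["tissue"] == tissue) & (t["direction"] == direction), "gene"])


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAM[stream], config.seed])


def gene_ids(config: SimConfig) -> pd.Index:
    return pd.Index([f"G{i:05d}" for i in range(config.n_genes)], name="gene")


# ---------------------------------------------------------------------------
# planted DEG / module bookkeeping (shared across generator calls)


def planted_degs(config: SimConfig) -> pd.DataFrame:
    """Deterministic planted DEG table (gene, tissue, direction)."""
    rng = _rng(config, "degs")
    genes = gene_ids(config)
    n = config.n_genes
    sizes = {
        ("KC", "down"): int(round(config.frac_deg_kc_down * n)),
        ("KC", "up"): int(round(config.frac_deg_kc_up * n)),
        ("skin", "down"): int(round(config.frac_deg_skin_down * n)),
        ("skin", "up"): int(round(config.frac_deg_skin_up * n)),
    }
    total = sum(sizes.values())
    chosen = rng.choice(n, size=min(total, n), replace=False)
    rows, k = [], 0
    for (tissue, direction), sz in sizes.items():
        for g in chosen[k : k + sz]:
            rows.append((genes[g], tissue, direction))
        k += sz
    return pd.DataFrame(rows, columns=["gene", "tissue", "direction"])


def module_assignment(config: SimConfig) -> pd.Series:
    """Deterministic gene -> module mapping (NA for unassigned genes).

    When ``align_modules_with_degs`` is set, planted KC-decreased genes are
    packed into the first modules so that count-level disease effects and
    reference-matrix co-expression agree, as they would for a real
    disease-repressed pathway.
    """
    rng = _rng(config, "modules")
    genes = gene_ids(config)
    assign = pd.Series(pd.NA, index=genes, dtype="Int64")
    if config.n_modules == 0:
        return assign
    lo, hi = config.module_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_modules)
    pool: list[str] = []
    if config.align_modules_with_degs:
        pool.extend(planted_degs(config).query("tissue == 'KC' and direction == 'down'")["gene"])
    rest = [g for g in genes if g not in set(pool)]
    rng.shuffle(rest)
    pool.extend(rest)
    if sizes.sum() > len(pool):
        raise ValueError("modules do not fit within n_genes")
    k = 0
    for m, sz in enumerate(sizes):
        assign.loc[pool[k : k + sz]] = m
        k += sz
    return assign


# ---------------------------------------------------------------------------
# counts


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """NB counts for the 24-sample paired design, plus the planted truth."""
    rng = _rng(config, "counts")
    genes = gene_ids(config)
    n = config.n_genes

    subjects = [f"P{i+1}" for i in range(config.n_patients)] + [
        f"C{i+1}" for i in range(config.n_controls)
    ]
    rows = []
    for subj in subjects:
        statuses = ("PP", "PN") if subj.startswith("P") else ("NN",)
        for status in statuses:
            for tissue in ("KC", "skin"):
                rows.append((f"{subj}_{status}_{tissue}", subj, tissue, status))
    meta = pd.DataFrame(rows, columns=["sample", "subject", "tissue", "status"]).set_index("sample")

    baseline = np.exp(rng.normal(0.0, config.baseline_sd, size=n))
    silent = rng.random(n) < config.frac_silent
    baseline[silent] *= 1e-4
    tissue_eff = 2.0 ** rng.normal(0.0, config.tissue_sd, size=n)  # skin relative to KC
    subj_eff = {s: 2.0 ** rng.normal(0.0, config.subject_sd, size=n) for s in subjects}

    truth_deg = planted_degs(config)
    disease = {"KC": np.zeros(n), "skin": np.zeros(n)}
    gpos = pd.Series(np.arange(n), index=genes)
    for _, r in truth_deg.iterrows():
        disease[r["tissue"]][gpos[r["gene"]]] = (
            -config.disease_lfc if r["direction"] == "down" else config.disease_lfc
        )

    lib_sizes = rng.integers(config.lib_size_range[0], config.lib_size_range[1] + 1,
                             size=len(meta))
    counts = np.empty((n, len(meta)), dtype=np.int64)
    for j, (sample, m) in enumerate(meta.iterrows()):
        rel = baseline * subj_eff[m["subject"]]
        if m["tissue"] == "skin":
            rel = rel * tissue_eff
        if m["status"] in ("PP", "PN"):
            scale = 1.0 if m["status"] == "PP" else config.disease_lfc_pn_scale
            rel = rel * 2.0 ** (scale * disease[m["tissue"]])
        mu = lib_sizes[j] * rel / rel.sum()
        if config.dispersion < 1e-8:
            counts[:, j] = rng.poisson(mu)
        else:
            shape = 1.0 / config.dispersion
            counts[:, j] = rng.poisson(rng.gamma(shape, mu * config.dispersion))
    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=meta.index), meta)
    return cm, SimTruth(true_deg=truth_deg)


# ---------------------------------------------------------------------------
# reference matrix


def simulate_reference_matrix(config: SimConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """FPKM-like reference matrix with planted co-expression modules.

    Genes of a module share a per-sample latent factor so that their
    pairwise latent correlation equals ``module_cor``; independent genes
    have none.  Values are exponentiated (lognormal-like), which mildly
    attenuates the Pearson correlation on the FPKM scale.
    """
    if config.n_ref_samples < 2:
        raise ValueError("need at least 2 reference samples")
    rng = _rng(config, "reference")
    genes = gene_ids(config)
    S = config.n_ref_samples
    assign = module_assignment(config)
    z = rng.normal(0.0, 1.0, size=(config.n_genes, S))
    if config.n_modules:
        rho = config.module_cor
        factors = rng.normal(0.0, 1.0, size=(config.n_modules, S))
        codes = assign.to_numpy(dtype="float")
        in_mod = ~np.isnan(codes)
        mids = codes[in_mod].astype(int)
        z[in_mod] = np.sqrt(rho) * factors[mids] + np.sqrt(1.0 - rho) * z[in_mod]
    base = rng.normal(2.0, config.ref_base_sd, size=config.n_genes)
    vals = np.exp(base[:, None] + config.ref_noise_sd * z)
    cols = [f"ref{j+1:02d}" for j in range(S)]
    em = ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=cols))
    return em, SimTruth(true_module_of_gene=assign)


# ---------------------------------------------------------------------------
# annotation and loci


def simulate_annotation(config: SimConfig) -> pd.DataFrame:
    """Gene annotation: chrom, tss, strand, length, go_n.

    TSS coordinates are strictly increasing and non-overlapping within each
    chromosome.  One gene per planted module receives the largest GO-term
    count among its members, so module labelling has a well-defined answer.
    """
    rng = _rng(config, "annotation")
    genes = gene_ids(config)
    n = config.n_genes
    n_chrom = min(config.n_chroms, n)
    chrom_of = np.arange(n) % n_chrom
    tss = np.empty(n, dtype=int)
    for c in range(n_chrom):
        idx = np.flatnonzero(chrom_of == c)
        jitter = rng.integers(0, max(config.gene_spacing // 4, 1), size=idx.size)
        tss[idx] = 100_000 + np.arange(idx.size) * config.gene_spacing + jitter
    strand = rng.choice(["+", "-"], size=n)
    length = np.clip(
        np.exp(rng.normal(7.8, 0.6, size=n)).astype(int), 200, config.gene_spacing // 2
    )
    go_n = rng.poisson(8, size=n)
    ann = pd.DataFrame(
        {
            "chrom": [f"chr{c+1}" for c in chrom_of],
            "tss": tss,
            "strand": strand,
            "length": length,
            "go_n": go_n,
        },
        index=genes,
    )
    assign = module_assignment(config)
    for m in range(config.n_modules):
        members = list(assign.index[assign == m])
        if not members:
            continue
        star = members[int(rng.integers(len(members)))]
        ann.loc[star, "go_n"] = int(ann.loc[members, "go_n"].max()) + 25
    return ann


def simulate_loci(config: SimConfig, annotation: pd.DataFrame) -> tuple[pd.DataFrame, SimTruth]:
    """GWAS locus table: regions with one or more loci, placed so that a
    configured fraction of regions lies near planted KC-decreased genes.

    Defaults produce 129 loci in 67 independent regions.
    """
    rng = _rng(config, "loci")
    kc_down = planted_degs(config).query("tissue == 'KC' and direction == 'down'")["gene"]
    n_near = int(round(config.locus_near_deg_frac * config.n_locus_regions))
    near_genes = list(rng.choice(kc_down, size=min(n_near, len(kc_down)), replace=False)) if len(kc_down) else []
    rows = []
    enriched: set[str] = set()
    for r in range(config.n_locus_regions):
        if r < len(near_genes):
            g = near_genes[r]
            chrom = annotation.loc[g, "chrom"]
            pos = int(annotation.loc[g, "tss"] + rng.integers(-config.locus_distance, config.locus_distance + 1))
            enriched.add(g)
        else:
            chrom = f"chr{int(rng.integers(min(config.n_chroms, config.n_genes))) + 1}"
            hi = int(annotation.loc[annotation['chrom'] == chrom, 'tss'].max()) + 50_000
            pos = int(rng.integers(1, hi))
        rows.append((f"region{r+1:03d}", f"rs{rng.integers(10**6, 10**7)}", chrom,
                     max(pos, 1), 10.0 ** -rng.uniform(8, 30)))
    # extra loci within already-defined regions (less significant, nearby)
    extra = config.n_loci - config.n_locus_regions
    for _ in range(max(extra, 0)):
        r = int(rng.integers(config.n_locus_regions))
        region, _, chrom, pos, p = rows[r]
        rows.append((region, f"rs{rng.integers(10**6, 10**7)}", chrom,
                     max(pos + int(rng.integers(-20_000, 20_001)), 1),
                     min(p * 10.0 ** rng.uniform(1, 6), 1.0)))
    loci = pd.DataFrame(rows, columns=["region", "snp", "chrom", "pos", "pvalue"])
    return loci, SimTruth(enriched_locus_genes=enriched)


# ---------------------------------------------------------------------------
# promoters, motif plants and genome


def simulate_promoters_and_motifs(
    config: SimConfig,
    annotation: pd.DataFrame,
    motifs: list[PWM],
    target_genes: list[str] | None = None,
    plant_motifs: list[str] | None = None,
    plant_frac_target: float = 0.5,
    plant_frac_background: float = 0.05,
) -> tuple[pd.DataFrame, SimTruth]:
    """Background promoter sequences with planted motif consensus sites.

    Each gene gets a 5500-base sequence drawn from an i.i.d. base model
    whose GC content is sampled from ``gc_background_range``; the planted
    motifs' consensus strings are inserted at recorded offsets (either
    strand) in a fraction of the target gene set and of the remaining
    background.  Sequences are gene-oriented, so offsets refer to the
    region a downstream scanner sees.

    Returns (promoters frame indexed by gene: sequence, gc; truth).
    """
    for p in motifs:
        if p.width >= REGION_LENGTH:
            raise ValueError(f"motif {p.id} wider than the promoter region")
    rng = _rng(config, "promoters")
    genes = list(annotation.index)
    if target_genes is None:
        target_genes = planted_degs(config).query("tissue == 'KC' and direction == 'down'")["gene"].tolist()
        target_genes = [g for g in target_genes if g in set(genes)]
    plant_ids = plant_motifs if plant_motifs is not None else ([motifs[0].id] if motifs else [])
    by_id = {p.id: p for p in motifs}

    gc_lo, gc_hi = config.gc_background_range
    seqs, gcs, plant_rows = {}, {}, []
    target_set = set(target_genes)
    for g in genes:
        gc = rng.uniform(gc_lo, gc_hi)
        probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        seq = "".join(_BASES[rng.choice(4, size=REGION_LENGTH, p=probs)])
        frac = plant_frac_target if g in target_set else plant_frac_background
        for mid in plant_ids:
            if rng.random() < frac:
                pwm = by_id[mid]
                site = pwm.consensus
                strand = "+" if rng.random() < 0.5 else "-"
                ins = site if strand == "+" else revcomp(site)
                off = int(rng.integers(0, REGION_LENGTH - pwm.width + 1))
                seq = seq[:off] + ins + seq[off + pwm.width :]
                plant_rows.append((g, mid, off, strand))
        seqs[g] = seq
        gcs[g] = (seq.count("G") + seq.count("C")) / len(seq)
    promoters = pd.DataFrame({"sequence": pd.Series(seqs), "gc": pd.Series(gcs)})
    promoters.index.name = "gene"
    truth = SimTruth(motif_plants=pd.DataFrame(plant_rows, columns=["gene", "motif", "offset", "strand"]))
    return promoters, truth


def simulate_genome(
    config: SimConfig, annotation: pd.DataFrame, promoters: pd.DataFrame
) -> dict[str, str]:
    """Random genome whose promoter spans reproduce the given sequences.

    Promoter sequences are pasted into each gene's TSS-proximal span
    (reverse-complemented for minus-strand genes) so that downstream
    promoter extraction recovers them exactly.  Intended for small
    configurations; sequence size grows with gene spacing.
    """
    rng = _rng(config, "genome")
    genome = {}
    for chrom, grp in annotation.groupby("chrom"):
        clen = int(grp["tss"].max()) + REGION_LENGTH + 1000
        arr = rng.choice(4, size=clen)
        seq = np.array(list("ACGT"))[arr]
        for gene, row in grp.iterrows():
            if gene not in promoters.index:
                continue
            tss = int(row["tss"])
            prom = promoters.loc[gene, "sequence"]
            if row["strand"] == "+":
                start = tss - 5000
                ins = prom
            else:
                start = tss - 500
                ins = revcomp(prom)
            if start < 0 or start + len(ins) > clen:
                continue
            seq[start : start + len(ins)] = list(ins)
        genome[str(chrom)] = "".join(seq)
    return genome


# ---------------------------------------------------------------------------
# external signatures and open chromatin


def simulate_signature(
    config: SimConfig, tissue: str = "KC", direction: str = "down", n_extra: int = 0
) -> pd.DataFrame:
    """A named gene list emulating an external expression signature.

    Built from planted DEGs of the requested tissue/direction (plus
    optional unrelated genes), with the signature direction set opposite to
    the planted disease change -- e.g. planted KC-decreased genes stand in
    for a differentiation-up signature repressed in disease.
    """
    rng = _rng(config, "loci")
    genes = planted_degs(config).query("tissue == @tissue and direction == @direction")["gene"].tolist()
    others = [g for g in gene_ids(config) if g not in set(genes)]
    extra = list(rng.choice(others, size=min(n_extra, len(others)), replace=False))
    sig_dir = "up" if direction == "down" else "down"
    return pd.DataFrame({"gene": genes + extra, "direction": sig_dir})


def simulate_open_chromatin(
    config: SimConfig,
    annotation: pd.DataFrame,
    genes_with_open_promoters: list[str],
    interval_width: int = 400,
) -> pd.DataFrame:
    """BED-style open-chromatin intervals centred on selected promoters."""
    rng = _rng(config, "genome")
    rows = []
    for g in genes_with_open_promoters:
        row = annotation.loc[g]
        tss = int(row["tss"])
        centre = tss - int(rng.integers(0, 4000)) if row["strand"] == "+" else tss + int(rng.integers(0, 4000))
        rows.append((row["chrom"], max(centre - interval_width // 2, 0), centre + interval_width // 2))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
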