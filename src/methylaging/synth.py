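"""Synthetic methylation, expression and GWAS data with known ground truth.

Every downstream stage of the pipeline (clock evaluation, age-acceleration
regression, paired differential-expression meta-analysis, permutation
gene-set enrichment) is testable against a world whose parameters are known
exactly:

* **Methylation** — a synthetic clock is built so that a noiseless beta
  profile generated for chronological age ``x`` in a tissue with aging-rate
  multiplier ``r`` yields DNAm age exactly ``r * x``.  A cerebellum-like
  tissue is given ``r < 1`` (it accumulates epigenetic age more slowly);
  reference tissues have ``r = 1``.
* **Expression** — a matched multi-region design (every subject measured in
  all regions) with a subject random intercept, per-region scalar shifts and
  planted over-/under-expressed probes in the contrast region.
* **GWAS** — multiple studies over one SNP panel; causal SNPs are placed
  inside the +/-50 kb windows of genes belonging to designated "enriched"
  gene sets and share their effect sign across studies; null SNPs have
  effect estimates drawn from N(0, SE^2).

One global seed fans out to per-stage child streams through
``numpy.random.SeedSequence`` spawn keys, so each generator is reproducible
in isolation and the whole bundle is byte-identical for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clock import ClockDefinition, inverse_transform_age, transform_age

__all__ = [
    "SimulationTruth",
    "make_clock",
    "simulate_methylation",
    "simulate_expression",
    "simulate_gwas",
    "make_gene_annotation",
    "make_gene_sets",
]

# stage indices for the splittable seed counter
_STAGES = {"clock": 0, "methylation": 1, "expression": 2, "gwas": 3, "annotation": 4}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Child RNG for a named pipeline stage, derived from one global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(int(seed), spawn_key=(_STAGES[stage],))
    )


@dataclass
class SimulationTruth:
    """Ground truth shared by the three generators.

    ``tissue_rate`` maps tissue name to an aging-rate multiplier (a
    cerebellum-like tissue < 1, reference tissues = 1).  ``noise_sd_beta``
    is the SD of i.i.d. Gaussian noise added on the beta scale (clipped to
    [0, 1]).  ``de_truth`` maps expression probe id to a planted
    log-expression effect in the contrast region (positive = over-expressed
    there).  ``enriched_sets`` maps gene-set name to a per-SNP causal effect
    size for the GWAS generator.
    """

    clock: ClockDefinition
    tissue_rate: dict[str, float]
    noise_sd_beta: float = 0.2
    de_truth: dict[str, float] = field(default_factory=dict)
    enriched_sets: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.tissue_rate.values()):
            raise ValueError("tissue aging-rate multipliers must be > 0")
        if self.noise_sd_beta < 0:
            raise ValueError("noise_sd_beta must be >= 0")


def make_clock(
    n_cpgs: int = 353,
    adult_age: float = 20.0,
    seed: int = 0,
    max_age: float = 120.0,
) -> ClockDefinition:
    """Construct a synthetic clock whose prediction inverts its generator.

    Each CpG gets a baseline beta ``b_i`` (uniform in [0.3, 0.7]) and a slope
    ``s_i`` on the transformed-age scale, with a random sign; amplitudes are
    scaled so betas stay within [0.05, 0.95] for ages 0..``max_age``.
    Weights satisfy ``sum_i w_i * s_i = 1`` and the intercept cancels the
    baselines, so a noiseless profile generated at transformed age ``t``
    scores exactly ``t`` — the calibration transform is exercised on both
    branches.
    """
    if n_cpgs < 1:
        raise ValueError("n_cpgs must be >= 1")
    rng = np.random.default_rng(seed)
    baseline = rng.uniform(0.3, 0.7, size=n_cpgs)
    direction = rng.choice([-1.0, 1.0], size=n_cpgs)
    f_extent = max(
        abs(transform_age(0.0, adult_age)), transform_age(max_age, adult_age)
    )
    amp = np.minimum(baseline - 0.05, 0.95 - baseline)
    slope = direction * amp / f_extent
    weights = direction * f_extent / (n_cpgs * amp)
    intercept = -float(weights @ baseline)
    cpg_ids = [f"cg{i:08d}" for i in range(n_cpgs)]
    return ClockDefinition(
        cpg_ids=cpg_ids,
        weights=weights,
        intercept=intercept,
        adult_age=adult_age,
        baseline=baseline,
        slope=slope,
    )


def simulate_methylation(
    truth: SimulationTruth,
    subjects: list[tuple[float, list[str], int]],
    n_filler_cpgs: int = 500,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a beta matrix and sample sheet for a multi-tissue cohort.

    ``subjects`` is a list of ``(age, tissues, n_replicates)``.  For every
    sample, clock-CpG betas are
    ``baseline + slope * F(rate * age) + N(0, noise_sd_beta)`` clipped to
    [0, 1]; filler CpGs are age-independent.  Replicates of one subject and
    tissue differ only by noise.

    Returns ``(beta, sheet)``: a CpG x sample DataFrame and a sample sheet
    with columns sample_id, subject_id, tissue, age, replicate.
    """
    clock = truth.clock
    if clock.baseline is None or clock.slope is None:
        raise ValueError("truth.clock must be a synthetic clock with ground truth")
    rng = stage_rng(truth.seed, "methylation")

    rows = []
    for subj_idx, (age, tissues, n_rep) in enumerate(subjects):
        if age < 0:
            raise ValueError(f"subject {subj_idx}: negative age {age}")
        for tissue in tissues:
            if tissue not in truth.tissue_rate:
                raise ValueError(f"unknown tissue {tissue!r}")
            for rep in range(1, int(n_rep) + 1):
                rows.append((subj_idx, tissue, float(age), rep))
    if not rows:
        raise ValueError("no samples requested")

    sheet = pd.DataFrame(rows, columns=["subject_id", "tissue", "age", "replicate"])
    sheet.insert(
        0,
        "sample_id",
        [
            f"S{s:03d}_{t}_r{r}"
            for s, t, r in zip(sheet.subject_id, sheet.tissue, sheet.replicate)
        ],
    )
    sheet["subject_id"] = [f"subj{s:03d}" for s in sheet.subject_id]

    rate = sheet.tissue.map(truth.tissue_rate).to_numpy(dtype=float)
    t_age = transform_age(rate * sheet.age.to_numpy(dtype=float), clock.adult_age)

    clock_block = clock.baseline[:, None] + clock.slope[:, None] * t_age[None, :]
    filler_base = rng.uniform(0.05, 0.95, size=n_filler_cpgs)
    filler_block = np.repeat(filler_base[:, None], len(sheet), axis=1)
    values = np.vstack([clock_block, filler_block])
    if truth.noise_sd_beta > 0:
        values = values + rng.normal(0.0, truth.noise_sd_beta, size=values.shape)
        values = np.clip(values, 0.0, 1.0)

    cpgs = list(clock.cpg_ids) + [f"fl{i:08d}" for i in range(n_filler_cpgs)]
    beta = pd.DataFrame(values, index=pd.Index(cpgs, name="cpg_id"),
                        columns=sheet.sample_id.to_list())
    return beta, sheet


def simulate_expression(
    truth: SimulationTruth,
    n_subjects: int,
    regions: list[str],
    contrast_region: str | None = None,
    m_probes: int = 2000,
    noise_sd: float = 1.0,
    subject_sd: float = 1.0,
    region_sd: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Matched multi-region expression with planted DE in the contrast region.

    Model per probe ``p``, subject ``s``, region ``r`` (log scale):
    ``mu_p + u_s + gamma_r + 1[r == contrast] * effect_p + eps`` with
    ``u_s ~ N(0, subject_sd^2)``, per-region scalar shifts
    ``gamma_r ~ N(0, region_sd^2)`` shared across probes (library-size-like,
    cancelled by the rank-based meta-analysis) and
    ``eps ~ N(0, noise_sd^2)`` i.i.d.  Planted effects come from
    ``truth.de_truth`` (probe id -> effect).

    Returns ``(expr, sample_map)``: probe x sample DataFrame and a map with
    columns sample_id, subject_id, region.
    """
    if len(regions) < 2:
        raise ValueError("need at least 2 regions")
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects for a paired analysis")
    contrast = regions[0] if contrast_region is None else contrast_region
    if contrast not in regions:
        raise ValueError(f"contrast region {contrast!r} not in regions")
    rng = stage_rng(truth.seed, "expression")

    probes = [f"pr{i:06d}" for i in range(m_probes)]
    effect = np.zeros(m_probes)
    for pid, eff in truth.de_truth.items():
        if pid not in probes:
            raise ValueError(f"de_truth probe {pid!r} outside probe universe")
        effect[probes.index(pid)] = eff

    mu = rng.uniform(2.0, 10.0, size=m_probes)
    u = rng.normal(0.0, subject_sd, size=n_subjects)
    gamma = rng.normal(0.0, region_sd, size=len(regions))

    cols, data = [], []
    sample_rows = []
    for s in range(n_subjects):
        for j, region in enumerate(regions):
            x = mu + u[s] + gamma[j]
            if region == contrast:
                x = x + effect
            x = x + rng.normal(0.0, noise_sd, size=m_probes)
            sid = f"E{s:03d}_{region}"
            cols.append(sid)
            data.append(x)
            sample_rows.append((sid, f"subj{s:03d}", region))
    expr = pd.DataFrame(
        np.column_stack(data), index=pd.Index(probes, name="probe_id"), columns=cols
    )
    sample_map = pd.DataFrame(sample_rows, columns=["sample_id", "subject_id", "region"])
    return expr, sample_map


def make_gene_annotation(
    n_genes: int = 100,
    seed: int = 0,
    n_chroms: int = 4,
    gene_length: tuple[int, int] = (5_000, 50_000),
    spacing: int = 150_000,
) -> pd.DataFrame:
    """Non-overlapping synthetic gene annotation (BED-style, 0-based half-open)."""
    rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(4,)))
    rows = []
    for i in range(n_genes):
        chrom = f"chr{i % n_chroms + 1}"
        slot = i // n_chroms
        start = 10_000 + slot * spacing + int(rng.integers(0, 20_000))
        length = int(rng.integers(*gene_length))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((f"gene{i:04d}", chrom, start, start + length, strand))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def make_gene_sets(
    genes: pd.DataFrame,
    n_sets: int = 10,
    set_size: int = 15,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Random gene sets drawn without replacement from an annotation."""
    rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(5,)))
    ids = genes.gene_id.to_list()
    return {
        f"set{k:02d}": sorted(rng.choice(ids, size=min(set_size, len(ids)),
                                         replace=False).tolist())
        for k in range(n_sets)
    }


def simulate_gwas(
    truth: SimulationTruth,
    n_studies: int,
    genes: pd.DataFrame,
    gene_sets: dict[str, list[str]] | None = None,
    maf_range: tuple[float, float] = (0.05, 0.5),
    n_per_study: int = 100,
    snps_per_gene: int = 5,
    window: int = 50_000,
) -> list[pd.DataFrame]:
    """Per-study GWAS summary statistics over a shared SNP panel.

    SNPs are placed inside each gene's +/-``window`` region (so every SNP is
    assignable).  Genes belonging to a set named in ``truth.enriched_sets``
    carry one causal SNP whose true effect magnitude is the set's effect
    size; its sign is drawn once and shared across studies.  Study ``k``
    reports ``beta_hat = true_beta + N(0, SE^2)`` with
    ``SE = 1 / sqrt(2 * maf * (1 - maf) * n_per_study)``.

    Positions in the returned tables are 1-based (GWAS convention).
    """
    if n_studies < 1:
        raise ValueError("need at least one study")
    if genes is None or len(genes) == 0:
        raise ValueError("empty gene annotation")
    rng = stage_rng(truth.seed, "gwas")
    gene_sets = gene_sets or {}

    causal_genes: set[str] = set()
    gene_effect: dict[str, float] = {}
    for set_name, eff in truth.enriched_sets.items():
        if set_name not in gene_sets:
            raise ValueError(f"enriched set {set_name!r} not in gene_sets")
        for g in gene_sets[set_name]:
            causal_genes.add(g)
            gene_effect[g] = float(eff)

    snp_rows = []  # snp_id, chrom, pos(1-based), maf, true_beta
    counter = 0
    margin = int(window * 0.8)  # keep SNPs safely inside the window
    for rec in genes.itertuples(index=False):
        lo = max(1, rec.start - margin)
        hi = rec.end + margin
        pos = np.sort(rng.integers(lo, hi, size=snps_per_gene))
        mafs = rng.uniform(*maf_range, size=snps_per_gene)
        causal_idx = rng.integers(0, snps_per_gene) if rec.gene_id in causal_genes else -1
        for j in range(snps_per_gene):
            beta_true = 0.0
            if j == causal_idx:
                sign = -1.0 if rng.random() < 0.5 else 1.0
                beta_true = sign * gene_effect[rec.gene_id]
            snp_rows.append(
                (f"rs{counter:07d}", rec.chrom, int(pos[j]) + 1, mafs[j], beta_true)
            )
            counter += 1
    panel = pd.DataFrame(
        snp_rows, columns=["snp_id", "chrom", "pos", "maf", "beta_true"]
    )

    se = 1.0 / np.sqrt(2.0 * panel.maf * (1.0 - panel.maf) * n_per_study)
    studies = []
    for _k in range(n_studies):
        beta_hat = panel.beta_true + rng.normal(0.0, se)
        studies.append(
            pd.DataFrame(
                {
                    "snp_id": panel.snp_id,
                    "chrom": panel.chrom,
                    "pos": panel.pos,
                    "beta": beta_hat,
                    "se": se,
                }
            )
        )
    return studies


def noiseless_dnam_age(truth: SimulationTruth, tissue: str, age: float) -> float:
    """Closed-form DNAm age of a noiseless sample: ``rate * age``."""
    rate = truth.tissue_rate[tissue]
    return float(
        inverse_transform_age(
            transform_age(rate * age, truth.clock.adult_age), truth.clock.adult_age
        )
    )
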