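"""Synthetic matched case-control cohorts with planted gene-level effects.

The generator emulates a young-onset-hypertension style design: a
population pool is simulated with per-SNP minor-allele frequencies and
within-gene LD (latent Gaussian, AR(1) correlation, thresholded to
Hardy-Weinberg genotype frequencies), disease status follows a logistic
liability on planted causal minor-allele counts plus a BMI term, cases
are ascertained from the affected and each is matched to an unaffected
control of the same gender within +/-5 years of age.

Companion expression matrices carry a group-level mean shift at the
planted genes on top of i.i.d. Gaussian noise and a linear BMI nuisance
term, mirroring a small matched expression follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .containers import (
    MISSING,
    ExpressionMatrix,
    GeneRecord,
    GenotypeDataset,
    MatchedDesign,
)

AGE_MATCH_YEARS = 5  # matching caliper, years


class SimulationError(RuntimeError):
    """Cohort could not be assembled (e.g. matching infeasible)."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated cohort.

    Defaults describe a scaled genome: 400 matched pairs, 20 genes with a
    mean of 6 SNPs each plus 60 intergenic SNPs, MAF uniform on
    [0.05, 0.5], AR(1) within-gene LD 0.3, two causal genes carrying five
    causal SNPs each at a per-allele odds ratio of 1.7, a BMI effect of
    0.1 log-odds per kg/m^2, and 0.2% missing calls (typical BeadChip
    missingness, under which nearly all samples pass the 0.99 call-rate
    gate as in the emulated design).
    """

    n_pairs: int = 400
    n_genes: int = 20
    snps_per_gene: int = 6          # Poisson mean, truncated at >=1
    n_intergenic_snps: int = 60
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.3
    causal_genes: int = 2
    causal_snps_per_gene: int = 5
    per_allele_log_or: float = float(np.log(1.7))
    bmi_log_or: float = 0.1
    missing_rate: float = 0.002
    base_prevalence: float = 0.2
    pool_factor: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_rate", "base_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not (0.0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError(f"ld_rho must be in [0,1), got {self.ld_rho}")
        if self.causal_genes > self.n_genes:
            raise ValueError("causal_genes exceeds n_genes")
        if min(self.n_pairs, self.n_genes, self.snps_per_gene, self.pool_factor) < 1:
            raise ValueError("counts must be positive")


@dataclass
class TruthTable:
    """Which genes/SNPs carry a planted effect, and how large."""

    causal_gene_ids: set[str] = field(default_factory=set)
    causal_snp_ids: set[str] = field(default_factory=set)
    snp_log_or: dict[str, float] = field(default_factory=dict)


def _genotypes_from_latent(z: np.ndarray, maf: np.ndarray) -> np.ndarray:
    """Threshold standard-normal latents to HWE genotype counts per column."""
    q = 1.0 - maf
    t_lo = norm.ppf(q**2)          # below: major homozygote
    t_hi = norm.ppf(1.0 - maf**2)  # above: minor homozygote
    g = np.zeros(z.shape, dtype=np.int8)
    g[z >= t_lo] = 1
    g[z >= t_hi] = 2
    return g


def _simulate_block(rng: np.random.Generator, n: int, maf: np.ndarray, rho: float) -> np.ndarray:
    """AR(1)-correlated latent Gaussians thresholded to genotypes; shape (n, L)."""
    L = len(maf)
    e = rng.standard_normal((n, L))
    z = np.empty_like(e)
    z[:, 0] = e[:, 0]
    a = np.sqrt(1.0 - rho**2)
    for j in range(1, L):
        z[:, j] = rho * z[:, j - 1] + a * e[:, j]
    return _genotypes_from_latent(z, maf)


def simulate_cohort(config: SimConfig):
    """Simulate (GenotypeDataset, MatchedDesign, gene records, TruthTable).

    Identical config (including seed) gives identical outputs. Raises
    :class:`SimulationError` when the population pool cannot supply the
    requested number of matched pairs.
    """
    rng = np.random.default_rng(config.seed)
    n_pool = 2 * config.n_pairs * config.pool_factor

    # --- genome layout: genes tiled over chromosomes, 1 kb SNP spacing ---
    gene_sizes = np.maximum(1, rng.poisson(config.snps_per_gene, size=config.n_genes))
    causal_gene_idx = rng.choice(config.n_genes, size=config.causal_genes, replace=False)
    for gi in causal_gene_idx:
        gene_sizes[gi] = max(gene_sizes[gi], config.causal_snps_per_gene)

    genes: list[GeneRecord] = []
    snp_ids: list[str] = []
    chrom: list[str] = []
    pos: list[int] = []
    gene_of_snp: list[str | None] = []
    genes_per_chrom = max(1, int(np.ceil(config.n_genes / 22)))
    cursor: dict[str, int] = {}
    for gi, size in enumerate(gene_sizes):
        c = str(gi // genes_per_chrom + 1)
        start = cursor.get(c, 100_000) + 50_000
        end = start + 1000 * int(size) + 500
        cursor[c] = end
        gid = f"GENE{gi + 1:03d}"
        genes.append(GeneRecord(gid, c, start, end))
        for k in range(size):
            snp_ids.append(f"rs{gi + 1:03d}_{k + 1:02d}")
            chrom.append(c)
            pos.append(start + 1000 * k + 250)
            gene_of_snp.append(gid)
    # intergenic SNPs: past the last gene on chromosome 1
    inter_start = cursor.get("1", 100_000) + 200_000
    for k in range(config.n_intergenic_snps):
        snp_ids.append(f"rsINT_{k + 1:03d}")
        chrom.append("1")
        pos.append(inter_start + 2000 * k)
        gene_of_snp.append(None)
    m = len(snp_ids)

    # --- genotypes for the pool ---
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    calls = np.empty((n_pool, m), dtype=np.int8)
    j = 0
    for size in gene_sizes:
        calls[:, j:j + size] = _simulate_block(rng, n_pool, maf[j:j + size], config.ld_rho)
        j += size
    calls[:, j:] = _genotypes_from_latent(
        rng.standard_normal((n_pool, m - j)), maf[j:]
    )

    # --- truth ---
    truth = TruthTable()
    beta = np.zeros(m)
    for gi in causal_gene_idx:
        gid = f"GENE{gi + 1:03d}"
        truth.causal_gene_ids.add(gid)
        idx = [i for i, g in enumerate(gene_of_snp) if g == gid]
        for i in idx[: config.causal_snps_per_gene]:
            truth.causal_snp_ids.add(snp_ids[i])
            truth.snp_log_or[snp_ids[i]] = config.per_allele_log_or
            beta[i] = config.per_allele_log_or

    # --- phenotype: logistic liability ---
    gender = np.where(rng.random(n_pool) < 0.5, "male", "female")
    age = rng.uniform(25.0, 50.0, size=n_pool)
    bmi = rng.normal(24.0, 3.0, size=n_pool)
    genetic = calls @ beta
    eta = (
        logit(config.base_prevalence)
        - genetic.mean()
        + genetic
        + config.bmi_log_or * (bmi - bmi.mean())
    )
    affected = rng.random(n_pool) < expit(eta)

    # --- ascertain cases and match controls (gender equal, age within band) ---
    case_pool = np.flatnonzero(affected)
    if len(case_pool) < config.n_pairs:
        raise SimulationError(
            f"only {len(case_pool)} affected individuals for {config.n_pairs} pairs; "
            "increase pool_factor"
        )
    cases = rng.choice(case_pool, size=config.n_pairs, replace=False)
    unaffected = np.flatnonzero(~affected)
    used = np.zeros(n_pool, dtype=bool)
    controls = np.empty(config.n_pairs, dtype=np.int64)
    by_gender = {g: unaffected[gender[unaffected] == g] for g in ("male", "female")}
    for k, ci in enumerate(cases):
        cand = by_gender[gender[ci]]
        cand = cand[~used[cand]]
        cand = cand[np.abs(age[cand] - age[ci]) <= AGE_MATCH_YEARS]
        if len(cand) == 0:
            raise SimulationError(
                f"no unaffected control matches case {k} (gender={gender[ci]}, "
                f"age={age[ci]:.1f}); increase pool_factor"
            )
        best = cand[np.argmin(np.abs(age[cand] - age[ci]))]
        controls[k] = best
        used[best] = True

    keep = np.concatenate([cases, controls])
    sample_ids = [f"CASE{k + 1:04d}" for k in range(config.n_pairs)] + [
        f"CTRL{k + 1:04d}" for k in range(config.n_pairs)
    ]
    design = MatchedDesign(pd.DataFrame({
        "sample_id": sample_ids,
        "status": ["case"] * config.n_pairs + ["control"] * config.n_pairs,
        "pair_id": [f"P{k + 1:04d}" for k in range(config.n_pairs)] * 2,
        "bmi": np.round(bmi[keep], 2),
        "gender": gender[keep],
        "age": np.round(age[keep], 1),
    }))

    cohort_calls = calls[keep].copy()
    if config.missing_rate > 0:
        mask = rng.random(cohort_calls.shape) < config.missing_rate
        cohort_calls[mask] = MISSING

    # recode to the cohort's empirically minor allele so that the
    # frequency-forced PED coding round-trips exactly
    alleles = [("A", "G")] * m
    obs = cohort_calls != MISSING
    with np.errstate(invalid="ignore"):
        freq = np.where(obs, cohort_calls, 0).sum(0) / np.maximum(2.0 * obs.sum(0), 1)
    for j in np.flatnonzero(freq > 0.5):
        col = cohort_calls[:, j]
        col[col != MISSING] = 2 - col[col != MISSING]
        alleles[j] = ("G", "A")
        if snp_ids[j] in truth.snp_log_or:  # effect now refers to the new minor allele
            truth.snp_log_or[snp_ids[j]] *= -1.0

    dataset = GenotypeDataset(
        sample_ids=sample_ids,
        snp_ids=snp_ids,
        chromosome=np.array(chrom, dtype=object),
        position=np.array(pos, dtype=np.int64),
        alleles=alleles,
        calls=cohort_calls,
    )
    return dataset, design, genes, truth


def simulate_expression(
    design: MatchedDesign,
    genes: list[GeneRecord],
    truth: TruthTable,
    effect_sd_units: float = 2.0,
    seed: int = 0,
    noise_sd: float = 1.0,
    bmi_slope: float = 0.05,
) -> ExpressionMatrix:
    """One expression feature per gene over the design's samples.

    Each gene gets a baseline intensity (spread across genes, so sample
    profiles are rank-correlated as on a real array) plus i.i.d. Gaussian
    noise; planted genes shift cases by ``effect_sd_units`` noise
    standard deviations, up or down with equal probability per gene; BMI
    enters every feature as a linear nuisance slope (units per kg/m^2).
    """
    if design.table.empty:
        raise ValueError("design is empty")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if design.n_pairs < 2:
        raise ValueError("need at least 2 matched pairs for expression simulation")
    rng = np.random.default_rng(seed)
    t = design.table
    is_case = (t["status"] == "case").to_numpy()
    bmi = t["bmi"].to_numpy(float)
    n = len(t)
    baseline = rng.normal(10.0, 2.0, size=len(genes))
    values = baseline[:, None] + rng.normal(0.0, noise_sd, size=(len(genes), n))
    values += bmi_slope * (bmi - bmi.mean())
    for i, g in enumerate(genes):
        if g.gene_id in truth.causal_gene_ids:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            values[i, is_case] += sign * effect_sd_units * noise_sd
    return ExpressionMatrix(
        feature_ids=[g.gene_id for g in genes],
        sample_ids=list(t["sample_id"]),
        values=values,
    )
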