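"""Sample/SNP quality control and population-structure diagnostics.

QC mirrors a standard GWAS gate: sample call rate, SNP call rate, an
exact Hardy-Weinberg test with a Benjamini-Hochberg FDR cut, then a
minor-allele-frequency floor, applied in that order with MAF recomputed
after sample removal. Structure diagnostics are the genomic-control
inflation factor on 1-df trend statistics, EigenStrat-style genotype
PCA, and Mood's median test of principal components between groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2, chi2_contingency, fisher_exact

from .containers import MISSING, GenotypeDataset, QcReport
from .multitest import bh_fdr

CHI2_1DF_MEDIAN = float(chi2.ppf(0.5, df=1))  # 0.45494


@dataclass
class HweResult:
    snp_id: str
    n_hom_major: int
    n_het: int
    n_hom_minor: int
    p: float
    fdr_adjusted_p: float = float("nan")


@dataclass
class StratReport:
    """Genomic-control lambda, top principal components, per-PC median-test p."""

    lambda_vif: float
    components: np.ndarray      # (n_samples, k)
    eigenvalues: np.ndarray     # length k, non-increasing
    median_test_p: np.ndarray | None = None


def call_rates(dataset: GenotypeDataset) -> tuple[pd.Series, pd.Series]:
    """Per-sample and per-SNP fractions of non-missing calls."""
    if dataset.n_samples == 0 or dataset.n_snps == 0:
        raise ValueError("empty dataset")
    obs = dataset.observed()
    sample = pd.Series(obs.mean(axis=1), index=dataset.sample_ids, name="call_rate")
    snp = pd.Series(obs.mean(axis=0), index=dataset.snp_ids, name="call_rate")
    return sample, snp


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact Hardy-Weinberg test conditional on the allele counts.

    Enumerates every heterozygote count compatible with the observed
    allele counts and sums the conditional probabilities of all tables no
    more probable than the observed one (ties included, no mid-p).
    Monomorphic input gives p = 1.
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_major + n_het + n_hom_minor
    if n == 0:
        raise ValueError("no genotypes")
    n_minor = 2 * n_hom_minor + n_het
    n_minor = min(n_minor, 2 * n - n_minor)  # symmetry: work with the rarer allele
    if n_minor == 0:
        return 1.0
    hs = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_min = (n_minor - hs) // 2
    hom_maj = n - hs - hom_min
    ok = hom_maj >= 0
    hs, hom_min, hom_maj = hs[ok], hom_min[ok], hom_maj[ok]
    logp = (
        gammaln(n + 1) - gammaln(hom_maj + 1) - gammaln(hs + 1) - gammaln(hom_min + 1)
        + hs * np.log(2.0)
        + gammaln(n_minor + 1) + gammaln(2 * n - n_minor + 1) - gammaln(2 * n + 1)
    )
    probs = np.exp(logp)
    probs /= probs.sum()  # guard accumulated rounding
    p_obs = probs[hs == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_table(dataset: GenotypeDataset) -> list[HweResult]:
    """Exact HWE p for every SNP (pooled samples), with BH-adjusted p."""
    results = []
    for j, sid in enumerate(dataset.snp_ids):
        col = dataset.calls[:, j]
        col = col[col != MISSING]
        counts = [int((col == g).sum()) for g in (0, 1, 2)]
        p = hwe_exact_test(*counts) if len(col) else 1.0
        results.append(HweResult(sid, *counts, p))
    adj = bh_fdr(np.array([r.p for r in results]))
    for r, a in zip(results, adj):
        r.fdr_adjusted_p = float(a)
    return results


def qc_filter(
    dataset: GenotypeDataset,
    sample_gcr_min: float = 0.99,
    snp_gcr_min: float = 0.9,
    hwe_fdr_max: float = 1e-3,
    maf_min: float = 0.01,
) -> tuple[GenotypeDataset, QcReport]:
    """Apply the QC gate; returns the filtered dataset and its accounting.

    Stage order: sample call rate >= ``sample_gcr_min``; SNP call rate
    >= ``snp_gcr_min``; exact-HWE BH-FDR >= ``hwe_fdr_max`` (SNPs with
    adjusted p below the cut are removed); MAF >= ``maf_min`` recomputed
    on the retained samples.
    """
    report = QcReport(n_input_snps=dataset.n_snps)
    sample_cr, _ = call_rates(dataset)
    keep_samples = sample_cr.to_numpy() >= sample_gcr_min
    report.n_removed_samples = int((~keep_samples).sum())
    ds = dataset.subset(sample_mask=keep_samples)

    _, snp_cr = call_rates(ds)
    keep = snp_cr.to_numpy() >= snp_gcr_min
    report.n_removed_gcr = int((~keep).sum())
    ds = ds.subset(snp_mask=keep)

    hwe = hwe_table(ds)
    keep = np.array([r.fdr_adjusted_p >= hwe_fdr_max for r in hwe])
    report.n_removed_hwe = int((~keep).sum())
    ds = ds.subset(snp_mask=keep)

    maf = ds.maf()
    keep = np.nan_to_num(maf, nan=0.0) >= maf_min
    report.n_removed_maf = int((~keep).sum())
    ds = ds.subset(snp_mask=keep)

    report.validate()
    if ds.n_snps == 0:
        warnings.warn("QC removed every SNP", stacklevel=2)
    return ds, report


def genomic_control_lambda(trend_chisq) -> float:
    """Genomic-control inflation factor from 1-df trend statistics.

    lambda = median(statistic) / median of the chi-square(1) distribution.
    """
    stats = np.asarray(trend_chisq, dtype=float)
    stats = stats[np.isfinite(stats)]
    if stats.size == 0:
        raise ValueError("no statistics supplied")
    if np.any(stats < 0):
        raise ValueError("chi-square statistics must be non-negative")
    return float(np.median(stats) / CHI2_1DF_MEDIAN)


def pca_genotypes(dataset: GenotypeDataset, k: int = 10) -> StratReport:
    """EigenStrat-style genotype PCA.

    Monomorphic SNPs are excluded; missing calls are imputed to the SNP
    mean; each SNP column is centred at twice its allele frequency and
    scaled by sqrt(p(1-p)). Returns sample coordinates for the top-k axes
    and their (non-increasing) eigenvalues of the sample covariance.
    """
    if dataset.n_samples < 2:
        raise ValueError("PCA needs at least two samples")
    X = dataset.calls.astype(float)
    X[X == MISSING] = np.nan
    p_hat = np.nanmean(X, axis=0) / 2.0
    poly = (p_hat > 0) & (p_hat < 1)
    X = X[:, poly]
    p_hat = p_hat[poly]
    mu = 2.0 * p_hat
    X = np.where(np.isnan(X), mu, X)
    X = (X - mu) / np.sqrt(p_hat * (1.0 - p_hat))
    rank = min(X.shape)
    if k > rank:
        warnings.warn(f"k={k} exceeds rank {rank}; truncating", stacklevel=2)
        k = rank
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    eigenvalues = S[:k] ** 2 / (dataset.n_samples - 1)
    components = U[:, :k] * S[:k]
    return StratReport(lambda_vif=float("nan"), components=components,
                       eigenvalues=eigenvalues)


def median_test(values, groups) -> float:
    """Mood's median test between two groups.

    Dichotomizes at the pooled median (above vs not above) and tests the
    2x2 table with a continuity-free chi-square, falling back to Fisher's
    exact test when any expected cell count is below 5. Identical values
    in both groups give p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"median test needs exactly two groups, got {labels}")
    med = np.median(values)
    table = np.array([
        [(values[groups == g] > med).sum(), (values[groups == g] <= med).sum()]
        for g in labels
    ])
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        return 1.0  # all values on one side of the pooled median (e.g. constant)
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    if (expected < 5).any():
        return float(fisher_exact(table)[1])
    return float(chi2_contingency(table, correction=False)[1])


def stratification_report(
    dataset: GenotypeDataset,
    trend_chisq,
    status,
    k: int = 10,
) -> StratReport:
    """Combine lambda, genotype PCA, and per-PC case/control median tests."""
    rep = pca_genotypes(dataset, k=k)
    rep.lambda_vif = genomic_control_lambda(trend_chisq)
    rep.median_test_p = np.array([
        median_test(rep.components[:, j], status) for j in range(rep.components.shape[1])
    ])
    return rep
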