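"""Gene-based association scan: truncated-product combination of SNP
p-values, closed-form independence null, matched-pair permutation
empirical p-values, and the two-step FDR selection gate.

The gene statistic is W = prod of SNP p-values <= tau (W = 1 when none
qualify; the boundary p = tau is included). Under L independent uniform
p-values the null CDF has a closed form, evaluated here in log space.
Because LD makes intragenic p-values dependent, significance is
validated by permuting disease status within matched pairs, which in
the pair-difference parameterisation is a per-pair sign flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .association import (
    CLR_MODELS,
    _model_parts,
    _wald,
    fit_pair_logit,
    pair_difference_design,
)
from .containers import GeneRecord, GenotypeDataset, MatchedDesign
from .multitest import bh_fdr

__all__ = [
    "GeneAssignment", "assign_snps_to_genes", "tpm_statistic",
    "tpm_analytic_p", "permutation_scan", "bh_fdr", "gene_scan_table",
    "two_step_select", "run_gbas",
]

DEFAULT_TAU = 0.05


@dataclass
class GeneAssignment:
    """SNP -> gene map (each SNP to at most one gene) with partition counts."""

    snp_to_gene: dict[str, str | None]
    gene_to_snps: dict[str, list[str]]
    assignment_seed: int
    genes: list[GeneRecord] = field(default_factory=list)

    @property
    def n_intragenic(self) -> int:
        return sum(1 for g in self.snp_to_gene.values() if g is not None)

    @property
    def n_intergenic(self) -> int:
        return sum(1 for g in self.snp_to_gene.values() if g is None)

    @property
    def n_genes(self) -> int:
        return sum(1 for s in self.gene_to_snps.values() if s)

    def summary(self) -> dict[str, float]:
        """Partition counts plus SNPs-per-gene distribution summaries."""
        sizes = np.array([len(s) for s in self.gene_to_snps.values() if s])
        return {
            "n_intragenic": self.n_intragenic,
            "n_intergenic": self.n_intergenic,
            "n_genes": self.n_genes,
            "mean_snps_per_gene": float(sizes.mean()) if sizes.size else float("nan"),
            "median_snps_per_gene": float(np.median(sizes)) if sizes.size else float("nan"),
            "pct_single_snp_genes": (
                100.0 * float((sizes == 1).mean()) if sizes.size else float("nan")
            ),
        }


def assign_snps_to_genes(
    dataset: GenotypeDataset, genes: list[GeneRecord], seed: int = 0
) -> GeneAssignment:
    """Assign each SNP to the gene whose body contains it (1-based inclusive).

    A SNP overlapping several genes is assigned to one of them uniformly
    at random using ``seed``; a SNP inside no gene is intergenic.
    """
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    snp_to_gene: dict[str, str | None] = {}
    gene_to_snps: dict[str, list[str]] = {g.gene_id: [] for g in genes}
    for sid, chrom, pos in zip(dataset.snp_ids, dataset.chromosome, dataset.position):
        hits = [g for g in by_chrom.get(str(chrom), []) if g.start <= pos <= g.end]
        if not hits:
            snp_to_gene[sid] = None
        else:
            chosen = hits[0] if len(hits) == 1 else hits[rng.integers(len(hits))]
            snp_to_gene[sid] = chosen.gene_id
            gene_to_snps[chosen.gene_id].append(sid)
    return GeneAssignment(snp_to_gene, gene_to_snps, seed, genes)


def _check_pvalues(p: np.ndarray) -> None:
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")


def tpm_statistic(pvalues, tau: float = DEFAULT_TAU) -> float:
    """Truncated product W = prod of p <= tau (1.0 when none qualify)."""
    p = np.asarray(pvalues, dtype=float)
    _check_pvalues(p)
    sel = p[p <= tau]
    return float(np.prod(sel)) if sel.size else 1.0


def _log_tpm(pvalues, tau: float) -> float:
    """log W, safe against underflow of the raw product."""
    p = np.asarray(pvalues, dtype=float)
    _check_pvalues(p)
    sel = p[p <= tau]
    return float(np.log(sel).sum()) if sel.size else 0.0


def tpm_analytic_p(W: float, L: int, tau: float = DEFAULT_TAU,
                   log_w: float | None = None) -> float:
    """P(W' <= W) for the truncated product of L independent uniforms.

    Sums over k (the number of p-values falling below tau): a binomial
    weight times either the full tau^k mass (when W > tau^k) or the
    conditional CDF of a product of k truncated uniforms. Accumulated in
    log space so large L and tiny W are safe.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    lw = float(np.log(W)) if log_w is None else float(log_w)
    if lw > 0 or not np.isfinite(lw):
        raise ValueError("W must lie in (0, 1]")
    if lw == 0.0:
        return 1.0
    ltau, l1mtau = np.log(tau), np.log1p(-tau)
    terms = []
    for k in range(1, L + 1):
        lbinom = gammaln(L + 1) - gammaln(k + 1) - gammaln(L - k + 1)
        prefix = lbinom + (L - k) * l1mtau
        if lw > k * ltau:                      # W above the k-truncation mass
            terms.append(prefix + k * ltau)
        else:
            A = k * ltau - lw                  # >= 0
            s = np.arange(k)
            with np.errstate(divide="ignore"):
                inner = logsumexp(np.where(s > 0, s * np.log(A) if A > 0 else -np.inf, 0.0)
                                  - gammaln(s + 1))
            terms.append(prefix + lw + inner)
    return float(min(1.0, np.exp(logsumexp(terms))))


def _snp_design_cache(dataset, design, snp_ids, models):
    """Pre-build pair-difference designs for the scanned SNPs/models."""
    design = design.aligned_to(dataset)
    case_idx, control_idx = design.pair_arrays(dataset)
    bmi = np.full(dataset.n_samples, np.nan)
    for sid, b in zip(design.table["sample_id"], design.table["bmi"]):
        bmi[dataset.sample_ids.index(sid)] = b
    bmi_diff = bmi[case_idx] - bmi[control_idx]
    cache = {}
    for sid in snp_ids:
        col = dataset.calls[:, dataset.snp_index(sid)]
        for model in models:
            coding, adjusted = _model_parts(model)
            X, geno_idx, pair_mask = pair_difference_design(
                col, case_idx, control_idx, coding, bmi_diff if adjusted else None
            )
            cache[(sid, model)] = (X, geno_idx, pair_mask)
    return cache, len(case_idx)


def _sign_matrix(n_pairs: int, B: int, seed: int, exact: bool) -> np.ndarray:
    if exact:
        if n_pairs > 20:
            raise ValueError("exact enumeration limited to <= 20 pairs")
        grid = np.arange(2 ** n_pairs)[:, None] >> np.arange(n_pairs)[None, :]
        return np.where(grid & 1, -1.0, 1.0)
    rng = np.random.default_rng(seed)
    return np.where(rng.random((B, n_pairs)) < 0.5, -1.0, 1.0)


def permutation_scan(
    dataset: GenotypeDataset,
    design: MatchedDesign,
    assignment: GeneAssignment,
    models: tuple[str, ...] = CLR_MODELS,
    B: int = 10_000,
    tau: float = DEFAULT_TAU,
    seed: int = 0,
    genes: list[str] | None = None,
    exact: bool = False,
) -> pd.DataFrame:
    """Empirical gene p-values from within-pair status swaps.

    Each replicate flips case/control within every pair independently
    with probability 1/2 (covariates travel with the individual, so the
    pair-difference row just changes sign); the SNP fits and the
    truncated product are recomputed per replicate, and
    empirical p = (1 + #{W_perm <= W_obs}) / (B + 1). ``exact=True``
    enumerates all 2^n sign vectors for small cohorts instead.

    SNPs whose observed fit is non-estimable or non-converged are
    excluded from observed and permuted products alike; a replicate in
    which a remaining SNP fit fails contributes no p for that SNP.
    """
    if B < 1 and not exact:
        raise ValueError("B must be >= 1")
    gene_list = genes if genes is not None else [
        g for g, s in assignment.gene_to_snps.items() if s
    ]
    snp_ids = sorted({s for g in gene_list for s in assignment.gene_to_snps[g]})
    cache, n_pairs = _snp_design_cache(dataset, design, snp_ids, models)
    signs = _sign_matrix(n_pairs, B, seed, exact)
    B_eff = signs.shape[0]

    # per (snp, model): observed log p and per-replicate log p
    obs_logp: dict[tuple[str, str], float] = {}
    perm_logp: dict[tuple[str, str], np.ndarray] = {}
    log_tau = np.log(tau)
    for key, (X, geno_idx, pair_mask) in cache.items():
        if X is None:
            continue
        beta, cov, conv = fit_pair_logit(X)
        if not conv[0]:
            continue
        stat, _, p = _wald(beta, cov, geno_idx)
        obs_logp[key] = float(np.log(p[0]))
        beta_b, cov_b, conv_b = fit_pair_logit(X, signs[:, pair_mask])
        _, _, p_b = _wald(beta_b, cov_b, geno_idx)
        lp = np.log(np.clip(p_b, 1e-300, 1.0))
        lp[~conv_b] = np.inf                 # failed replicate fit: no p
        perm_logp[key] = lp

    rows = []
    for gid in gene_list:
        for model in models:
            keys = [(s, model) for s in assignment.gene_to_snps[gid] if (s, model) in obs_logp]
            if not keys:
                continue  # gene has no estimable SNP under this model
            olp = np.array([obs_logp[k] for k in keys])
            log_w_obs = olp[olp <= log_tau].sum()
            P = np.stack([perm_logp[k] for k in keys])      # (L, B)
            contrib = np.where(P <= log_tau, P, 0.0)
            log_w_perm = contrib.sum(axis=0)
            hits = int((log_w_perm <= log_w_obs + 1e-12).sum())
            rows.append(dict(
                gene_id=gid, model=model, L=len(keys),
                W=float(np.exp(log_w_obs)), log_w=log_w_obs,
                p_empirical=(1 + hits) / (B_eff + 1),
            ))
    return pd.DataFrame(rows)


def gene_scan_table(
    sbas: pd.DataFrame,
    assignment: GeneAssignment,
    tau: float = DEFAULT_TAU,
) -> pd.DataFrame:
    """Step-1 table: per (gene, model) truncated product and analytic p.

    Only converged, estimable SNP fits contribute; L counts the
    combined SNPs. fdr_step1 is BH-adjusted per model across genes.
    """
    usable = sbas[sbas["converged"] & sbas["estimable"] & sbas["p"].notna()]
    rows = []
    for (gid, snps) in assignment.gene_to_snps.items():
        if not snps:
            continue
        sub = usable[usable["snp_id"].isin(snps)]
        for model, grp in sub.groupby("model"):
            p = grp["p"].to_numpy()
            log_w = _log_tpm(p, tau)
            rows.append(dict(
                gene_id=gid, model=model, L=len(p),
                W=float(np.exp(log_w)), log_w=log_w,
                p_analytic=tpm_analytic_p(np.exp(log_w), len(p), tau, log_w=log_w),
            ))
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["fdr_step1"] = np.nan
    for model, grp in table.groupby("model"):
        table.loc[grp.index, "fdr_step1"] = bh_fdr(grp["p_analytic"].to_numpy())
    return table


def two_step_select(
    step1: pd.DataFrame,
    step2_empirical: pd.DataFrame,
    models: tuple[str, ...] = CLR_MODELS,
    step1_fdr_max: float = 1e-3,
    step2_fdr_max: float = 5e-2,
) -> pd.DataFrame:
    """Apply the two-step gate and report per-gene significance patterns.

    Step 1 prioritizes a gene when its analytic-p BH-FDR is below
    ``step1_fdr_max`` in at least one model. Step 2 pools the empirical
    p-values of prioritized genes across the four models into one BH-FDR
    and validates a gene when any pooled entry falls below
    ``step2_fdr_max``. The pattern records which models met step 1.
    """
    if step1.empty:
        return pd.DataFrame(columns=["gene_id", "pattern", "identified"])
    pri = step1[step1["fdr_step1"] < step1_fdr_max]
    prioritized = sorted(pri["gene_id"].unique())
    patterns = {}
    for gid in prioritized:
        hit = set(pri.loc[pri["gene_id"] == gid, "model"])
        patterns[gid] = "".join("1" if m in hit else "0" for m in models)
    if not prioritized:
        return pd.DataFrame(columns=["gene_id", "model", "p_empirical",
                                     "fdr_joint", "pattern", "identified"])
    pool = step2_empirical[step2_empirical["gene_id"].isin(prioritized)].copy()
    pool = pool.reset_index(drop=True)
    pool["fdr_joint"] = bh_fdr(pool["p_empirical"].to_numpy())
    validated = set(pool.loc[pool["fdr_joint"] < step2_fdr_max, "gene_id"])
    pool["pattern"] = pool["gene_id"].map(patterns)
    pool["identified"] = pool["gene_id"].isin(validated)
    return pool


def run_gbas(
    dataset: GenotypeDataset,
    design: MatchedDesign,
    genes: list[GeneRecord],
    models: tuple[str, ...] = CLR_MODELS,
    tau: float = DEFAULT_TAU,
    B: int = 10_000,
    assignment_seed: int = 0,
    permutation_seed: int = 1,
    step1_fdr_max: float = 1e-3,
    step2_fdr_max: float = 5e-2,
    sbas: pd.DataFrame | None = None,
):
    """Full gene-based scan: assignment, step-1 gate, permutations, selection.

    Returns (assignment, step1_table, selection_table). Permutations run
    only for the genes prioritized at step 1.
    """
    from .association import run_sbas
    assignment = assign_snps_to_genes(dataset, genes, seed=assignment_seed)
    if sbas is None:
        sbas = run_sbas(dataset, design, models)
    step1 = gene_scan_table(sbas, assignment, tau)
    if step1.empty:
        return assignment, step1, pd.DataFrame(columns=["gene_id", "identified"])
    prioritized = sorted(step1.loc[step1["fdr_step1"] < step1_fdr_max, "gene_id"].unique())
    if not prioritized:
        return assignment, step1, pd.DataFrame(columns=["gene_id", "identified"])
    empirical = permutation_scan(
        dataset, design, assignment, models=models, B=B, tau=tau,
        seed=permutation_seed, genes=prioritized,
    )
    selection = two_step_select(step1, empirical, models, step1_fdr_max, step2_fdr_max)
    return assignment, step1, selection
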