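"""Post-scan validation: risk-genotype labelling, extreme-discordant-pair
selection, quantile normalization, ANCOVA/ANOVA differential expression,
and clustering/PCA summaries of expression profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import kendalltau, rankdata, t as t_dist

from .containers import MISSING, ExpressionMatrix, GenotypeDataset, MatchedDesign


@dataclass(frozen=True)
class GenotypeRiskLabel:
    snp_id: str
    genotype: int            # class 0/1/2
    label: str               # risky | protective | neutral
    case_freq: float
    control_freq: float


@dataclass
class DiffExprResult:
    feature_id: str
    beta_group: float
    se: float
    p_group: float
    method: str              # ANCOVA | ANOVA


@dataclass
class ClusterSummary:
    sample_ids: list[str]
    cluster: np.ndarray              # two-cluster membership (1/2)
    misclassified: int               # vs known groups, min over label swap
    variance_fractions: np.ndarray   # PCA variance explained per component
    linkage_matrix: np.ndarray
    newick: str


def label_genotype_risk(
    dataset: GenotypeDataset,
    design: MatchedDesign,
    snp_ids: list[str],
) -> list[GenotypeRiskLabel]:
    """Label each (SNP, genotype class) by its case/control frequency gap.

    A class is risky when its frequency among cases exceeds that among
    controls, protective when lower, neutral when equal. Frequencies are
    over non-missing calls within each group.
    """
    if not snp_ids:
        raise ValueError("no SNPs supplied")
    design = design.aligned_to(dataset)
    pos = {s: i for i, s in enumerate(dataset.sample_ids)}
    case_rows = [pos[s] for s, st in zip(design.table["sample_id"], design.table["status"])
                 if st == "case"]
    control_rows = [pos[s] for s, st in zip(design.table["sample_id"], design.table["status"])
                    if st == "control"]
    labels = []
    for sid in snp_ids:
        col = dataset.calls[:, dataset.snp_index(sid)]
        ca, co = col[case_rows], col[control_rows]
        ca, co = ca[ca != MISSING], co[co != MISSING]
        for g in (0, 1, 2):
            fa = float((ca == g).mean()) if len(ca) else np.nan
            fo = float((co == g).mean()) if len(co) else np.nan
            if np.isnan(fa) or np.isnan(fo) or fa == fo:
                lab = "neutral"
            else:
                lab = "risky" if fa > fo else "protective"
            labels.append(GenotypeRiskLabel(sid, g, lab, fa, fo))
    return labels


def subject_risk_scores(
    labels: list[GenotypeRiskLabel],
    dataset: GenotypeDataset,
    design: MatchedDesign,
    gene_to_snps: dict[str, list[str]],
    target_label: str,
) -> pd.Series:
    """Per-subject mean (over genes) proportion of target-labelled genotypes.

    Within a gene, the proportion counts the subject's non-missing,
    non-neutral genotype calls: neutral classes enter neither numerator
    nor denominator. A gene with no countable call contributes 0.
    """
    lab = {(l.snp_id, l.genotype): l.label for l in labels}
    design = design.aligned_to(dataset)
    pos = {s: i for i, s in enumerate(dataset.sample_ids)}
    scores = {}
    for sample in design.table["sample_id"]:
        row = dataset.calls[pos[sample]]
        per_gene = []
        for snps in gene_to_snps.values():
            hit = tot = 0
            for sid in snps:
                g = int(row[dataset.snp_index(sid)])
                if g == MISSING:
                    continue
                l = lab.get((sid, g))
                if l is None or l == "neutral":
                    continue
                tot += 1
                hit += l == target_label
            per_gene.append(hit / tot if tot else 0.0)
        scores[sample] = float(np.mean(per_gene)) if per_gene else 0.0
    return pd.Series(scores)


def select_extreme_pairs(
    labels: list[GenotypeRiskLabel],
    dataset: GenotypeDataset,
    design: MatchedDesign,
    gene_to_snps: dict[str, list[str]],
    k: int = 12,
) -> tuple[list[str], list[str]]:
    """Pick the k cases richest in risky genotypes and the k controls
    richest in protective genotypes. Ties break by sample id, so the
    selection is invariant to input order."""
    design = design.aligned_to(dataset)
    design_t = design.table
    cases = list(design_t.loc[design_t["status"] == "case", "sample_id"])
    controls = list(design_t.loc[design_t["status"] == "control", "sample_id"])
    if k > len(cases) or k > len(controls):
        raise ValueError(f"k={k} exceeds group size ({len(cases)} cases, "
                         f"{len(controls)} controls)")
    risky = subject_risk_scores(labels, dataset, design, gene_to_snps, "risky")
    prot = subject_risk_scores(labels, dataset, design, gene_to_snps, "protective")
    if (risky[cases] == 0).all() and (prot[controls] == 0).all():
        warnings.warn("all risk scores are zero; selection is tie-break order",
                      stacklevel=2)

    def top(ids, s):
        return sorted(ids, key=lambda x: (-s[x], x))[:k]

    return top(cases, risky), top(controls, prot)


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Force identical value distributions across samples.

    Each column's sorted values are replaced by the across-column mean of
    order statistics; within-column ranks are preserved and ties receive
    the average of their target values. Idempotent; a single column is
    returned unchanged.
    """
    X = expr.values
    if np.isnan(X).any():
        raise ValueError("expression matrix contains missing values")
    if X.shape[1] < 2:
        return ExpressionMatrix(list(expr.feature_ids), list(expr.sample_ids), X.copy())
    n = X.shape[0]
    mean_sorted = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X, dtype=float)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(X.shape[1]):
        ranks = rankdata(X[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, mean_sorted)
    return ExpressionMatrix(list(expr.feature_ids), list(expr.sample_ids), out)


def _ols_group_test(y, group, covariate=None):
    """Closed-form OLS of y ~ 1 + group (+ covariate); t-test on group."""
    cols = [np.ones_like(y), group]
    if covariate is not None:
        if np.ptp(covariate) == 0:
            warnings.warn("constant covariate dropped from ANCOVA", stacklevel=3)
        else:
            cols.append(covariate)
    X = np.column_stack(cols)
    df = len(y) - X.shape[1]
    if df < 1:
        return np.nan, np.nan, np.nan
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    s2 = resid @ resid / df
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(cov[1, 1])
    if se == 0:
        return float(beta[1]), 0.0, 1.0
    tt = beta[1] / se
    return float(beta[1]), float(se), float(2 * t_dist.sf(abs(tt), df))


def differential_expression(
    expr: ExpressionMatrix,
    groups,
    bmi=None,
) -> list[DiffExprResult]:
    """Per-feature group test: ANCOVA (``value ~ group + bmi``) when a BMI
    covariate is supplied, else one-way ANOVA (``value ~ group``), which
    for two groups is the pooled-variance t-test."""
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    g = (groups == levels[-1]).astype(float)
    if min(g.sum(), (1 - g).sum()) < 2:
        raise ValueError("each group needs at least two samples")
    method = "ANOVA" if bmi is None else "ANCOVA"
    cov = None if bmi is None else np.asarray(bmi, dtype=float)
    results = []
    for i, fid in enumerate(expr.feature_ids):
        b, se, p = _ols_group_test(expr.values[i], g, cov)
        results.append(DiffExprResult(fid, b, se, p, method))
    return results


def kendall_dissimilarity(x, y) -> float:
    """d = (1 - Kendall tau_b) / 2, mapping agreement to [0, 1]."""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant profile: Kendall dissimilarity undefined")
    tau = kendalltau(x, y).statistic
    return float((1.0 - tau) / 2.0)


def _linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    n = len(leaf_names)

    def node(i):
        if i < n:
            return leaf_names[i]
        a, b, dist, _ = Z[i - n]
        return f"({node(int(a))},{node(int(b))}):{dist:.4f}"

    a, b, dist, _ = Z[-1]
    return f"({node(int(a))},{node(int(b))});"


def cluster_and_summarize(expr: ExpressionMatrix, groups) -> ClusterSummary:
    """Average-linkage clustering under Kendall's dissimilarity plus PCA.

    The dendrogram is cut at the last merge into two clusters; the
    misclassification count against the known groups is minimized over
    the label swap. PCA runs on feature-centred data; variance fractions
    sum to 1 over all components.
    """
    X = expr.values
    n = X.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples to cluster")
    const = np.ptp(X, axis=0) == 0
    if const.any():
        bad = [expr.sample_ids[j] for j in np.flatnonzero(const)]
        raise ValueError(f"constant expression profile for samples {bad}")
    cond = []
    for i in range(n):
        for j in range(i + 1, n):
            cond.append(kendall_dissimilarity(X[:, i], X[:, j]))
    Z = linkage(np.asarray(cond), method="average")
    cluster = fcluster(Z, t=2, criterion="maxclust")
    groups = np.asarray(groups)
    levels = np.unique(groups)
    gnum = (groups == levels[-1]).astype(int) + 1
    mis = min(int((cluster != gnum).sum()), int((cluster != (3 - gnum)).sum()))
    centered = X - X.mean(axis=1, keepdims=True)
    s = np.linalg.svd(centered.T, compute_uv=False)
    var = s**2
    return ClusterSummary(
        sample_ids=list(expr.sample_ids),
        cluster=cluster,
        misclassified=mis,
        variance_fractions=var / var.sum(),
        linkage_matrix=Z,
        newick=_linkage_to_newick(Z, list(expr.sample_ids)),
    )
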