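"""Gene-centric cis-eQTL scan and direction-of-effect classification.

For each gene with an expression feature, SNPs inside a 2-Mb window
around the gene body (gene +/- 1 Mb by default; transcription start
+/- 1 Mb behind a flag) are correlated with expression via Spearman's
rank correlation on the continuous minor-allele coding. Records passing
the significance cut are crossed with the disease-association log-odds
of the minor allele to yield the four direction labels: risky or
protective allele, up- or down-regulated expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.stats import spearmanr

from .containers import MISSING, ExpressionMatrix, GeneRecord, GenotypeDataset

EXACT_PERM_MAX_N = 9  # exact Spearman permutation null up to this n


@dataclass
class EqtlRecord:
    gene_id: str
    snp_id: str
    rho: float
    p_corr: float
    window_start: int
    window_end: int
    clr_beta: float = float("nan")
    direction: str = "unclassified"


def cis_window(gene: GeneRecord, flank: int = 1_000_000) -> tuple[int, int]:
    """[start - flank, end + flank], clipped at coordinate 1."""
    return max(1, gene.start - flank), gene.end + flank


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rho (small n).

    Enumerates all pairings of the rank vectors; ties are handled by
    correlating average ranks (tau-b style Pearson on ranks).
    """
    from scipy.stats import rankdata

    rx = rankdata(x)
    ry = rankdata(y)
    n = len(rx)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    perms = np.array(list(permutations(range(n))))
    rhos = (ry_c[perms] @ rx_c) / denom
    return float((np.abs(rhos) >= abs(rho_obs) - 1e-12).mean())


def spearman_test(genotype: np.ndarray, expression: np.ndarray) -> tuple[float, float]:
    """Spearman rho and p; exact permutation p below n=10, else the
    t approximation."""
    n = len(genotype)
    rho, p = spearmanr(genotype, expression)
    if np.isnan(rho):
        return float("nan"), float("nan")
    if n < 10:
        p = _spearman_exact_p(genotype, expression, rho)
    return float(rho), float(p)


def cis_eqtl_scan(
    expr: ExpressionMatrix,
    dataset: GenotypeDataset,
    genes: list[GeneRecord],
    alpha: float = 0.05,
    flank: int = 1_000_000,
    anchor: str = "body",
    clr_beta: dict[str, float] | None = None,
) -> list[EqtlRecord]:
    """Scan SNPs in cis windows for expression correlation.

    Only records with p < ``alpha`` are retained. Expression samples must
    be a subset of genotyped samples; monomorphic SNPs within the tested
    samples and constant expression features are skipped. When
    ``clr_beta`` (per-SNP trend log-odds for the minor allele) is given,
    each record also receives its direction label.
    """
    if anchor not in ("body", "tss"):
        raise ValueError("anchor must be 'body' or 'tss'")
    missing = [s for s in expr.sample_ids if s not in dataset.sample_ids]
    if missing:
        raise ValueError(f"expression samples not genotyped: {missing[:5]}")
    rows = [dataset.sample_ids.index(s) for s in expr.sample_ids]
    feat = {f: i for i, f in enumerate(expr.feature_ids)}
    records: list[EqtlRecord] = []
    for gene in genes:
        if gene.gene_id not in feat:
            continue
        e = expr.values[feat[gene.gene_id]]
        if np.ptp(e) == 0:
            continue  # constant expression: skipped
        if anchor == "body":
            lo, hi = cis_window(gene, flank)
        else:
            lo, hi = max(1, gene.start - flank), gene.start + flank
        in_win = (
            (dataset.chromosome == gene.chromosome)
            & (dataset.position >= lo)
            & (dataset.position <= hi)
        )
        for j in np.flatnonzero(in_win):
            g = dataset.calls[rows, j].astype(float)
            ok = g != MISSING
            if ok.sum() < 3 or np.ptp(g[ok]) == 0:
                continue  # monomorphic or too few calls
            rho, p = spearman_test(g[ok], e[ok])
            if np.isnan(p) or p >= alpha:
                continue
            rec = EqtlRecord(gene.gene_id, dataset.snp_ids[j], rho, p, lo, hi)
            if clr_beta is not None and dataset.snp_ids[j] in clr_beta:
                rec.clr_beta = clr_beta[dataset.snp_ids[j]]
                rec.direction = classify_direction(rec, rec.clr_beta)
            records.append(rec)
    return records


def classify_direction(record: EqtlRecord, clr_beta_for_minor_allele: float) -> str:
    """Cross the disease-association sign with the regulation sign.

    The minor allele is risky when its trend log-odds is positive,
    protective when negative; expression is up-regulated when rho > 0.
    A zero (or non-finite) component leaves the record unclassified.
    """
    beta, rho = clr_beta_for_minor_allele, record.rho
    if not np.isfinite(beta) or not np.isfinite(rho) or beta == 0 or rho == 0:
        return "unclassified"
    return ("r" if beta > 0 else "p") + "/" + ("u" if rho > 0 else "d")
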