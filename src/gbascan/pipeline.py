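"""Pipeline configuration and the end-to-end demo orchestration."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .association import CLR_MODELS, run_sbas
from .containers import QcReport
from .eqtl import cis_eqtl_scan
from .genescan import run_gbas
from .qc import qc_filter, stratification_report
from .simulate import SimConfig, simulate_cohort, simulate_expression
from .validation import (
    cluster_and_summarize,
    differential_expression,
    label_genotype_risk,
    quantile_normalize,
    select_extreme_pairs,
)

log = logging.getLogger("gbascan")


@dataclass
class PipelineConfig:
    """Thresholds, permutation depth and seeds for a full run."""

    out_dir: str = "results/run"
    sample_gcr: float = 0.99
    snp_gcr: float = 0.9
    hwe_fdr: float = 1e-3
    maf: float = 0.01
    tau: float = 0.05
    step1_fdr: float = 1e-3
    step2_fdr: float = 0.05
    eqtl_alpha: float = 0.05
    B: int = 10_000
    n_extreme_pairs: int = 12
    simulation_seed: int = 0
    assignment_seed: int = 1
    permutation_seed: int = 2
    sim: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("sample_gcr", "snp_gcr", "hwe_fdr", "maf", "tau",
                     "step1_fdr", "step2_fdr", "eqtl_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0,1), got {v}")
        if self.B < 1:
            raise ValueError("B must be >= 1")


def run_pipeline(config: PipelineConfig) -> dict:
    """simulate -> qc -> strat -> sbas -> gbas -> select-pairs -> diffexpr -> eqtl.

    Writes every stage's TSV under ``config.out_dir`` and returns the
    in-memory artifacts. Rerunning with the same config reproduces
    identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = SimConfig(**{"seed": config.simulation_seed, **config.sim})
    dataset, design, genes, truth = simulate_cohort(sim_cfg)
    io.write_genotypes(dataset, out / "cohort.ped", out / "cohort.map", design)
    io.write_design(design, out / "design.tsv")
    io.write_gene_table(genes, out / "genes.tsv")
    log.info("simulate: n_pairs=%d n_snps=%d causal_genes=%d",
             design.n_pairs, dataset.n_snps, len(truth.causal_gene_ids))

    clean, report = qc_filter(dataset, config.sample_gcr, config.snp_gcr,
                              config.hwe_fdr, config.maf)
    report.validate()
    log.info("qc: input=%d removed_gcr=%d removed_hwe=%d removed_maf=%d retained=%d",
             report.n_input_snps, report.n_removed_gcr, report.n_removed_hwe,
             report.n_removed_maf, report.n_retained)
    pd.DataFrame([asdict(report) | {"n_retained": report.n_retained}]).to_csv(
        out / "qc_report.tsv", sep="\t", index=False)

    design = design.aligned_to(clean)
    in_design = np.isin(np.asarray(clean.sample_ids), design.table["sample_id"])
    clean = clean.subset(sample_mask=in_design)  # drop pair-broken samples
    sbas = run_sbas(clean, design, CLR_MODELS)
    sbas.to_csv(out / "sbas.tsv", sep="\t", index=False)

    trend = sbas.loc[(sbas["model"] == "CLR_C") & sbas["converged"], "wald"].dropna()
    status = [("case" if s == "case" else "control") for s in design.table["status"]]
    strat = stratification_report(clean, trend, np.asarray(status), k=5)
    log.info("strat: lambda=%.4f", strat.lambda_vif)
    pd.DataFrame({
        "component": np.arange(1, len(strat.eigenvalues) + 1),
        "eigenvalue": strat.eigenvalues,
        "median_test_p": strat.median_test_p,
    }).to_csv(out / "strat.tsv", sep="\t", index=False)

    assignment, step1, selection = run_gbas(
        clean, design, genes, tau=config.tau, B=config.B,
        assignment_seed=config.assignment_seed,
        permutation_seed=config.permutation_seed,
        step1_fdr_max=config.step1_fdr, step2_fdr_max=config.step2_fdr,
        sbas=sbas,
    )
    s = assignment.summary()
    if s["n_intragenic"] + s["n_intergenic"] != clean.n_snps:
        raise RuntimeError("assignment partition does not conserve SNP count")
    log.info("assignment: intragenic=%d intergenic=%d total=%d conserved=true",
             s["n_intragenic"], s["n_intergenic"], clean.n_snps)
    step1.to_csv(out / "gbas_step1.tsv", sep="\t", index=False)
    selection.to_csv(out / "gbas_selected.tsv", sep="\t", index=False)
    identified = sorted(set(selection.loc[selection.get("identified", pd.Series(dtype=bool)) == True, "gene_id"])) if not selection.empty else []
    log.info("gbas: prioritized=%d identified=%s",
             step1["gene_id"].nunique() if not step1.empty else 0, identified)

    results = dict(dataset=clean, design=design, genes=genes, truth=truth,
                   report=report, sbas=sbas, strat=strat, assignment=assignment,
                   step1=step1, selection=selection, identified=identified)
    if not identified:
        log.info("no genes identified; downstream stages skipped")
        return results

    gene_to_snps = {g: assignment.gene_to_snps[g] for g in identified}
    snps = [s for v in gene_to_snps.values() for s in v]
    labels = label_genotype_risk(clean, design, snps)
    k = min(config.n_extreme_pairs, design.n_pairs)
    top_cases, top_controls = select_extreme_pairs(labels, clean, design, gene_to_snps, k)
    sub_design = design.table[design.table["sample_id"].isin(top_cases + top_controls)]
    from .containers import MatchedDesign
    pd.DataFrame({"sample_id": top_cases + top_controls,
                  "group": ["case"] * k + ["control"] * k}).to_csv(
        out / "extreme_pairs.tsv", sep="\t", index=False)

    sel = design.table[design.table["sample_id"].isin(top_cases + top_controls)].reset_index(drop=True)
    expr = simulate_expression(
        MatchedDesign(_repair_pairs(sel)), genes, truth,
        seed=config.simulation_seed + 7,
    )
    expr = quantile_normalize(expr)
    io.write_expression(expr, out / "expression.tsv")
    groups = ["case" if s in top_cases else "control" for s in expr.sample_ids]
    bmi = [float(design.table.set_index("sample_id").loc[s, "bmi"]) for s in expr.sample_ids]
    de = differential_expression(expr, groups, bmi)
    de_table = pd.DataFrame([asdict(r) for r in de])
    de_table.to_csv(out / "diffexpr.tsv", sep="\t", index=False)
    hits = de_table.loc[de_table["p_group"] < 0.05, "feature_id"].tolist()
    log.info("diffexpr: %d/%d features at p<0.05", len(hits), len(de_table))

    de_genes = [g for g in genes if g.gene_id in hits]
    if len(hits) >= 2:
        summary = cluster_and_summarize(
            _subset_expr(expr, hits), groups)
        (out / "cluster.nwk").write_text(summary.newick + "\n")
        log.info("cluster: misclassified=%d top2_var=%.3f", summary.misclassified,
                 summary.variance_fractions[:2].sum())
        results["cluster"] = summary
    beta_map = dict(
        sbas.loc[(sbas["model"] == "CLR_C") & sbas["converged"], ["snp_id", "beta1"]]
        .itertuples(index=False))
    eqtl = cis_eqtl_scan(expr, clean, de_genes, alpha=config.eqtl_alpha,
                         clr_beta=beta_map)
    pd.DataFrame([asdict(r) for r in eqtl]).to_csv(out / "eqtl.tsv", sep="\t", index=False)
    log.info("eqtl: %d records below alpha", len(eqtl))
    results.update(expr=expr, diffexpr=de_table, eqtl=eqtl,
                   extreme=(top_cases, top_controls))
    return results


def _repair_pairs(table: pd.DataFrame) -> pd.DataFrame:
    """Re-pair a selected subset so the MatchedDesign invariant holds.

    Extreme cases and controls are selected independently, so original
    pair ids rarely survive; expression simulation only needs group
    labels and covariates, so subjects are re-paired by rank order.
    """
    t = table.copy().reset_index(drop=True)
    cases = t[t["status"] == "case"].reset_index(drop=True)
    controls = t[t["status"] == "control"].reset_index(drop=True)
    n = min(len(cases), len(controls))
    cases = cases.iloc[:n].copy()
    controls = controls.iloc[:n].copy()
    cases["pair_id"] = [f"X{i + 1:03d}" for i in range(n)]
    controls["pair_id"] = [f"X{i + 1:03d}" for i in range(n)]
    return pd.concat([cases, controls], ignore_index=True)


def _subset_expr(expr, feature_ids):
    from .containers import ExpressionMatrix
    idx = [expr.feature_ids.index(f) for f in feature_ids]
    return ExpressionMatrix(feature_ids=list(feature_ids),
                            sample_ids=list(expr.sample_ids),
                            values=expr.values[idx])
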