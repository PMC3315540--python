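"""SNP-level association models for matched and unmatched designs.

For 1:1 matched pairs the conditional likelihood reduces exactly to an
intercept-free logistic regression on within-pair covariate differences
(case minus control) with an all-ones response; the per-pair nuisance
intercepts cancel. The Newton solver below fits that reduced likelihood
and is vectorised over sign-flip vectors, which is what makes
matched-pair permutation scans cheap: permuting disease status within a
pair just flips the sign of that pair's difference row.

Four matched models are supported (trend or nominal genotype coding,
with or without a BMI covariate) plus the unconditional logistic
analogues (with or without gender) for unmatched replication designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from .containers import MISSING, GenotypeDataset, MatchedDesign

CLR_MODELS = ("CLR_N", "CLR_C", "CLR_N,BMI", "CLR_C,BMI")
LR_MODELS = ("LR_N", "LR_C", "LR_N,Gender", "LR_C,Gender")

_BETA_MAX = 15.0   # |log OR| beyond this is treated as separation
_STEP_MAX = 4.0
_GRAD_TOL = 1e-8


@dataclass
class SnpModelFit:
    snp_id: str
    model: str
    beta: np.ndarray = field(default_factory=lambda: np.array([]))
    se: np.ndarray = field(default_factory=lambda: np.array([]))
    wald_stat: float = float("nan")
    df: int = 0
    p: float = float("nan")
    converged: bool = False
    estimable: bool = True
    n_used: int = 0


def _model_parts(model: str) -> tuple[str, bool]:
    """Split a model name into (coding, adjusted) parts."""
    base, _, cov = model.partition(",")
    coding = "nominal" if base.endswith("N") else "continuous"
    return coding, bool(cov)


def fit_pair_logit(X: np.ndarray, signs: np.ndarray | None = None,
                   max_iter: int = 40):
    """Maximize sum_i log sigmoid(s_i * x_i'b) over b, batched over sign rows.

    Parameters
    ----------
    X : (n, p) pair-difference design matrix.
    signs : (B, n) array of +/-1, one row per permutation replicate;
        ``None`` means the observed data (a single all-ones row).

    Returns
    -------
    beta : (B, p), cov : (B, p, p), converged : (B,) bool
    """
    n, p = X.shape
    if signs is None:
        signs = np.ones((1, n))
    signs = np.asarray(signs, dtype=float)
    B = signs.shape[0]
    beta = np.zeros((B, p))
    active = np.arange(B)
    for _ in range(max_iter):
        s = signs[active]
        eta = s * (X @ beta[active].T).T      # (A, n)
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = ((1.0 - mu) * s) @ X           # (A, p)
        gmax = np.abs(grad).max(axis=1)
        live = gmax > _GRAD_TOL
        if not live.any():
            break
        active = active[live]
        w = (mu * (1.0 - mu))[live]
        H = np.einsum("bi,ip,iq->bpq", w, X, X)
        H += 1e-10 * np.eye(p)
        try:
            step = np.linalg.solve(H, grad[live][:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = np.einsum("bpq,bq->bp", np.linalg.pinv(H), grad[live])
        norm = np.linalg.norm(step, axis=1, keepdims=True)
        step *= np.minimum(1.0, _STEP_MAX / np.maximum(norm, 1e-12))
        beta[active] += step
        np.clip(beta, -2 * _BETA_MAX, 2 * _BETA_MAX, out=beta)
    eta = signs * (X @ beta.T).T
    mu = 1.0 / (1.0 + np.exp(-eta))
    grad = ((1.0 - mu) * signs) @ X
    w = mu * (1.0 - mu)
    H = np.einsum("bi,ip,iq->bpq", w, X, X) + 1e-12 * np.eye(p)
    cov = np.linalg.pinv(H)
    converged = (np.abs(grad).max(axis=1) <= 1e-5) & (
        np.abs(beta).max(axis=1) < _BETA_MAX
    )
    return beta, cov, converged


def _wald(beta: np.ndarray, cov: np.ndarray, idx: list[int]):
    """Wald quadratic form on the coefficients at ``idx``; batched.

    Returns (stat, df, p) with shapes following the leading batch axis.
    """
    b = beta[..., idx]
    C = cov[..., idx, :][..., :, idx]
    df = len(idx)
    if df == 1:
        stat = b[..., 0] ** 2 / C[..., 0, 0]
    else:
        sol = np.linalg.solve(C, b[..., None])[..., 0]
        stat = np.einsum("...p,...p->...", b, sol)
    return stat, df, chi2.sf(stat, df)


def pair_difference_design(
    genotypes_at_snp: np.ndarray,
    case_idx: np.ndarray,
    control_idx: np.ndarray,
    coding: str,
    bmi_diff: np.ndarray | None = None,
):
    """Build the within-pair difference design for one SNP.

    Pairs with a missing genotype in either member are dropped. Returns
    (X, genotype_col_idx, pair_mask); X is None when no genotype column
    is estimable (all informative differences zero). ``pair_mask`` marks
    the retained pairs, so permutation sign vectors can be subset to
    match X's rows.
    """
    g = np.asarray(genotypes_at_snp, dtype=float)
    gc, gk = g[case_idx], g[control_idx]
    ok = (gc != MISSING) & (gk != MISSING)
    gc, gk = gc[ok], gk[ok]
    if coding == "continuous":
        cols = [gc - gk]
    elif coding == "nominal":
        cols = [(gc == 1).astype(float) - (gk == 1).astype(float),
                (gc == 2).astype(float) - (gk == 2).astype(float)]
    else:
        raise ValueError(f"unknown coding {coding!r}")
    keep = [c for c in cols if np.any(c != 0)]
    geno_idx = list(range(len(keep)))
    if not keep:
        return None, [], ok
    if bmi_diff is not None:
        keep.append(np.asarray(bmi_diff, dtype=float)[ok])
    return np.column_stack(keep), geno_idx, ok


def fit_matched_clr(
    genotypes_at_snp,
    design: MatchedDesign,
    coding: str = "continuous",
    adjust_bmi: bool = False,
    snp_id: str = "",
) -> SnpModelFit:
    """Conditional logistic fit for one SNP on a 1:1 matched design.

    ``genotypes_at_snp`` is ordered like ``design.table`` rows. The Wald
    test covers the genotype coefficients only (1 df for the trend
    coding, 2 df nominal unless a genotype class is absent).
    """
    model = ("CLR_N" if coding == "nominal" else "CLR_C") + (",BMI" if adjust_bmi else "")
    case_idx, control_idx = design.pair_arrays()
    bmi = design.table["bmi"].to_numpy(float)
    bmi_diff = bmi[case_idx] - bmi[control_idx] if adjust_bmi else None
    X, geno_idx, pair_mask = pair_difference_design(
        genotypes_at_snp, case_idx, control_idx, coding, bmi_diff
    )
    fit = SnpModelFit(snp_id=snp_id, model=model, n_used=int(pair_mask.sum()))
    if X is None:
        fit.estimable = False
        return fit
    beta, cov, conv = fit_pair_logit(X)
    fit.beta, fit.se = beta[0], np.sqrt(np.diag(cov[0]))
    fit.converged = bool(conv[0])
    if fit.converged:
        stat, df, p = _wald(beta, cov, geno_idx)
        fit.wald_stat, fit.df, fit.p = float(stat[0]), df, float(p[0])
    else:
        fit.df = len(geno_idx)
    return fit


def fit_unconditional_lr(
    genotypes_at_snp,
    status,
    coding: str = "continuous",
    adjust_gender: bool = False,
    gender=None,
    snp_id: str = "",
) -> SnpModelFit:
    """Ordinary logistic regression for an unmatched case/control design."""
    model = ("LR_N" if coding == "nominal" else "LR_C") + (",Gender" if adjust_gender else "")
    g = np.asarray(genotypes_at_snp, dtype=float)
    y = np.asarray([1.0 if s == "case" else 0.0 for s in status])
    ok = g != MISSING
    g, y = g[ok], y[ok]
    fit = SnpModelFit(snp_id=snp_id, model=model, n_used=int(ok.sum()))
    if coding == "continuous":
        cols = [g]
    else:
        cols = [(g == 1).astype(float), (g == 2).astype(float)]
    cols = [c for c in cols if np.ptp(c) > 0]
    if not cols:
        fit.estimable = False
        return fit
    geno_idx = list(range(1, 1 + len(cols)))
    X = [np.ones_like(g)] + cols
    if adjust_gender:
        gv = np.asarray([1.0 if s == "male" else 0.0 for s in gender])[ok]
        X.append(gv)
    X = np.column_stack(X)
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        conv = bool(res.mle_retvals.get("converged", False))
    except Exception:
        fit.converged = False
        return fit
    beta = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    fit.beta = beta[geno_idx]
    fit.se = np.sqrt(np.diag(cov))[geno_idx]
    fit.converged = conv and bool(np.all(np.abs(beta) < _BETA_MAX))
    if fit.converged:
        stat, df, p = _wald(beta[None, :], cov[None, :, :], geno_idx)
        fit.wald_stat, fit.df, fit.p = float(stat[0]), df, float(p[0])
    else:
        fit.df = len(geno_idx)
    return fit


def run_sbas(
    dataset: GenotypeDataset,
    design: MatchedDesign,
    models: tuple[str, ...] = CLR_MODELS,
) -> pd.DataFrame:
    """Fit every (SNP, model) pair; returns a tidy table.

    Columns: snp_id, model, beta1, se1, beta2, se2, wald, df, p,
    converged, estimable, n_pairs. Deterministic given its inputs.
    """
    design = design.aligned_to(dataset)
    case_idx, control_idx = design.pair_arrays(dataset)
    bmi = np.full(dataset.n_samples, np.nan)
    for sid, b in zip(design.table["sample_id"], design.table["bmi"]):
        bmi[dataset.sample_ids.index(sid)] = b
    bmi_diff_all = bmi[case_idx] - bmi[control_idx]

    rows = []
    for j, sid in enumerate(dataset.snp_ids):
        col = dataset.calls[:, j]
        for model in models:
            coding, adjusted = _model_parts(model)
            X, geno_idx, pair_mask = pair_difference_design(
                col, case_idx, control_idx, coding,
                bmi_diff_all if adjusted else None,
            )
            rec = dict(snp_id=sid, model=model, beta1=np.nan, se1=np.nan,
                       beta2=np.nan, se2=np.nan, wald=np.nan, df=0,
                       p=np.nan, converged=False, estimable=X is not None,
                       n_pairs=int(pair_mask.sum()))
            if X is not None:
                beta, cov, conv = fit_pair_logit(X)
                se = np.sqrt(np.diag(cov[0]))
                rec["beta1"], rec["se1"] = beta[0, 0], se[0]
                if len(geno_idx) > 1:
                    rec["beta2"], rec["se2"] = beta[0, 1], se[1]
                rec["converged"] = bool(conv[0])
                rec["df"] = len(geno_idx)
                if rec["converged"]:
                    stat, df, p = _wald(beta, cov, geno_idx)
                    rec["wald"], rec["p"] = float(stat[0]), float(p[0])
            rows.append(rec)
    return pd.DataFrame(rows)
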