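import numpy as np
import pandas as pd
import pytest

from gbascan.containers import GeneRecord, GenotypeDataset, MatchedDesign
from gbascan.simulate import SimConfig, simulate_cohort


def make_design(n_pairs: int, bmi=None, gender=None) -> MatchedDesign:
    """Minimal valid 1:1 design with constant covariates by default."""
    ids = [f"CASE{i:03d}" for i in range(n_pairs)] + [f"CTRL{i:03d}" for i in range(n_pairs)]
    return MatchedDesign(pd.DataFrame({
        "sample_id": ids,
        "status": ["case"] * n_pairs + ["control"] * n_pairs,
        "pair_id": [f"P{i:03d}" for i in range(n_pairs)] * 2,
        "bmi": 24.0 if bmi is None else np.concatenate([bmi, bmi]),
        "gender": ["male"] * 2 * n_pairs if gender is None else list(gender) * 2,
        "age": 40.0,
    }))


def make_dataset(calls, snp_ids=None, positions=None, chrom="1") -> GenotypeDataset:
    """Wrap a raw call matrix into a GenotypeDataset with stub metadata."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    snp_ids = snp_ids or [f"snp{j}" for j in range(m)]
    positions = positions if positions is not None else 1000 * (np.arange(m) + 1)
    return GenotypeDataset(
        sample_ids=[f"S{i:03d}" for i in range(n)],
        snp_ids=list(snp_ids),
        chromosome=np.array([chrom] * m, dtype=object),
        position=np.asarray(positions),
        alleles=[("A", "G")] * m,
        calls=calls,
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small matched cohort with two planted genes for smoke-level checks."""
    cfg = SimConfig(n_pairs=60, n_genes=6, snps_per_gene=4, n_intergenic_snps=10,
                    per_allele_log_or=0.9, seed=3)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """No planted effects, no missingness; for calibration checks."""
    cfg = SimConfig(n_pairs=150, n_genes=10, snps_per_gene=5, n_intergenic_snps=20,
                    causal_genes=0, missing_rate=0.0, seed=17)
    return simulate_cohort(cfg)


@pytest.fixture()
def discordant_fixture():
    """Handcrafted 10-pair cohort whose trend test crosses the tau gate.

    SNP s1 has 9:1 discordance (Wald p ~= 0.037, converged), s2 is 7:3.
    Small enough for exhaustive sign-flip enumeration.
    """
    n = 10
    case_g = np.c_[[1] * 9 + [0], [1] * 7 + [0] * 3]
    ctrl_g = np.c_[[0] * 9 + [1], [0] * 7 + [1] * 3]
    calls = np.vstack([case_g, ctrl_g]).astype(np.int8)
    ids = [f"CASE{i}" for i in range(n)] + [f"CTRL{i}" for i in range(n)]
    ds = GenotypeDataset(ids, ["s1", "s2"], np.array(["1", "1"], object),
                         np.array([1000, 2000]), [("A", "G")] * 2, calls)
    design = MatchedDesign(pd.DataFrame({
        "sample_id": ids,
        "status": ["case"] * n + ["control"] * n,
        "pair_id": [f"P{i}" for i in range(n)] * 2,
        "bmi": 24.0, "gender": ["male"] * 2 * n, "age": 40.0,
    }))
    genes = [GeneRecord("G1", "1", 1, 3000)]
    return ds, design, genes
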