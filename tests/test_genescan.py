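"""Truncated-product statistic, analytic null, SNP-gene assignment,
permutation empirical p, BH-FDR and the two-step gate."""

import numpy as np
import pandas as pd
import pytest

from gbascan.containers import GeneRecord
from gbascan.genescan import (
    assign_snps_to_genes,
    bh_fdr,
    gene_scan_table,
    permutation_scan,
    run_gbas,
    tpm_analytic_p,
    tpm_statistic,
    two_step_select,
)
from gbascan.association import run_sbas, CLR_MODELS

from conftest import make_dataset


class TestAssignment:
    def test_single_overlap(self):
        ds = make_dataset(np.zeros((2, 1), dtype=np.int8), positions=[150])
        genes = [GeneRecord("A", "1", 100, 200), GeneRecord("B", "1", 300, 400)]
        a = assign_snps_to_genes(ds, genes)
        assert a.snp_to_gene["snp0"] == "A"

    def test_multi_overlap_uniform_over_seeds(self):
        ds = make_dataset(np.zeros((2, 1), dtype=np.int8), positions=[150])
        genes = [GeneRecord("A", "1", 100, 200), GeneRecord("B", "1", 120, 260)]
        picks = [assign_snps_to_genes(ds, genes, seed=s).snp_to_gene["snp0"]
                 for s in range(400)]
        assert picks == [assign_snps_to_genes(ds, genes, seed=s).snp_to_gene["snp0"]
                         for s in range(400)]  # reproducible
        frac_a = np.mean([p == "A" for p in picks])
        half = 2.576 * np.sqrt(0.25 / 400)
        assert abs(frac_a - 0.5) < half

    def test_partition_conservation(self, tiny_cohort):
        ds, _, genes, _ = tiny_cohort
        a = assign_snps_to_genes(ds, genes)
        assert a.n_intragenic + a.n_intergenic == ds.n_snps
        all_assigned = [s for v in a.gene_to_snps.values() for s in v]
        assert len(all_assigned) == len(set(all_assigned)) == a.n_intragenic


class TestTpmStatistic:
    @pytest.mark.parametrize("ps,expected", [
        ((0.01, 0.5, 0.04), 4e-4),
        ((0.2, 0.9), 1.0),
        ((0.05,), 0.05),          # boundary p = tau enters the product
    ])
    def test_definitional_product(self, ps, expected):
        assert tpm_statistic(ps) == pytest.approx(expected)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            tpm_statistic([0.0, 0.5])
        with pytest.raises(ValueError):
            tpm_statistic([])


class TestTpmAnalyticP:
    def test_single_uniform(self):
        assert tpm_analytic_p(0.01, 1) == pytest.approx(0.01)

    def test_two_uniform_exact_decomposition(self):
        """P(W <= 0.01) at L=2: 2 * 0.95 * 0.01 + 0.05^2 = 0.0215."""
        W = tpm_statistic([0.01, 0.5])
        assert tpm_analytic_p(W, 2) == pytest.approx(0.0215, rel=1e-9)

    def test_w_one_gives_one(self):
        for L in (1, 5, 50):
            assert tpm_analytic_p(1.0, L) == 1.0

    def test_monte_carlo_agreement_grid(self):
        """Analytic CDF within 3 MC SE of direct simulation on an (L, W) grid."""
        rng = np.random.default_rng(0)
        n_mc = 100_000
        for L in (1, 2, 5, 10, 50):
            U = rng.random((n_mc, L))
            W = np.where(U <= 0.05, U, 1.0).prod(axis=1)
            W_pos = W[W < 1]
            if W_pos.size == 0:
                continue
            for q in (0.1, 0.5, 0.9):
                w = np.quantile(W_pos, q)
                mc = (W <= w).mean()
                se = np.sqrt(mc * (1 - mc) / n_mc)
                assert abs(tpm_analytic_p(w, L) - mc) <= 3 * se, (L, q)

    def test_monotone_in_w_and_l(self):
        ws = np.logspace(-8, -0.5, 12)
        ps = [tpm_analytic_p(w, 5) for w in ws]
        assert np.all(np.diff(ps) >= 0)
        for w in (1e-6, 1e-3, 0.04):
            pl = [tpm_analytic_p(w, L) for L in range(1, 30)]
            assert np.all(np.diff(pl) >= -1e-12)

    def test_agrees_with_gamma_survival_oracle(self):
        """Independent route: conditional on k p-values <= tau, the product is
        tau^k e^-G with G ~ Gamma(k, 1), so the null CDF is a binomial
        mixture of upper gamma tails. Exercises large L / tiny W too."""
        from scipy.stats import binom
        from scipy.special import gammaincc

        def oracle(w, L, tau=0.05):
            lw, lt = np.log(w), np.log(tau)
            tot = 0.0
            for k in range(1, L + 1):
                A = k * lt - lw
                tot += binom.pmf(k, L, tau) * (1.0 if A <= 0 else gammaincc(k, A))
            return tot

        for L, w in [(1500, 1e-280), (50, 1e-20), (10, 1e-6), (2, 0.01), (5, 1e-3)]:
            assert tpm_analytic_p(w, L) == pytest.approx(oracle(w, L), rel=1e-9)
            assert 0 < tpm_analytic_p(w, L) <= 1

    def test_w_ranking_equals_analytic_p_ranking(self):
        """For fixed L, ordering replicates by W equals ordering by analytic p."""
        rng = np.random.default_rng(3)
        for L in (2, 6):
            Ws = np.sort(rng.uniform(1e-8, 0.05, 20))
            ps = np.array([tpm_analytic_p(w, L) for w in Ws])
            assert np.all(np.diff(ps) >= 0)


class TestBhFdr:
    def test_step_up_formula_cases(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(bh_fdr([0.001, 1.0]), [0.002, 1.0])
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_never_decreases_and_preserves_order(self):
        rng = np.random.default_rng(1)
        p = rng.random(50)
        q = bh_fdr(p)
        assert np.all(q >= p)
        assert np.all(q[np.argsort(p)] == np.sort(q))


class TestPermutation:
    def test_exact_enumeration_matches_sampling(self, discordant_fixture):
        ds, design, genes = discordant_fixture
        a = assign_snps_to_genes(ds, genes)
        ex = permutation_scan(ds, design, a, models=("CLR_C",), exact=True)
        sam = permutation_scan(ds, design, a, models=("CLR_C",), B=10_000, seed=5)
        pe = ex["p_empirical"].iloc[0]
        ps = sam["p_empirical"].iloc[0]
        assert 0 < pe < 1  # the fixture is informative
        assert abs(pe - ps) <= 3 * np.sqrt(pe * (1 - pe) / 10_000)

    def test_observed_w_one_gives_empirical_one(self, null_cohort):
        ds, design, genes, _ = null_cohort
        a = assign_snps_to_genes(ds, genes)
        emp = permutation_scan(ds, design, a, models=("CLR_C",), B=50, seed=2)
        ties = emp[emp["W"] == 1.0]
        assert not ties.empty
        assert (ties["p_empirical"] == 1.0).all()

    def test_empirical_p_convention_floor(self, discordant_fixture):
        """Empirical p can never be 0: floor is 1/(B+1)."""
        ds, design, genes = discordant_fixture
        a = assign_snps_to_genes(ds, genes)
        emp = permutation_scan(ds, design, a, models=("CLR_C",), B=100, seed=1)
        assert (emp["p_empirical"] >= 1 / 101).all()

    def test_seed_reproducible(self, discordant_fixture):
        ds, design, genes = discordant_fixture
        a = assign_snps_to_genes(ds, genes)
        x = permutation_scan(ds, design, a, models=("CLR_C",), B=500, seed=9)
        y = permutation_scan(ds, design, a, models=("CLR_C",), B=500, seed=9)
        assert x.equals(y)

    def test_empirical_p_valid_under_null(self, null_cohort):
        """Sub-uniformity P(p <= x) <= x (+3 binomial SE) on a null cohort."""
        ds, design, genes, _ = null_cohort
        a = assign_snps_to_genes(ds, genes)
        emp = permutation_scan(ds, design, a, models=("CLR_C",), B=200, seed=6)
        p = emp["p_empirical"].to_numpy()
        for x in (0.05, 0.1, 0.25, 0.5):
            assert (p <= x).mean() <= x + 3 * np.sqrt(x * (1 - x) / len(p))


class TestTwoStepGate:
    def _tables(self):
        genes = ["G1", "G2", "G3"]
        rows = []
        for g in genes:
            for m in CLR_MODELS:
                p = 1e-9 if g == "G1" else (1e-6 if (g == "G2" and m == "CLR_C") else 0.5)
                rows.append(dict(gene_id=g, model=m, L=5, W=p, log_w=np.log(p),
                                 p_analytic=p))
        step1 = pd.DataFrame(rows)
        step1["fdr_step1"] = np.nan
        for m, grp in step1.groupby("model"):
            step1.loc[grp.index, "fdr_step1"] = bh_fdr(grp["p_analytic"].to_numpy())
        emp = pd.DataFrame([
            dict(gene_id=g, model=m, p_empirical=(0.001 if g != "G3" else 0.9))
            for g in genes for m in CLR_MODELS
        ])
        return step1, emp

    def test_all_four_models_pattern(self):
        step1, emp = self._tables()
        sel = two_step_select(step1, emp)
        g1 = sel[sel["gene_id"] == "G1"]
        assert (g1["pattern"] == "1111").all()
        assert g1["identified"].all()

    def test_gate_excludes_step1_failures(self):
        step1, emp = self._tables()
        sel = two_step_select(step1, emp)
        assert "G3" not in set(sel["gene_id"])

    def test_empty_prioritized_set(self):
        step1, emp = self._tables()
        step1["fdr_step1"] = 0.5
        sel = two_step_select(step1, emp)
        assert sel.empty


class TestEndToEndRecovery:
    def test_planted_gene_identified(self, tiny_cohort):
        ds, design, genes, truth = tiny_cohort
        assignment, step1, sel = run_gbas(ds, design, genes, B=300,
                                          assignment_seed=0, permutation_seed=1)
        assert not sel.empty
        identified = set(sel.loc[sel["identified"], "gene_id"])
        assert identified & truth.causal_gene_ids

    def test_l_fixed_across_permutations_means_w_ranking_valid(self, discordant_fixture):
        """Within a gene the SNP count is constant over replicates, so the
        permutation comparison on W matches comparison on analytic p."""
        ds, design, genes = discordant_fixture
        a = assign_snps_to_genes(ds, genes)
        sb = run_sbas(ds, design, ("CLR_C",))
        t = gene_scan_table(sb, a)
        assert (t["L"] == 2).all()
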