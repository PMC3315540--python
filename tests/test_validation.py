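"""Risk labelling, discordant-pair selection, quantile normalization,
ANCOVA/ANOVA and Kendall-dissimilarity clustering."""

import numpy as np
import pytest
from scipy.stats import kstest

from gbascan.containers import ExpressionMatrix, GeneRecord, MISSING
from gbascan.simulate import SimConfig, simulate_cohort, simulate_expression
from gbascan.validation import (
    cluster_and_summarize,
    differential_expression,
    kendall_dissimilarity,
    label_genotype_risk,
    quantile_normalize,
    select_extreme_pairs,
    subject_risk_scores,
)

from conftest import make_dataset, make_design


def expr_matrix(values, features=None):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        feature_ids=features or [f"f{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{j}" for j in range(values.shape[1])],
        values=values,
    )


class TestRiskLabels:
    def test_definitional_risky(self):
        # genotype 2 in 2/3 cases vs 0/3 controls
        calls = np.array([[2], [2], [0], [0], [0], [0]], dtype=np.int8)
        ds = make_dataset(calls)
        design = make_design(3)
        design.table["sample_id"] = ds.sample_ids  # align names
        labels = label_genotype_risk(ds, design, ["snp0"])
        by = {(l.snp_id, l.genotype): l.label for l in labels}
        assert by[("snp0", 2)] == "risky"
        assert by[("snp0", 0)] == "protective"

    def test_equal_frequencies_neutral(self):
        calls = np.array([[1], [0], [1], [0]], dtype=np.int8)
        ds = make_dataset(calls)
        design = make_design(2)
        design.table["sample_id"] = ds.sample_ids
        labels = label_genotype_risk(ds, design, ["snp0"])
        assert all(l.label == "neutral" for l in labels)

    def test_planted_risk_alleles_labelled_risky(self):
        """Risk-allele homozygote marked risky at most causal SNPs."""
        hits = tot = 0
        for rep in range(30):
            cfg = SimConfig(n_pairs=150, n_genes=2, snps_per_gene=5,
                            n_intergenic_snps=0, causal_genes=1,
                            per_allele_log_or=0.7, maf_range=(0.2, 0.5),
                            missing_rate=0.0, seed=900 + rep)
            ds, design, _, truth = simulate_cohort(cfg)
            labels = label_genotype_risk(ds, design, sorted(truth.causal_snp_ids))
            by = {(l.snp_id, l.genotype): l.label for l in labels}
            for sid in truth.causal_snp_ids:
                g_risk = 2 if truth.snp_log_or[sid] > 0 else 0
                tot += 1
                hits += by[(sid, g_risk)] == "risky"
        assert hits / tot >= 0.9


class TestExtremePairs:
    def _fixture(self):
        # 2 genes, 3 SNPs; gene A: snp0, snp1; gene B: snp2
        calls = np.array([
            [2, 2, 2],   # case rich in risky
            [2, 0, 0],
            [0, 0, 2],
            [0, 0, 0],   # control rich in protective
            [2, 2, 0],
            [0, 2, 2],
        ], dtype=np.int8)
        ds = make_dataset(calls)
        design = make_design(3)
        design.table["sample_id"] = ds.sample_ids
        g2s = {"A": ["snp0", "snp1"], "B": ["snp2"]}
        labels = label_genotype_risk(ds, design, ["snp0", "snp1", "snp2"])
        return ds, design, g2s, labels

    def test_carriers_ranked_first(self):
        ds, design, g2s, labels = self._fixture()
        cases, controls = select_extreme_pairs(labels, ds, design, g2s, k=1)
        assert cases == [ds.sample_ids[0]]

    def test_scores_match_hand_enumeration(self):
        """Oracle: exhaustively count risky/protective labels per subject."""
        ds, design, g2s, labels = self._fixture()
        lab = {(l.snp_id, l.genotype): l.label for l in labels}
        risky = subject_risk_scores(labels, ds, design, g2s, "risky")
        for i, sample in enumerate(ds.sample_ids):
            per_gene = []
            for snps in g2s.values():
                hit = tot = 0
                for sid in snps:
                    g = int(ds.calls[i, ds.snp_index(sid)])
                    l = lab[(sid, g)]
                    if l != "neutral":
                        tot += 1
                        hit += l == "risky"
                per_gene.append(hit / tot if tot else 0.0)
            assert risky[sample] == pytest.approx(np.mean(per_gene))

    def test_all_neutral_warns(self):
        calls = np.array([[1], [0], [1], [0]], dtype=np.int8)
        ds = make_dataset(calls)
        design = make_design(2)
        design.table["sample_id"] = ds.sample_ids
        labels = label_genotype_risk(ds, design, ["snp0"])
        with pytest.warns(UserWarning, match="tie-break"):
            cases, controls = select_extreme_pairs(labels, ds, design,
                                                   {"A": ["snp0"]}, k=1)
        assert cases == [sorted(ds.sample_ids[:2])[0]]

    def test_order_invariance(self):
        ds, design, g2s, labels = self._fixture()
        a = select_extreme_pairs(labels, ds, design, g2s, k=2)
        shuffled = design.table.sample(frac=1, random_state=0).reset_index(drop=True)
        from gbascan.containers import MatchedDesign
        b = select_extreme_pairs(labels, ds, MatchedDesign(shuffled), g2s, k=2)
        assert a == b

    def test_k_too_large_rejected(self):
        ds, design, g2s, labels = self._fixture()
        with pytest.raises(ValueError):
            select_extreme_pairs(labels, ds, design, g2s, k=5)


class TestQuantileNormalize:
    def test_mean_of_order_statistics(self):
        e = expr_matrix(np.array([[1, 4], [2, 5], [3, 6]]))
        out = quantile_normalize(e)
        np.testing.assert_allclose(out.values, [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        e = expr_matrix(rng.normal(size=(30, 6)))
        once = quantile_normalize(e)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(once.values, twice.values)

    def test_columns_share_sorted_values(self):
        rng = np.random.default_rng(4)
        e = expr_matrix(rng.normal(size=(25, 5)))
        out = quantile_normalize(e).values
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)

    def test_single_column_unchanged(self):
        e = expr_matrix([[3.0], [1.0], [2.0]])
        np.testing.assert_allclose(quantile_normalize(e).values, e.values)


class TestDifferentialExpression:
    def test_pooled_t_closed_form(self):
        """3 vs 3 with means 2 and 5: beta=3, t=3.674 (df 4), p~=0.0214."""
        e = expr_matrix([[1, 2, 3, 4, 5, 6]])
        res = differential_expression(e, ["a"] * 3 + ["b"] * 3)
        r = res[0]
        assert r.beta_group == pytest.approx(3.0)
        assert r.beta_group / r.se == pytest.approx(3.674, abs=1e-3)
        assert r.p_group == pytest.approx(0.0214, abs=2e-4)
        assert r.method == "ANOVA"

    def test_identical_group_means_zero_beta(self):
        e = expr_matrix([[1, 2, 3, 3, 2, 1]])
        res = differential_expression(e, ["a"] * 3 + ["b"] * 3)
        assert res[0].beta_group == pytest.approx(0.0)

    def test_constant_covariate_equals_anova(self):
        rng = np.random.default_rng(7)
        e = expr_matrix(rng.normal(size=(10, 8)))
        groups = ["a"] * 4 + ["b"] * 4
        with pytest.warns(UserWarning):
            ancova = differential_expression(e, groups, bmi=np.full(8, 24.0))
        anova = differential_expression(e, groups)
        for x, y in zip(ancova, anova):
            assert x.p_group == pytest.approx(y.p_group)
            assert x.method == "ANCOVA"

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(11)
        e = expr_matrix(rng.normal(size=(1000, 24)))
        groups = ["a"] * 12 + ["b"] * 12
        bmi = rng.normal(24, 3, 24)
        res = differential_expression(e, groups, bmi)
        assert kstest([r.p_group for r in res], "uniform").pvalue > 0.01

    def test_planted_two_sd_shift_power(self):
        """2-SD shift in 12v12 detected at p<0.05 in >=95% of replicates."""
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            cfg = SimConfig(n_pairs=12, n_genes=1, snps_per_gene=2,
                            n_intergenic_snps=0, causal_genes=1, seed=300 + rep)
            _, design, genes, truth = simulate_cohort(cfg)
            expr = simulate_expression(design, genes, truth,
                                       effect_sd_units=2.0, seed=rep)
            res = differential_expression(expr, design.table["status"].to_numpy(),
                                          design.table["bmi"].to_numpy(float))
            causal = {r.feature_id: r for r in res}[next(iter(truth.causal_gene_ids))]
            hits += causal.p_group < 0.05
        assert hits / n_rep >= 0.95


class TestClustering:
    def test_kendall_bounds(self):
        x = np.arange(10.0)
        assert kendall_dissimilarity(x, x) == pytest.approx(0.0)
        assert kendall_dissimilarity(x, -x) == pytest.approx(1.0)

    def test_constant_profile_named_in_error(self):
        e = expr_matrix(np.c_[np.ones(5), np.arange(5.0), np.arange(5.0) ** 2])
        with pytest.raises(ValueError, match="s0"):
            cluster_and_summarize(e, ["a", "a", "b"])

    def test_separated_groups_cluster_cleanly(self):
        rng = np.random.default_rng(21)
        # per-feature baselines give within-group rank correlation (as in
        # real expression); group b shifts half the features by 3 noise SD
        baselines = rng.normal(10, 3, size=20)
        base = baselines[:, None] + rng.normal(0, 1, size=(20, 12))
        base[:10, 6:] += 3.0
        e = expr_matrix(base)
        summary = cluster_and_summarize(e, ["a"] * 6 + ["b"] * 6)
        assert summary.misclassified == 0
        assert summary.variance_fractions.sum() == pytest.approx(1.0)
        assert summary.newick.endswith(";")

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(22)
        e = expr_matrix(rng.normal(size=(15, 7)))
        s = cluster_and_summarize(e, ["a"] * 4 + ["b"] * 3)
        assert s.variance_fractions.sum() == pytest.approx(1.0)
        assert np.all(np.diff(s.variance_fractions) <= 1e-12)
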