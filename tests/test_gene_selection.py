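import numpy as np
import pandas as pd
import pytest

from airwaydx.cohort_io import Dataset, ExpressionMatrix, PhenotypeTable
from airwaydx.gene_selection import (SeparationError, cluster_genes,
                                     fit_baseline, reduce_cluster,
                                     select_cancer_genes,
                                     select_cluster_subset)
from airwaydx.stats_core import moderated_t
from airwaydx.synthetic import SimulationConfig, simulate_cohort


def _null_covariates(rng, sample_ids):
    n = len(sample_ids)
    return pd.DataFrame({"GG": rng.integers(0, 2, n).astype(float),
                         "GS": rng.random(n), "GPY": rng.random(n)},
                        index=sample_ids)


class TestBaseline:
    def test_residuals_sum_to_zero(self, planted_cohort, rng):
        d, _ = planted_cohort
        base = fit_baseline(d, _null_covariates(rng, d.sample_ids))
        assert base.residuals.sum() == pytest.approx(0.0, abs=1e-6)
        assert ((base.fitted > 0) & (base.fitted < 1)).all()

    def test_null_residual_variance_matches_base_rate(self, rng):
        # covariates carry no signal -> fitted ~ prevalence, residual
        # variance ~ p(1-p)
        d, _ = simulate_cohort(SimulationConfig(
            seed=21, n_genes=400, genes_per_cluster=3, n_smoking_genes=5,
            n_py_genes=5, cluster_effect_sizes=(0.0,) * 11,
            age_cancer=(60, 10), age_benign=(60, 10)))
        base = fit_baseline(d, _null_covariates(rng, d.sample_ids))
        p = d.phenotypes.column("cancer_status").mean()
        assert base.residuals.var() == pytest.approx(p * (1 - p), rel=0.1)

    def test_single_class_rejected(self, rng):
        expr = ExpressionMatrix(pd.DataFrame(
            rng.normal(size=(3, 6)), index=list("abc"),
            columns=[f"S{j}" for j in range(6)]))
        ph = PhenotypeTable(pd.DataFrame({
            "cancer_status": [1] * 6, "age": [60.0] * 6},
            index=expr.sample_ids))
        with pytest.raises(ValueError, match="class"):
            fit_baseline(Dataset(expr, ph),
                         _null_covariates(rng, expr.sample_ids))

    def test_perfect_separation_flagged(self, rng):
        n = 40
        y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        expr = ExpressionMatrix(pd.DataFrame(
            rng.normal(size=(2, n)), index=["g1", "g2"],
            columns=[f"S{j}" for j in range(n)]))
        ph = PhenotypeTable(pd.DataFrame({
            "cancer_status": y, "age": 60.0 + 10.0 * y},  # age separates...
            index=expr.sample_ids))
        cov = _null_covariates(rng, expr.sample_ids)
        cov["GPY"] = y.astype(float)  # ...and GPY separates perfectly
        with pytest.raises(SeparationError):
            fit_baseline(Dataset(expr, ph), cov)


class TestSelectCancerGenes:
    def test_recall_of_planted_genes(self, planted_cohort, rng):
        d, truth = planted_cohort
        base = fit_baseline(d, _null_covariates(rng, d.sample_ids))
        hits = select_cancer_genes(d, base.residuals)
        planted = set(truth.cancer_genes)
        recall = len(planted & set(hits.index)) / len(planted)
        assert recall >= 0.90

    def test_covariate_explained_gene_not_selected(self, planted_cohort):
        """A gene that is an exact function of a modeled covariate has ~zero
        association with the baseline residuals, even though it associates
        with cancer marginally through that covariate."""
        d, _ = planted_cohort
        rng = np.random.default_rng(9)
        age = d.phenotypes.column("age").to_numpy()
        gene = 0.1 * age + rng.normal(0, 0.1, size=len(age))
        df = d.expression.data.copy()
        df.loc["AGEPROXY"] = gene
        d2 = Dataset(ExpressionMatrix(df), d.phenotypes)
        y = d.phenotypes.column("cancer_status").to_numpy()
        # marginally cancer-associated (age differs by class)...
        marginal = moderated_t(d2.expression, y - y.mean(),
                               gene_as_predictor=True)
        t_marginal = marginal.t[marginal.gene_ids.index("AGEPROXY")]
        assert abs(t_marginal) > 2.7
        # ...but not against residuals of a baseline that includes age
        cov = _null_covariates(rng, d.sample_ids)
        base = fit_baseline(d2, cov)
        hits = select_cancer_genes(d2, base.residuals)
        assert "AGEPROXY" not in hits.index

    def test_exact_covariate_function_orthogonal(self, planted_cohort, rng):
        # residuals of the MLE are exactly orthogonal to fitted covariates
        d, _ = planted_cohort
        cov = _null_covariates(rng, d.sample_ids)
        base = fit_baseline(d, cov)
        gene = 2.0 + 3.0 * cov["GS"].to_numpy()
        df = d.expression.data.iloc[:50].copy()
        df.loc["GSLINEAR"] = gene
        d2 = Dataset(ExpressionMatrix(df), d.phenotypes)
        res = moderated_t(d2.expression, base.residuals,
                          gene_as_predictor=True)
        assert abs(res.t[res.gene_ids.index("GSLINEAR")]) < 0.2

    def test_null_false_selection_count(self, null_cohort):
        d, _ = null_cohort
        y = d.phenotypes.column("cancer_status").to_numpy().astype(float)
        hits = select_cancer_genes(d, y - y.mean())
        # expectation ~ 2 * (1 - Phi(2.7)) * 10000 ~ 70
        assert 35 <= len(hits) <= 110


class TestClusterGenes:
    def test_anticorrelated_blocks_split(self, rng):
        n = 60
        f = rng.normal(size=n)
        up = np.vstack([f + rng.normal(0, 0.1, n) for _ in range(5)])
        down = np.vstack([-f + rng.normal(0, 0.1, n) for _ in range(5)])
        expr = ExpressionMatrix(pd.DataFrame(
            np.vstack([up, down]) + 8.0,
            index=[f"U{i}" for i in range(5)] + [f"D{i}" for i in range(5)],
            columns=[f"S{j}" for j in range(n)]))
        ph = PhenotypeTable(pd.DataFrame(
            {"cancer_status": ([0, 1] * n)[:n]}, index=expr.sample_ids))
        lab = cluster_genes(Dataset(expr, ph), list(expr.gene_ids),
                            n_clusters=2)
        assert lab[[f"U{i}" for i in range(5)]].nunique() == 1
        assert lab[[f"D{i}" for i in range(5)]].nunique() == 1
        assert lab["U0"] != lab["D0"]

    def test_input_order_invariance(self, planted_cohort):
        d, truth = planted_cohort
        genes = truth.cancer_genes
        lab1 = cluster_genes(d, genes, n_clusters=6)
        lab2 = cluster_genes(d, genes[::-1], n_clusters=6)
        assert lab1.sort_index().equals(lab2.sort_index())

    def test_planted_structure_recovered(self, planted_cohort):
        from sklearn.metrics import adjusted_rand_score

        d, truth = planted_cohort
        planted = [g for mem in truth.cluster_members.values() for g in mem]
        lab = cluster_genes(d, planted, n_clusters=11)
        ari = adjusted_rand_score(truth.cluster_of().loc[lab.index], lab)
        assert ari >= 0.9

    def test_duplicate_genes_cocluster(self, rng):
        n = 30
        base = rng.normal(size=n)
        rows = {"dup1": base, "dup2": base.copy(),
                "other": rng.normal(size=n)}
        expr = ExpressionMatrix(pd.DataFrame(rows, index=None).T.set_axis(
            [f"S{j}" for j in range(n)], axis=1))
        ph = PhenotypeTable(pd.DataFrame(
            {"cancer_status": ([0, 1] * n)[:n]}, index=expr.sample_ids))
        lab = cluster_genes(Dataset(expr, ph), ["dup1", "dup2", "other"],
                            n_clusters=2)
        assert lab["dup1"] == lab["dup2"]

    def test_too_few_genes_rejected(self, planted_cohort):
        d, truth = planted_cohort
        with pytest.raises(ValueError):
            cluster_genes(d, truth.cancer_genes[:3], n_clusters=11)


class TestReduceCluster:
    def test_identical_genes_two_representatives(self, rng):
        n = 30
        base = rng.normal(size=n) + 8.0
        expr = ExpressionMatrix(pd.DataFrame(
            np.vstack([base] * 5), index=[f"g{i}" for i in range(5)],
            columns=[f"S{j}" for j in range(n)]))
        ph = PhenotypeTable(pd.DataFrame(
            {"cancer_status": ([0, 1] * n)[:n]}, index=expr.sample_ids))
        reps, r = reduce_cluster(Dataset(expr, ph), list(expr.gene_ids))
        assert len(reps) == 2
        assert r == pytest.approx(1.0)

    def test_size_two_cluster_returns_both(self, planted_cohort):
        d, truth = planted_cohort
        genes = truth.cluster_members[1][:2]
        reps, _ = reduce_cluster(d, genes)
        assert sorted(reps) == sorted(genes)

    def test_factor_cluster_reaches_target(self, planted_cohort):
        d, truth = planted_cohort
        reps, r = reduce_cluster(d, truth.cluster_members[4])
        assert 2 <= len(reps) <= 4
        assert r >= 0.90  # rho = 0.6 factor cluster of 20 genes


class TestClusterSubset:
    def test_signal_clusters_chosen(self, planted_cohort):
        """6 planted signal + 5 planted null clusters: every signal cluster
        is admitted; sequential selection may allow at most one extra."""
        from airwaydx.cfgc import apply_cfgc, fit_cfgc, select_covariate_genes
        from airwaydx.pipeline import _FACTOR_TO_FEATURE, _FACTORS

        d, truth = planted_cohort
        tgt = {"sex": 1, "smoking_status": 3, "pack_years": 2}
        cov = {}
        for f in _FACTORS:
            hits = select_covariate_genes(d, f, min_genes=tgt[f])
            m = fit_cfgc(d, f, list(hits.index[:100]), n_genes=tgt[f])
            cov[_FACTOR_TO_FEATURE[f]] = apply_cfgc(m, d.expression)
        cov = pd.DataFrame(cov, index=d.sample_ids)
        reps_map = {c: reduce_cluster(d, mem)[0]
                    for c, mem in truth.cluster_members.items()}
        chosen, auc = select_cluster_subset(d, reps_map, cov, reps=50,
                                            seed=0)
        signal = {c for c, e in truth.cluster_effects.items() if e != 0}
        assert signal <= set(chosen)
        assert len(set(chosen) - signal) <= 1
        assert auc > 0.85

    def test_single_strong_cluster_chosen(self, planted_cohort, rng):
        d, truth = planted_cohort
        reps_map = {4: truth.cluster_members[4][:3]}
        cov = _null_covariates(rng, d.sample_ids)
        chosen, auc = select_cluster_subset(d, reps_map, cov, reps=30,
                                            seed=0)
        assert chosen == [4]
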