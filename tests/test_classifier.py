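import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from airwaydx.classifier import (choose_threshold, classify, cluster_means,
                                 compute_features, fit_final, score)
from airwaydx.cohort_io import ExpressionMatrix

# plausible log2-scale feature ranges for property tests
_FEATURE_RANGES = {
    "Age": (35.0, 90.0), "GG": (0.0, 1.0), "GS": (0.0, 1.0),
    "GPY": (0.0, 1.0), "CA1": (2.0, 14.0), "CA2": (2.0, 14.0),
    "CA4": (2.0, 14.0), "CA7": (2.0, 14.0), "CA9": (2.0, 14.0),
    "CA10": (2.0, 14.0),
}

feature_vectors = st.fixed_dictionaries({
    name: st.floats(lo, hi, allow_nan=False)
    for name, (lo, hi) in _FEATURE_RANGES.items()})


class TestLockedScore:
    def test_score_at_zero_features(self, locked):
        fv = {f: 0.0 for f in _FEATURE_RANGES}
        # logistic of the bare intercept 3.3173
        assert round(score(fv, locked), 5) == 0.96502

    def test_score_half_at_linear_zero(self, locked):
        fv = {f: 0.0 for f in _FEATURE_RANGES}
        # cancel the intercept through the age term
        fv["Age"] = -locked.intercept / locked.coefficients["Age"]
        assert score(fv, locked) == pytest.approx(0.5, abs=1e-12)

    def test_regression_fixture_hand_arithmetic(self, locked):
        fv = {"Age": 65.0, "GG": 1.0, "GS": 0.9, "GPY": 0.8, "CA1": 6.0,
              "CA2": 7.0, "CA4": 8.0, "CA7": 6.5, "CA9": 5.0, "CA10": 6.0}
        # independent hand evaluation of the published linear form
        y = (3.3173 + 0.0623 * 65.0 + 0.5450 * 1.0 + 0.1661 * 0.9
             + 3.0205 * 0.8 - 0.4406 * 6.0 - 0.3402 * 7.0 + 0.1725 * 8.0
             + 0.5670 * 6.5 - 0.3160 * 5.0 - 0.3791 * 6.0)
        expected = math.exp(y) / (1.0 + math.exp(y))
        assert score(fv, locked) == pytest.approx(expected, abs=1e-12)

    @given(fv=feature_vectors)
    def test_score_in_unit_interval(self, locked, fv):
        assert 0.0 < score(fv, locked) < 1.0

    @given(fv=feature_vectors, delta=st.floats(0.01, 2.0))
    def test_monotonicity_matches_coefficient_signs(self, locked, fv, delta):
        base = score(fv, locked)
        for feat, b in locked.coefficients.items():
            bumped = dict(fv)
            bumped[feat] = fv[feat] + delta
            if b > 0:
                assert score(bumped, locked) > base
            else:
                assert score(bumped, locked) < base

    def test_scorer_is_pure(self, locked, locked_cohort):
        d, _ = locked_cohort
        age = d.phenotypes.column("age")
        s1 = score(compute_features(d.expression, age, locked), locked)
        s2 = score(compute_features(d.expression, age, locked), locked)
        assert np.array_equal(s1.to_numpy(), s2.to_numpy())

    def test_missing_feature_rejected(self, locked):
        fv = {f: 0.0 for f in _FEATURE_RANGES if f != "GPY"}
        with pytest.raises(KeyError, match="GPY"):
            score(fv, locked)


class TestClassify:
    @pytest.mark.parametrize("s,call", [
        (0.65, 1),       # boundary inclusive
        (0.649999, 0),
        (1.0, 1),
        (0.0, 0),
    ])
    def test_boundary(self, s, call):
        assert classify(s) == call

    def test_vectorized(self):
        calls = classify(np.array([0.1, 0.65, 0.9]))
        assert calls.tolist() == [0, 1, 1]


class TestClusterMeans:
    def _expr(self, rows):
        return ExpressionMatrix(pd.DataFrame(
            rows, columns=["S1", "S2"]))

    def test_two_gene_mean(self):
        expr = self._expr(pd.DataFrame({"S1": [4.0, 6.0], "S2": [5.0, 7.0]},
                                       index=["g1", "g2"]))
        ca = cluster_means(expr, {"CA": ["g1", "g2"]})
        assert ca["CA"].tolist() == [5.0, 6.0]

    def test_constant_members(self):
        expr = self._expr(pd.DataFrame({"S1": [3.0, 3.0], "S2": [3.0, 3.0]},
                                       index=["g1", "g2"]))
        assert (cluster_means(expr, {"CA": ["g1", "g2"]})["CA"] == 3.0).all()

    def test_member_order_irrelevant(self, rng):
        df = pd.DataFrame(rng.normal(size=(3, 2)), index=["a", "b", "c"],
                          columns=["S1", "S2"])
        expr = ExpressionMatrix(df)
        m1 = cluster_means(expr, {"CA": ["a", "b", "c"]})
        m2 = cluster_means(expr, {"CA": ["c", "a", "b"]})
        assert np.allclose(m1["CA"], m2["CA"])

    def test_missing_member_named(self, rng):
        expr = ExpressionMatrix(pd.DataFrame(
            rng.normal(size=(1, 2)), index=["g1"], columns=["S1", "S2"]))
        with pytest.raises(KeyError, match="LYPD2"):
            cluster_means(expr, {"CA9": ["g1", "LYPD2"]})


class TestFitFinal:
    def _features(self, rng, n=400):
        feats = pd.DataFrame({
            "Age": rng.normal(60, 10, n), "GG": rng.integers(0, 2, n),
            "GS": rng.random(n), "GPY": rng.random(n),
            "CA1": rng.normal(8, 1, n), "CA7": rng.normal(6, 1, n),
        })
        eta = -2.0 + 0.05 * feats["Age"] + 0.5 * feats["GG"] \
            - 0.5 * feats["CA1"] + 0.6 * feats["CA7"]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        return feats, y

    def test_zero_penalty_equals_mle(self, rng):
        import statsmodels.api as sm

        feats, y = self._features(rng)
        fit = fit_final(feats, y, penalty_clusters=0.0)
        ml = sm.Logit(y, sm.add_constant(feats)).fit(disp=0)
        assert np.abs(fit.coefficients.to_numpy()
                      - np.asarray(ml.params)[1:]).max() < 1e-6
        assert fit.intercept == pytest.approx(ml.params.iloc[0], abs=1e-6)

    def test_huge_penalty_collapses_cluster_coefficients(self, rng):
        feats, y = self._features(rng)
        fit = fit_final(feats, y, penalty_clusters=1e8)
        assert np.abs(fit.coefficients[["CA1", "CA7"]]).max() < 1e-3
        # covariates stay essentially at their covariate-only MLE
        import statsmodels.api as sm

        covs = feats[["Age", "GG", "GS", "GPY"]]
        ml = sm.Logit(y, sm.add_constant(covs)).fit(disp=0)
        assert np.abs(fit.coefficients[covs.columns].to_numpy()
                      - np.asarray(ml.params)[1:]).max() < 1e-3

    def test_l1_zero_penalty_matches_mle(self, rng):
        import statsmodels.api as sm

        feats, y = self._features(rng)
        fit = fit_final(feats, y, penalty_clusters=0.0, penalty="l1")
        ml = sm.Logit(y, sm.add_constant(feats)).fit(disp=0)
        assert np.abs(fit.coefficients.to_numpy()
                      - np.asarray(ml.params)[1:]).max() < 1e-4

    def test_single_class_rejected(self, rng):
        feats, _ = self._features(rng, n=50)
        with pytest.raises(ValueError, match="class"):
            fit_final(feats, np.ones(50))


class TestChooseThreshold:
    def test_perfect_separation(self):
        status = np.array([0, 0, 1, 1, 1])
        scores = status.astype(float)
        t = choose_threshold(scores, status, target_sensitivity=0.9)
        assert t == 1.0  # largest cutoff keeping sensitivity >= 0.9

    def test_target_one_returns_min_cancer_score(self, rng):
        scores = rng.random(100)
        status = (rng.random(100) < 0.5).astype(int)
        t = choose_threshold(scores, status, target_sensitivity=1.0)
        assert t <= scores[status == 1].min()

    def test_subgroup_sensitivity_hits_target(self, locked, locked_cohort):
        d, truth = locked_cohort
        y = d.phenotypes.column("cancer_status").to_numpy()
        b = d.phenotypes.column("bronchoscopy_diagnostic").to_numpy()
        s = truth["score"].to_numpy()
        nondx = b == 0
        t = choose_threshold(s, y, nondx, target_sensitivity=0.90)
        sens = (s[nondx & (y == 1)] >= t).mean()
        assert 0.90 <= sens <= 0.95

    def test_no_cancers_rejected(self):
        with pytest.raises(ValueError):
            choose_threshold(np.array([0.2, 0.4]), np.array([0, 0]))
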