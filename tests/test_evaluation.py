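import numpy as np
import pandas as pd
import pytest

from airwaydx.evaluation import (combine_with_bronchoscopy, compare_models,
                                 confusion_metrics, cv_harness,
                                 delong_auc_variance, performance_table,
                                 roc_auc)


def brute_auc(scores, truth):
    """Oracle: fraction of concordant (cancer, benign) pairs plus half-ties."""
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_bronchoscopy_sensitivity_row(self):
        # 40 of 78 cancers detected at bronchoscopy
        truth = np.r_[np.ones(78, int), np.zeros(85, int)]
        calls = np.r_[np.ones(40, int), np.zeros(38, int), np.zeros(85, int)]
        cm = confusion_metrics(truth, calls)
        sens, ci = cm.sensitivity
        assert round(100 * sens) == 51
        assert (round(100 * ci[0]), round(100 * ci[1])) == (40, 62)

    def test_classifier_and_combined_rows(self):
        # among 38 non-diagnostic cancers the classifier finds 34
        cm = confusion_metrics(np.ones(38, int),
                               np.r_[np.ones(34, int), np.zeros(4, int)])
        assert round(100 * cm.sensitivity[0]) == 89
        # combined detections: 40 + 34 = 74 of 78
        cm2 = confusion_metrics(np.ones(78, int),
                                np.r_[np.ones(74, int), np.zeros(4, int)])
        assert round(100 * cm2.sensitivity[0]) == 95

    def test_counts_consistency(self, rng):
        truth = rng.integers(0, 2, 200)
        calls = rng.integers(0, 2, 200)
        cm = confusion_metrics(truth, calls)
        assert cm.n == 200
        sens, _ = cm.sensitivity
        assert round(sens * (cm.tp + cm.fn)) == cm.tp

    def test_zero_denominator_undefined(self):
        cm = confusion_metrics(np.zeros(5, int), np.zeros(5, int))
        assert cm.sensitivity == (None, None)
        assert cm.specificity[0] == 1.0

    def test_empty_subgroup_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confusion_metrics(np.array([1]), np.array([1]),
                              subgroup_mask=np.array([False]))


class TestCombine:
    @pytest.mark.parametrize("b,c,expected", [
        (1, 0, 1), (0, 0, 0), (1, 1, 1), (0, 1, 1)])
    def test_or_rule(self, b, c, expected):
        assert combine_with_bronchoscopy([b], [c])[0] == expected

    def test_table_counts(self):
        b = np.r_[np.ones(40, int), np.zeros(38, int)]
        c = np.r_[np.zeros(40, int), np.ones(34, int), np.zeros(4, int)]
        assert combine_with_bronchoscopy(b, c).sum() == 74

    def test_performance_table_row(self):
        truth = np.r_[np.ones(78, int), np.zeros(85, int)]
        b = np.r_[np.ones(40, int), np.zeros(123, int)]
        c = np.r_[np.zeros(40, int), np.ones(34, int), np.zeros(4, int),
                  np.zeros(85, int)]
        row = performance_table(truth, b, c).iloc[0]
        assert row["bronchoscopy_sensitivity_pct"] == 51
        assert row["classifier_sensitivity_pct"] == 89
        assert row["combined_sensitivity_pct"] == 95


class TestRocAuc:
    def test_perfect_scores(self):
        r = roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
        assert r.auc == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(8)
        scores = rng.random(1000)
        truth = rng.integers(0, 2, 1000)
        r = roc_auc(scores, truth)
        assert 0.45 <= r.auc <= 0.55
        assert r.ci[0] <= r.auc <= r.ci[1]

    def test_matches_bruteforce_pair_counting(self, rng):
        scores = np.round(rng.random(150), 2)  # deliberate ties
        truth = rng.integers(0, 2, 150)
        auc, _ = delong_auc_variance(scores, truth)
        assert auc == pytest.approx(brute_auc(scores, truth), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.random(100)
        truth = rng.integers(0, 2, 100)
        a1, _ = delong_auc_variance(scores, truth)
        a2, _ = delong_auc_variance(np.exp(3 * scores), truth)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))


class TestCompareModels:
    def test_identical_scores(self, rng):
        s = rng.random(80)
        y = rng.integers(0, 2, 80)
        a1, a2, p = compare_models(s, s, y)
        assert a1 == a2
        assert p == 1.0

    def test_complement_scores_sum_to_one(self, rng):
        s = rng.random(80)
        y = rng.integers(0, 2, 80)
        a1, a2, _ = compare_models(s, 1 - s, y)
        assert a1 + a2 == pytest.approx(1.0)

    def test_genomic_beats_clinical_on_cluster_signal(self, locked,
                                                      locked_cohort):
        from airwaydx.pipeline import clinical_model_scores

        d, truth = locked_cohort
        y = d.phenotypes.column("cancer_status").to_numpy()
        full = truth["score"].to_numpy()
        clinical = clinical_model_scores(d).to_numpy()
        a_full, a_clin, p = compare_models(full, clinical, y)
        assert a_full > a_clin
        assert p < 0.05


class TestCvHarness:
    def _fast_config(self):
        from airwaydx.pipeline import PipelineConfig

        return PipelineConfig(cluster_cv_reps=15, max_candidates=50)

    def test_reproducible_folds_and_no_leakage(self, monkeypatch,
                                               planted_cohort):
        import airwaydx.pipeline as pl

        d, _ = planted_cohort
        seen_train: list[set] = []
        original = pl.derive

        def recording_derive(train, config=None, seed=0):
            seen_train.append(set(train.sample_ids))
            return original(train, config, seed=seed)

        monkeypatch.setattr(pl, "derive", recording_derive)
        cv1 = cv_harness(self._fast_config(), d, reps=1, seed=11)
        cv2 = cv_harness(self._fast_config(), d, reps=1, seed=11)
        assert np.array_equal(cv1.holdout_indices[0], cv2.holdout_indices[0])
        assert cv1.per_rep_auc == cv2.per_rep_auc
        ids = np.asarray(d.sample_ids)
        for train_ids, held in zip(seen_train, [cv1.holdout_indices[0],
                                                cv2.holdout_indices[0]]):
            assert train_ids.isdisjoint(ids[held])

    def test_signal_cohort_high_cv_auc(self, locked):
        """Strong planted effects: pooled leak-free CV AUC stays high."""
        from airwaydx.synthetic import simulate_from_locked

        d, _ = simulate_from_locked(locked, 299, seed=17, feature_sd=2.0,
                                    n_noise_genes=300)
        cv = cv_harness(self._fast_config(), d, reps=4, seed=3)
        assert cv.pooled_auc >= 0.85
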