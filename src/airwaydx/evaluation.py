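"""Diagnostic-performance evaluation and the cross-validation harness.

Covers the reporting conventions of diagnostic-test studies: confusion
metrics (sensitivity, specificity, NPV, PPV) with Wilson 95% intervals,
bronchoscopy-combined calls (a patient is positive when bronchoscopy was
diagnostic OR the classifier calls positive — bronchoscopy has no false
positives, so its specificity is treated as 100%), ROC/AUC with DeLong
variance, paired DeLong comparison of two models, and a repeated 10%
stratified-holdout harness that re-runs the *entire* derivation inside each
training fold so the performance estimate carries no selection leakage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import Dataset
from .stats_core import wilson_ci

__all__ = [
    "ConfusionSummary",
    "RocResult",
    "confusion_metrics",
    "combine_with_bronchoscopy",
    "roc_auc",
    "delong_auc_variance",
    "compare_models",
    "cv_harness",
    "CvResult",
]


@dataclass(frozen=True)
class ConfusionSummary:
    """Confusion counts and derived metrics with Wilson 95% CIs.

    A metric whose denominator is zero is reported as ``None`` (undefined),
    never as 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    subgroup: str = ""

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def prevalence(self) -> float | None:
        return (self.tp + self.fn) / self.n if self.n else None

    def _rate(self, num: int, den: int):
        if den == 0:
            return None, None
        return num / den, wilson_ci(num, den)

    @property
    def sensitivity(self):
        return self._rate(self.tp, self.tp + self.fn)

    @property
    def specificity(self):
        return self._rate(self.tn, self.tn + self.fp)

    @property
    def npv(self):
        return self._rate(self.tn, self.tn + self.fn)

    @property
    def ppv(self):
        return self._rate(self.tp, self.tp + self.fp)

    def as_row(self) -> dict:
        def fmt(pair):
            value, ci = pair
            if value is None:
                return "undefined"
            lo, hi = ci
            return (f"{_pct(value)}% ({_pct(lo)}-{_pct(hi)}%)")

        return {
            "subgroup": self.subgroup, "N": self.n,
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "sensitivity": fmt(self.sensitivity),
            "specificity": fmt(self.specificity),
            "NPV": fmt(self.npv), "PPV": fmt(self.ppv),
        }


def _pct(x: float) -> int:
    """Percent rounded half-up to an integer (display convention)."""
    return int(np.floor(100.0 * x + 0.5))


def confusion_metrics(truth, calls, subgroup_mask=None, subgroup: str = ""
                      ) -> ConfusionSummary:
    """Confusion summary of binary calls against binary truth."""
    y = np.asarray(truth, dtype=int)
    c = np.asarray(calls, dtype=int)
    if y.size != c.size:
        raise ValueError("truth and calls must have equal length")
    if subgroup_mask is not None:
        mask = np.asarray(subgroup_mask, dtype=bool)
        y, c = y[mask], c[mask]
    if y.size == 0:
        raise ValueError("empty subgroup")
    return ConfusionSummary(
        tp=int(((y == 1) & (c == 1)).sum()),
        fp=int(((y == 0) & (c == 1)).sum()),
        tn=int(((y == 0) & (c == 0)).sum()),
        fn=int(((y == 1) & (c == 0)).sum()),
        subgroup=subgroup)


def combine_with_bronchoscopy(bronch_diagnostic, classifier_call):
    """Combined call: positive iff bronchoscopy diagnostic OR classifier positive."""
    b = np.asarray(bronch_diagnostic, dtype=int)
    c = np.asarray(classifier_call, dtype=int)
    return ((b == 1) | (c == 1)).astype(int)


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci: tuple[float, float]
    comparison_p: float | None = None


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, truth: np.ndarray
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC (Mann-Whitney with midranks) and its structural components."""
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n          # per-positive component
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m    # per-negative component
    return float(auc), v10, v01


def delong_auc_variance(scores, truth) -> tuple[float, float]:
    """AUC and its DeLong variance estimate."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth, dtype=int)
    auc, v10, v01 = _delong_components(s, y)
    var = (np.var(v10, ddof=1) / v10.size if v10.size > 1 else 0.0) + \
          (np.var(v01, ddof=1) / v01.size if v01.size > 1 else 0.0)
    return auc, float(var)


def roc_auc(scores, truth, level: float = 0.95) -> RocResult:
    """ROC curve and AUC with a DeLong confidence interval."""
    from sklearn.metrics import roc_curve

    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth, dtype=int)
    auc, var = delong_auc_variance(s, y)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    fpr, tpr, _ = roc_curve(y, s)
    return RocResult(fpr=fpr, tpr=tpr, auc=auc,
                     ci=(max(0.0, auc - half), min(1.0, auc + half)))


def compare_models(scores_full, scores_clinical, truth
                   ) -> tuple[float, float, float]:
    """Paired DeLong comparison of two score sets on the same samples.

    Returns ``(auc_full, auc_clinical, two-sided p)``.
    """
    s1 = np.asarray(scores_full, dtype=float)
    s2 = np.asarray(scores_clinical, dtype=float)
    y = np.asarray(truth, dtype=int)
    if s1.size != s2.size or s1.size != y.size:
        raise ValueError("score vectors and truth must share samples")
    a1, v10_1, v01_1 = _delong_components(s1, y)
    a2, v10_2, v01_2 = _delong_components(s2, y)
    m, n = v10_1.size, v01_1.size

    def cov(u, v):
        return float(np.cov(u, v, ddof=1)[0, 1]) if u.size > 1 else 0.0

    var = (np.var(v10_1, ddof=1) + np.var(v10_2, ddof=1)
           - 2 * cov(v10_1, v10_2)) / m \
        + (np.var(v01_1, ddof=1) + np.var(v01_2, ddof=1)
           - 2 * cov(v01_1, v01_2)) / n
    if var <= 0:
        p = 1.0
    else:
        zstat = (a1 - a2) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(zstat)))
    return a1, a2, p


# ---------------------------------------------------------------------------
# cross-validation harness
# ---------------------------------------------------------------------------

@dataclass
class CvResult:
    per_rep_auc: list[float]
    pooled_auc: float
    holdout_indices: list[np.ndarray]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.per_rep_auc))


def cv_harness(pipeline_config, d: Dataset, holdout: float = 0.10,
               reps: int = 20, seed: int = 0) -> CvResult:
    """Repeated stratified holdout estimate of derived-classifier AUC.

    Each repetition holds out a stratified ``holdout`` fraction, runs the
    complete derivation (CFGCs -> baseline -> gene selection -> clustering
    -> reduction -> cluster subset -> final fit) on the remaining samples
    only, then scores the held-out samples with the freshly derived model.
    Returns per-repetition AUCs and the pooled AUC over all held-out scores.
    """
    from sklearn.model_selection import StratifiedShuffleSplit

    from .pipeline import derive, score_dataset

    if reps < 1:
        raise ValueError("reps must be >= 1")
    y = d.phenotypes.column("cancer_status").to_numpy(dtype=int)
    sss = StratifiedShuffleSplit(n_splits=reps, test_size=holdout,
                                 random_state=seed)
    per_rep, pooled_scores, pooled_truth, held = [], [], [], []
    sample_ids = np.asarray(d.sample_ids)
    for rep, (tr, te) in enumerate(sss.split(np.zeros(len(y)), y)):
        train = Dataset(d.expression.subset_samples(sample_ids[tr]),
                        d.phenotypes.subset(sample_ids[tr]))
        result = derive(train, pipeline_config, seed=seed + rep + 1)
        test_expr = d.expression.subset_samples(sample_ids[te])
        test_age = d.phenotypes.subset(sample_ids[te]).column("age")
        scores = score_dataset(test_expr, test_age, result.model)
        auc, _ = delong_auc_variance(scores.to_numpy(), y[te])
        per_rep.append(auc)
        pooled_scores.append(scores.to_numpy())
        pooled_truth.append(y[te])
        held.append(te)
    pooled_auc, _ = delong_auc_variance(np.concatenate(pooled_scores),
                                        np.concatenate(pooled_truth))
    return CvResult(per_rep_auc=per_rep, pooled_auc=float(pooled_auc),
                    holdout_indices=held)


def performance_table(truth, bronch_diagnostic, classifier_call,
                      strata: pd.Series | None = None) -> pd.DataFrame:
    """Bronchoscopy / classifier / combined sensitivity rows, optionally
    stratified (by histology, stage, or mass size)."""
    y = np.asarray(truth, dtype=int)
    b = np.asarray(bronch_diagnostic, dtype=int)
    c = np.asarray(classifier_call, dtype=int)
    combined = combine_with_bronchoscopy(b, c)
    groups = {"all": np.ones_like(y, dtype=bool)}
    if strata is not None:
        for level in pd.unique(strata):
            groups[str(level)] = (strata == level).to_numpy()
    rows = []
    for name, mask in groups.items():
        cancers = mask & (y == 1)
        n = int(cancers.sum())
        if n == 0:
            continue
        nondx = cancers & (b == 0)
        rows.append({
            "stratum": name, "N": n,
            "bronchoscopy_sensitivity_pct": _pct(b[cancers].mean()),
            "classifier_sensitivity_pct":
                _pct(c[nondx].mean()) if nondx.any() else None,
            "combined_sensitivity_pct": _pct(combined[cancers].mean()),
        })
    return pd.DataFrame(rows)
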