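"""Clinical-Factor Gene-expression Correlates (CFGCs).

Three small sub-models predict clinical covariates from expression alone, and
their outputs — genomic gender (GG), genomic smoking status (GS), genomic
pack-years (GPY) — replace the reported covariates as classifier features:

* GG: a single-gene threshold rule; the published model calls a patient
  female (GG = 1) when RPS4Y1 log2 expression < 7.5 (a Y-linked transcript,
  essentially bimodal by sex).
* GS: logistic in SLC7A11, CLND10 and TKT; GS in (0, 1) rises toward
  current smoking.
* GPY: logistic in RUNX1T1 and AKR1C2; GPY in (0, 1) rises toward heavier
  cumulative exposure (pack-years dichotomized at 10 during derivation).

This module provides both the locked published formulas (pure functions of
the named genes) and the derivation path: empirical-Bayes gene ranking at
p < 0.001 followed by an L1-penalized (LASSO) logistic fit over the
candidates, with an unpenalized refit on the surviving genes so the final
sub-model has the plain logistic form of the published formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .cohort_io import Dataset, ExpressionMatrix
from .stats_core import moderated_t

__all__ = [
    "CfgcModel",
    "FACTOR_POSITIVE",
    "factor_response",
    "select_covariate_genes",
    "fit_cfgc",
    "apply_cfgc",
    "genomic_gender",
    "genomic_smoking",
    "genomic_pack_years",
    "LOCKED_GG",
    "LOCKED_GS",
    "LOCKED_GPY",
]

# Positive class per clinical factor (the level coded 1).
FACTOR_POSITIVE = {
    "sex": "female",
    "smoking_status": "current",
    "pack_years": ">10",
}

# The published sub-model parameterizations.
LOCKED_GG = {"type": "threshold", "gene": "RPS4Y1", "cutpoint": 7.5,
             "positive_if": "below"}
LOCKED_GS = {"type": "logistic", "intercept": 40.8579,
             "coefficients": {"SLC7A11": -0.4462, "CLND10": -2.1298,
                              "TKT": -1.8256}}
LOCKED_GPY = {"type": "logistic", "intercept": -5.1429,
              "coefficients": {"RUNX1T1": 2.1891, "AKR1C2": -0.9506}}


@dataclass(frozen=True)
class CfgcModel:
    """A fitted CFGC: either a plain logistic form or a threshold rule."""

    factor: str
    genes: list[str]
    intercept: float | None = None
    coefficients: dict[str, float] | None = None
    cutpoint: float | None = None
    positive_if: str | None = None   # "below" | "above" (threshold rules)
    training_auc: float = float("nan")

    def __post_init__(self) -> None:
        logistic = self.coefficients is not None
        rule = self.cutpoint is not None
        if logistic == rule:
            raise ValueError("exactly one of coefficients / threshold rule "
                             "must be present")
        if not self.genes:
            raise ValueError("a CFGC must use at least one gene")

    @property
    def is_threshold_rule(self) -> bool:
        return self.cutpoint is not None

    def to_sub_model(self) -> dict:
        """The serializable form embedded in a classifier document."""
        if self.is_threshold_rule:
            return {"type": "threshold", "gene": self.genes[0],
                    "cutpoint": self.cutpoint,
                    "positive_if": self.positive_if}
        return {"type": "logistic", "intercept": self.intercept,
                "coefficients": dict(self.coefficients)}


def factor_response(d: Dataset, factor: str) -> np.ndarray:
    """Binary 0/1 response vector for a clinical factor.

    Pack-years are dichotomized at 10 (> 10 coded 1).
    """
    ph = d.phenotypes
    if factor == "sex":
        return (ph.column("sex").to_numpy() == "female").astype(int)
    if factor == "smoking_status":
        return (ph.column("smoking_status").to_numpy() == "current").astype(int)
    if factor == "pack_years":
        return (ph.column("pack_years").to_numpy(dtype=float) > 10.0).astype(int)
    raise ValueError(f"unknown clinical factor {factor!r}")


def select_covariate_genes(
    d: Dataset,
    factor: str,
    p_cut: float = 0.001,
    min_genes: int = 0,
) -> pd.DataFrame:
    """Genes associated with a clinical factor at moderated-t p < p_cut.

    Returns a frame indexed by gene with columns ``t`` and ``p``, ranked by
    p-value.  ``min_genes`` keeps at least that many top-ranked genes even
    when fewer pass the cutoff (used by the pipeline on weak cohorts).
    Raises on a factor constant in the cohort.
    """
    y = factor_response(d, factor)
    if y.min() == y.max():
        raise ValueError(f"clinical factor {factor!r} is constant in cohort")
    res = moderated_t(d.expression, y)
    frame = res.as_frame()[["t", "p"]].sort_values("p", kind="mergesort")
    hits = frame[frame["p"] < p_cut]
    if len(hits) < min_genes:
        hits = frame.iloc[:min_genes]
    return hits


def _threshold_rule(values: np.ndarray, y: np.ndarray, gene: str,
                    factor: str) -> CfgcModel:
    pos, neg = values[y == 1], values[y == 0]
    if pos.mean() < neg.mean():
        cut = (pos.max() + neg.min()) / 2.0
        direction = "below"
    else:
        cut = (neg.max() + pos.min()) / 2.0
        direction = "above"
    return CfgcModel(factor=factor, genes=[gene], cutpoint=float(cut),
                     positive_if=direction, training_auc=1.0)


def fit_cfgc(
    d: Dataset,
    factor: str,
    candidate_genes: list[str],
    n_genes: int | None = None,
    cv_folds: int = 10,
    seed: int = 0,
) -> CfgcModel:
    """Derive one CFGC from candidate genes by LASSO logistic regression.

    The L1 penalty is chosen by K-fold cross-validated deviance over a
    logarithmic grid; when ``n_genes`` is given, the grid is restricted to
    penalties whose fitted support has exactly that size when possible
    (nearest size otherwise).  The selected genes are then refit without
    penalty so the reported intercept/coefficients have the plain logistic
    form of the published formulas.  If the top-ranked candidate separates
    the factor perfectly (the Y-linked-gene case for sex) a single-gene
    threshold rule is returned instead.
    """
    if not candidate_genes:
        raise ValueError("candidate gene list is empty")
    y = factor_response(d, factor)
    if y.min() == y.max():
        raise ValueError(f"clinical factor {factor!r} is constant in cohort")

    top = candidate_genes[0]
    top_vals = d.expression.gene(top)
    if roc_auc_score(y, top_vals) in (0.0, 1.0):
        return _threshold_rule(top_vals, y, top, factor)

    X = d.expression.subset_genes(candidate_genes).values.T  # samples x genes
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    def lasso_support(C: float) -> np.ndarray:
        clf = LogisticRegression(solver="liblinear", l1_ratio=1.0, C=C,
                                 max_iter=5000)
        clf.fit(Z, y)
        return np.flatnonzero(np.abs(clf.coef_[0]) > 1e-8)

    Cs = list(np.logspace(-3, 2, 40))
    supports: dict[float, np.ndarray] = {C: lasso_support(C) for C in Cs}
    sizes = {C: s.size for C, s in supports.items()}

    if n_genes is not None and n_genes not in sizes.values():
        # refine the penalty by bisection toward the requested support size
        grid = sorted(sizes)
        for lo, hi in zip(grid, grid[1:]):
            if sizes[lo] < n_genes < sizes[hi]:
                for _ in range(30):
                    mid = float(np.sqrt(lo * hi))
                    smid = lasso_support(mid)
                    supports[mid] = smid
                    sizes[mid] = smid.size
                    if smid.size == n_genes:
                        break
                    if smid.size < n_genes:
                        lo = mid
                    else:
                        hi = mid
                break

    usable = [C for C, k in sizes.items() if k > 0]
    if not usable:
        C0 = max(sizes)
        supports[C0] = np.array([candidate_genes.index(top)])
        usable = [C0]
    if n_genes is not None:
        best_gap = min(abs(sizes.get(C, 0) - n_genes) for C in usable)
        usable = [C for C in usable
                  if abs(sizes.get(C, 0) - n_genes) == best_gap]

    # cross-validated deviance over the remaining penalty grid
    n_splits = min(cv_folds, int(np.bincount(y).min()))
    if n_splits >= 2 and len(usable) > 1:
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                              random_state=seed)
        cv_dev = {}
        for C in usable:
            dev = 0.0
            for tr, te in skf.split(Z, y):
                clf = LogisticRegression(solver="liblinear", l1_ratio=1.0,
                                         C=C, max_iter=5000)
                clf.fit(Z[tr], y[tr])
                p = clf.predict_proba(Z[te])[:, 1]
                dev += log_loss(y[te], p, labels=[0, 1]) * te.size
            cv_dev[C] = dev
        best_C = min(usable, key=lambda C: (cv_dev[C], C))
    else:
        best_C = usable[0]

    idx = supports[best_C]
    genes = [candidate_genes[j] for j in idx]
    Xsel = X[:, idx]

    # unpenalized refit on the surviving genes
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, sm.add_constant(Xsel)).fit(disp=0, maxiter=200)
            params = np.asarray(fit.params, dtype=float)
            if not np.isfinite(params).all() or np.abs(params).max() > 1e4:
                raise RuntimeError("diverging refit")
            intercept, coefs = float(params[0]), params[1:]
            probs = fit.predict(sm.add_constant(Xsel))
        except Exception:
            # quasi-separation: fall back to a very lightly penalized refit
            clf = LogisticRegression(solver="lbfgs", l1_ratio=0.0, C=1e6,
                                     max_iter=10000)
            clf.fit(Xsel, y)
            intercept = float(clf.intercept_[0])
            coefs = clf.coef_[0]
            probs = clf.predict_proba(Xsel)[:, 1]
    return CfgcModel(
        factor=factor, genes=genes, intercept=intercept,
        coefficients={g: float(b) for g, b in zip(genes, coefs)},
        training_auc=float(roc_auc_score(y, probs)))


def apply_cfgc(model: CfgcModel, expr: ExpressionMatrix) -> np.ndarray:
    """Per-sample CFGC value: {0,1} for threshold rules, (0,1) otherwise."""
    from .classifier import _apply_cfgc

    return _apply_cfgc(model.to_sub_model(), expr)


# ---------------------------------------------------------------------------
# locked published formulas
# ---------------------------------------------------------------------------

def _check_finite(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError(f"non-finite {name} expression value")
    return arr


def genomic_gender(rps4y1) -> np.ndarray | int:
    """GG = 1 (female) iff RPS4Y1 log2 expression < 7.5 (strict)."""
    v = _check_finite("RPS4Y1", rps4y1)
    out = (v < LOCKED_GG["cutpoint"]).astype(int)
    return int(out) if np.ndim(rps4y1) == 0 else out


def genomic_smoking(slc7a11, clnd10, tkt):
    """GS in (0,1): logistic of the published three-gene linear form."""
    c = LOCKED_GS["coefficients"]
    x = (LOCKED_GS["intercept"]
         + c["SLC7A11"] * _check_finite("SLC7A11", slc7a11)
         + c["CLND10"] * _check_finite("CLND10", clnd10)
         + c["TKT"] * _check_finite("TKT", tkt))
    out = 1.0 / (1.0 + np.exp(-x))
    return float(out) if np.ndim(x) == 0 else out


def genomic_pack_years(runx1t1, akr1c2):
    """GPY in (0,1): logistic of the published two-gene linear form."""
    c = LOCKED_GPY["coefficients"]
    x = (LOCKED_GPY["intercept"]
         + c["RUNX1T1"] * _check_finite("RUNX1T1", runx1t1)
         + c["AKR1C2"] * _check_finite("AKR1C2", akr1c2))
    out = 1.0 / (1.0 + np.exp(-x))
    return float(out) if np.ndim(x) == 0 else out
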