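"""The lung-cancer classifier: locked scorer and differential-penalty fit.

The final model is a logistic regression on ten features:

    score = 1 / (1 + exp(-y)),   y = b0 + sum_i b_i * x_i

with features Age (years, unscaled), the three clinical-factor gene-expression
correlates GG / GS / GPY (see :mod:`airwaydx.cfgc`), and six cancer-cluster
means CA1, CA2, CA4, CA7, CA9, CA10 — each the arithmetic mean of the log2
expression of 2-4 representative genes.  A sample is called cancer-positive
when score >= 0.65 (boundary inclusive).

The published coefficient set ships as a package resource
(:func:`locked_model`); :func:`fit_final` re-derives such a model from a
feature table using ridge-type penalized logistic regression with per-feature
penalty factors (0 for the clinical correlates and age, 10 for each cluster
mean, applied to standardized cluster features against the summed
log-likelihood).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources as _resources

import numpy as np
import pandas as pd
from scipy import optimize, special

from .cohort_io import ExpressionMatrix, SchemaError

__all__ = [
    "LockedClassifier",
    "locked_model",
    "cluster_means",
    "compute_features",
    "score",
    "classify",
    "fit_final",
    "choose_threshold",
    "FEATURE_ORDER",
]

FEATURE_ORDER = ("Age", "GG", "GS", "GPY",
                 "CA1", "CA2", "CA4", "CA7", "CA9", "CA10")


@dataclass(frozen=True)
class LockedClassifier:
    """A complete, serializable classifier parameterization."""

    intercept: float
    coefficients: dict[str, float]          # feature -> b_i
    clusters: dict[str, list[str]]          # CA name -> member genes
    cfgc: dict[str, dict]                   # GG/GS/GPY sub-model definitions
    threshold: float = 0.65
    reference_means: dict[str, float] | None = None
    name: str = "classifier"
    schema_version: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise SchemaError("decision threshold must be in (0, 1)")
        for feat, b in self.coefficients.items():
            if not math.isfinite(b):
                raise SchemaError(f"non-finite coefficient for {feat!r}")
        for ca in self.clusters:
            if ca not in self.coefficients:
                raise SchemaError(f"cluster {ca!r} has no coefficient")

    @property
    def feature_names(self) -> list[str]:
        return list(self.coefficients)

    @property
    def cancer_genes(self) -> list[str]:
        return [g for members in self.clusters.values() for g in members]

    @property
    def cfgc_genes(self) -> list[str]:
        out: list[str] = []
        for sub in self.cfgc.values():
            if sub["type"] == "threshold":
                out.append(sub["gene"])
            else:
                out.extend(sub["coefficients"])
        return out

    @property
    def all_genes(self) -> list[str]:
        return self.cfgc_genes + self.cancer_genes

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "name": self.name,
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "clusters": {k: list(v) for k, v in self.clusters.items()},
            "cfgc": self.cfgc,
            "threshold": self.threshold,
            "reference_means": self.reference_means,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "LockedClassifier":
        version = doc.get("schema_version")
        if version != 1:
            raise SchemaError(f"unsupported model schema version: {version!r}")
        required = ("intercept", "coefficients", "clusters", "cfgc",
                    "threshold")
        missing = [k for k in required if k not in doc]
        if missing:
            raise SchemaError(f"model document missing fields: {missing}")
        return cls(
            intercept=float(doc["intercept"]),
            coefficients={k: float(v)
                          for k, v in doc["coefficients"].items()},
            clusters={k: list(v) for k, v in doc["clusters"].items()},
            cfgc=doc["cfgc"],
            threshold=float(doc["threshold"]),
            reference_means=doc.get("reference_means"),
            name=doc.get("name", "classifier"),
        )


def locked_model() -> LockedClassifier:
    """The published 23-feature classifier, shipped as a package resource.

    Its training-set reference means were never published, so
    ``reference_means`` is ``None``: scoring a cohort from another platform
    requires a user-supplied reference (see :mod:`airwaydx.cross_platform`).
    """
    text = (_resources.files("airwaydx") / "resources"
            / "locked_model.json").read_text()
    return LockedClassifier.from_dict(json.loads(text))


def cluster_means(expr: ExpressionMatrix, memberships: dict[str, list[str]]
                  ) -> pd.DataFrame:
    """Per-sample arithmetic mean of each cluster's member genes.

    Raises ``KeyError`` naming the first missing member gene; run the
    cross-platform imputation first if the matrix lacks model genes.
    """
    cols = {}
    for ca, members in memberships.items():
        vals = np.vstack([expr.gene(g) for g in members])
        cols[ca] = vals.mean(axis=0)
    return pd.DataFrame(cols, index=pd.Index(expr.sample_ids,
                                             name="sample_id"))


def _apply_cfgc(sub: dict, expr: ExpressionMatrix) -> np.ndarray:
    if sub["type"] == "threshold":
        vals = expr.gene(sub["gene"])
        below = vals < sub["cutpoint"]
        positive = below if sub["positive_if"] == "below" else ~below
        return positive.astype(float)
    x = np.full(len(expr.sample_ids), float(sub["intercept"]))
    for gene, coef in sorted(sub["coefficients"].items()):
        x = x + coef * expr.gene(gene)
    return special.expit(x)


def compute_features(expr: ExpressionMatrix, age: pd.Series,
                     model: LockedClassifier) -> pd.DataFrame:
    """Assemble the model's feature vector table from expression + age."""
    feats = pd.DataFrame(index=pd.Index(expr.sample_ids, name="sample_id"))
    feats["Age"] = age.reindex(expr.sample_ids).to_numpy(dtype=float)
    if feats["Age"].isna().any():
        missing = feats.index[feats["Age"].isna()].tolist()
        raise ValueError(f"age missing for samples: {missing}")
    for name, sub in model.cfgc.items():
        feats[name] = _apply_cfgc(sub, expr)
    ca = cluster_means(expr, model.clusters)
    for col in ca.columns:
        feats[col] = ca[col]
    return feats


def score(features, model: LockedClassifier):
    """Logistic score of a feature table (or a single mapping) in (0, 1)."""
    single = isinstance(features, dict)
    fv = pd.DataFrame([features]) if single else pd.DataFrame(features)
    missing = [f for f in model.feature_names if f not in fv.columns]
    if missing:
        raise KeyError(f"feature vector missing features: {missing}")
    y = np.full(len(fv), model.intercept)
    # canonical (sorted) accumulation order: scores are bit-identical no
    # matter how the coefficient mapping happens to be ordered on disk
    for feat, b in sorted(model.coefficients.items()):
        vals = fv[feat].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError(f"non-finite value in feature {feat!r}")
        y = y + b * vals
    out = special.expit(y)
    if single:
        return float(out[0])
    return pd.Series(out, index=fv.index, name="score")


def classify(scores, threshold: float = 0.65):
    """Cancer-positive iff score >= threshold (boundary inclusive)."""
    arr = np.asarray(scores, dtype=float)
    calls = (arr >= threshold).astype(int)
    if np.ndim(scores) == 0:
        return int(calls)
    if isinstance(scores, pd.Series):
        return pd.Series(calls, index=scores.index, name="call")
    return calls


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FinalFit:
    """Result of a differential-penalty logistic fit, in original units."""

    intercept: float
    coefficients: pd.Series
    penalties: pd.Series
    converged: bool
    n_iter: int
    objective: float = field(default=float("nan"))


def _neg_loglik_grad(beta: np.ndarray, X: np.ndarray, y: np.ndarray,
                     lam: np.ndarray) -> tuple[float, np.ndarray]:
    eta = X @ beta
    # summed negative log-likelihood + sum_j lam_j beta_j^2
    nll = float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)
    p = special.expit(eta)
    grad = X.T @ (p - y) + 2.0 * lam * beta
    return nll + float(lam @ beta**2), grad


def fit_final(
    features: pd.DataFrame,
    status,
    penalty_covariates: float = 0.0,
    penalty_clusters: float = 10.0,
    cluster_features: list[str] | None = None,
    penalty: str = "l2",
    tol: float = 1e-10,
    max_iter: int = 20000,
) -> FinalFit:
    """Penalized logistic regression with per-feature penalty factors.

    Cluster-mean features are standardized before penalization (the penalty
    applies to coefficients on the standardized scale, against the summed
    log-likelihood) and the fitted coefficients are transformed back to the
    original units.  ``penalty="l2"`` (default) uses a squared penalty
    ``sum_j lam_j beta_j^2`` solved by L-BFGS; ``penalty="l1"`` uses
    ``sum_j lam_j |beta_j|`` solved by proximal gradient (FISTA).
    """
    y = np.asarray(status, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("status must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    if cluster_features is None:
        cluster_features = [c for c in features.columns if c.startswith("CA")]
    cols = list(features.columns)
    X = features.to_numpy(dtype=float)
    n, p = X.shape

    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    if (scale == 0).any():
        bad = [cols[j] for j in np.flatnonzero(scale == 0)]
        raise ValueError(f"constant feature(s): {bad}")
    Z = (X - center) / scale
    Zd = np.hstack([np.ones((n, 1)), Z])

    lam = np.zeros(p + 1)
    for j, c in enumerate(cols):
        lam[j + 1] = (penalty_clusters if c in cluster_features
                      else penalty_covariates)

    beta0 = np.zeros(p + 1)
    beta0[0] = special.logit(np.clip(y.mean(), 1e-6, 1 - 1e-6))

    if penalty == "l2":
        res = optimize.minimize(
            _neg_loglik_grad, beta0, args=(Zd, y, lam), jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-15})
        beta = res.x
        converged = bool(res.success)
        n_iter = int(res.nit)
        objective = float(res.fun)
        if not converged and np.linalg.norm(res.jac) > 1e-4:
            raise RuntimeError(
                f"penalized logistic fit did not converge: {res.message} "
                f"(|grad| = {np.linalg.norm(res.jac):.3g})")
    elif penalty == "l1":
        beta, n_iter, converged = _fista_l1(Zd, y, lam, beta0, max_iter)
        eta = Zd @ beta
        objective = float(np.sum(np.logaddexp(0.0, eta)) - y @ eta
                          + lam @ np.abs(beta))
        if not converged:
            raise RuntimeError("l1 penalized logistic fit did not converge")
    else:
        raise ValueError(f"unknown penalty {penalty!r}")

    # back-transform to original units
    coefs = beta[1:] / scale
    intercept = float(beta[0] - coefs @ center)
    return FinalFit(
        intercept=intercept,
        coefficients=pd.Series(coefs, index=cols, name="coefficient"),
        penalties=pd.Series(lam[1:], index=cols, name="penalty"),
        converged=converged, n_iter=n_iter, objective=objective)


def _fista_l1(X: np.ndarray, y: np.ndarray, lam: np.ndarray,
              beta0: np.ndarray, max_iter: int
              ) -> tuple[np.ndarray, int, bool]:
    """Proximal gradient with Nesterov acceleration for l1 penalties."""
    # Lipschitz constant of the logistic gradient: ||X||^2 / 4
    L = float(np.linalg.norm(X, 2) ** 2) / 4.0
    step = 1.0 / L
    beta = beta0.copy()
    z = beta.copy()
    t = 1.0
    for it in range(max_iter):
        eta = X @ z
        grad = X.T @ (special.expit(eta) - y)
        w = z - step * grad
        new = np.sign(w) * np.maximum(np.abs(w) - step * lam, 0.0)
        t_new = (1.0 + math.sqrt(1.0 + 4.0 * t * t)) / 2.0
        z = new + (t - 1.0) / t_new * (new - beta)
        delta = np.max(np.abs(new - beta))
        beta, t = new, t_new
        if delta < 1e-10:
            return beta, it + 1, True
    return beta, max_iter, False


def choose_threshold(
    scores,
    status,
    subgroup_mask=None,
    target_sensitivity: float = 0.90,
) -> float:
    """Largest threshold whose subgroup sensitivity meets the target.

    The subgroup defaults to all samples; the intended use restricts it to
    patients with a non-diagnostic bronchoscopy.  With ``m`` subgroup cancers
    the returned threshold is the ``ceil(target * m)``-th largest cancer
    score, the largest cutoff at which at least that many cancers are called
    positive (calls use score >= threshold).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(status, dtype=int)
    mask = (np.ones_like(y, dtype=bool) if subgroup_mask is None
            else np.asarray(subgroup_mask, dtype=bool))
    cancers = np.sort(s[mask & (y == 1)])[::-1]
    m = cancers.size
    if m == 0:
        raise ValueError("subgroup contains no cancer-positive samples")
    k = math.ceil(target_sensitivity * m)
    if k > m:
        import warnings

        warnings.warn("target sensitivity unattainable; returning the "
                      "minimum cancer score", stacklevel=2)
        k = m
    return float(cancers[k - 1])
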