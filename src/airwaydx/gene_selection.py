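"""Selection, clustering and reduction of cancer-associated genes.

The derivation isolates expression signal that is *orthogonal* to the
clinical picture: a baseline logistic model predicts cancer status from the
genomic covariates (GG, GS, GPY) and age, and genes are then ranked by the
empirical-Bayes moderated t of regressing the baseline's response residuals
(observed status minus fitted probability) on each gene's expression.  Genes
exceeding the |T| > 2.7 criterion are grouped by average-linkage hierarchical
clustering on the correlation distance 1 - r, each cluster is reduced to 2-4
representative genes whose running mean tracks the full cluster mean, and a
forward cross-validated search picks which cluster means earn a place in the
final classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit

from .cohort_io import Dataset
from .stats_core import moderated_t

__all__ = [
    "SeparationError",
    "BaselineModel",
    "GeneClusterSet",
    "fit_baseline",
    "select_cancer_genes",
    "cluster_genes",
    "reduce_cluster",
    "select_cluster_subset",
]


class SeparationError(RuntimeError):
    """The baseline logistic fit is perfectly separated.

    Raised rather than silently reporting infinite coefficients; a
    penalized fit of the final model is the recommended fallback.
    """


@dataclass(frozen=True)
class BaselineModel:
    """Clinical/genomic-covariate-only logistic model and its residuals."""

    params: pd.Series                 # intercept + coefficients
    fitted: np.ndarray                # per-sample fitted probability
    residuals: np.ndarray             # observed status - fitted probability

    def __post_init__(self) -> None:
        if ((self.fitted <= 0) | (self.fitted >= 1)).any():
            raise ValueError("fitted probabilities must lie in (0, 1)")


@dataclass
class GeneClusterSet:
    """Clustered cancer genes with representatives and the retained subset."""

    t_scores: pd.Series                       # signed moderated T per gene
    assignments: pd.Series                    # gene -> integer cluster label
    representatives: dict[int, list[str]] = field(default_factory=dict)
    representative_r: dict[int, float] = field(default_factory=dict)
    chosen_clusters: list[int] = field(default_factory=list)


def fit_baseline(d: Dataset, cov: pd.DataFrame) -> BaselineModel:
    """Maximum-likelihood logistic fit of cancer status on GG/GS/GPY/age.

    ``cov`` must carry columns GG, GS, GPY aligned to the dataset's samples;
    age is taken from the phenotype table.  Exposes response residuals
    (observed - fitted), the quantity the gene selection regresses on.
    """
    y = d.phenotypes.column("cancer_status").to_numpy(dtype=int)
    if y.min() == y.max():
        raise ValueError("both cancer classes must be present")
    X = pd.DataFrame({
        "GG": cov["GG"].to_numpy(dtype=float),
        "GS": cov["GS"].to_numpy(dtype=float),
        "GPY": cov["GPY"].to_numpy(dtype=float),
        "Age": d.phenotypes.column("age").to_numpy(dtype=float),
    }, index=d.sample_ids)
    Xd = sm.add_constant(X)
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # overflow under separation
            fit = sm.Logit(y, Xd).fit(disp=0, maxiter=200)
    except Exception as exc:
        raise SeparationError(
            f"baseline logistic fit failed ({exc}); consider a penalized "
            "fit") from exc
    params = np.asarray(fit.params, dtype=float)
    fitted = np.asarray(fit.predict(Xd), dtype=float)
    if (not np.isfinite(params).all() or np.abs(params).max() > 1e4
            or fitted.min() <= 1e-12 or fitted.max() >= 1 - 1e-12):
        raise SeparationError(
            "baseline covariates separate the classes perfectly; use a "
            "penalized fit instead")
    return BaselineModel(
        params=pd.Series(params, index=Xd.columns, name="coefficient"),
        fitted=fitted, residuals=y - fitted)


def select_cancer_genes(d: Dataset, residuals, t_cut: float = 2.7
                        ) -> pd.Series:
    """Genes whose moderated |T| against the baseline residuals exceeds t_cut.

    Each gene's expression is the independent variable and the residual
    vector the dependent variable, so a gene whose cancer association is
    fully explained by the clinical covariates scores near zero.  Returns
    the signed T scores, strongest first.
    """
    res = moderated_t(d.expression, residuals, gene_as_predictor=True)
    t = pd.Series(res.t, index=res.gene_ids, name="T")
    hits = t[np.abs(t) > t_cut]
    return hits.iloc[np.argsort(-np.abs(hits.to_numpy()), kind="stable")]


def cluster_genes(d: Dataset, genes: list[str], n_clusters: int = 11
                  ) -> pd.Series:
    """Partition genes by average-linkage clustering on 1 - Pearson r.

    The tree is cut to the configured cluster count.  Signed correlation is
    used, so anti-correlated genes (up- vs down-regulated modules) land in
    different clusters.  Genes are processed in sorted order and labels
    assigned deterministically (clusters numbered by decreasing size, ties
    by alphabetically first member), so the result is invariant to input
    order.
    """
    genes = sorted(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to cluster")
    if len(genes) < n_clusters:
        raise ValueError(f"cannot form {n_clusters} clusters from "
                         f"{len(genes)} genes")
    X = d.expression.subset_genes(genes).values
    r = np.corrcoef(X)
    dist = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    # deterministic relabeling: by decreasing size, tie-break on first member
    order = sorted(
        set(raw),
        key=lambda lab: (-int(np.sum(raw == lab)),
                         min(g for g, l in zip(genes, raw) if l == lab)))
    remap = {lab: i + 1 for i, lab in enumerate(order)}
    return pd.Series([remap[l] for l in raw], index=pd.Index(genes, name="gene"),
                     name="cluster")


def reduce_cluster(
    d: Dataset,
    cluster_genes_: list[str],
    k_max: int = 4,
    r_target: float = 0.95,
) -> tuple[list[str], float]:
    """Greedy 2-4 gene representative subset for one cluster.

    Starts from the gene most correlated with the full cluster mean, then
    repeatedly adds the gene that maximizes the correlation of the running
    subset mean with the cluster mean, stopping once the correlation reaches
    ``r_target`` (but never before 2 genes) or ``k_max`` genes are used.
    Returns the representatives and the achieved correlation.
    """
    genes = list(cluster_genes_)
    if len(genes) < 2:
        raise ValueError("cluster must contain at least 2 genes")
    X = d.expression.subset_genes(genes).values   # genes x samples
    target = X.mean(axis=0)

    def corr_with_target(v: np.ndarray) -> float:
        vs, ts = v - v.mean(), target - target.mean()
        denom = np.sqrt((vs @ vs) * (ts @ ts))
        return 1.0 if denom == 0 else float(vs @ ts / denom)

    chosen: list[int] = []
    remaining = list(range(len(genes)))
    while len(chosen) < min(k_max, len(genes)):
        best_j, best_r = None, -np.inf
        for j in remaining:
            subset = X[chosen + [j]].mean(axis=0)
            rj = corr_with_target(subset)
            if rj > best_r:
                best_j, best_r = j, rj
        chosen.append(best_j)
        remaining.remove(best_j)
        if len(chosen) >= 2 and best_r >= r_target:
            break
    reps = [genes[j] for j in chosen]
    achieved = corr_with_target(X[chosen].mean(axis=0))
    return reps, achieved


def _cv_auc(
    features: pd.DataFrame,
    y: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    penalty_clusters: float,
) -> np.ndarray:
    """Per-fold holdout AUCs of the differential-penalty fit."""
    from .classifier import fit_final

    aucs = []
    for tr, te in folds:
        fit = fit_final(features.iloc[tr], y[tr],
                        penalty_clusters=penalty_clusters, tol=1e-8)
        eta = (fit.intercept
               + features.iloc[te].to_numpy(dtype=float)
               @ fit.coefficients.to_numpy())
        aucs.append(roc_auc_score(y[te], eta))
    return np.asarray(aucs)


def select_cluster_subset(
    d: Dataset,
    representatives: dict[int, list[str]],
    cov: pd.DataFrame,
    reps: int = 100,
    holdout: float = 0.10,
    seed: int = 0,
    penalty_clusters: float = 10.0,
    exhaustive: bool = False,
) -> tuple[list[int], float]:
    """Choose which cluster means join the covariates in the final model.

    Candidate cluster means (means of each cluster's representative genes)
    are added to the GG/GS/GPY/age covariates by forward selection, scored
    by repeated stratified 10% holdout CV AUC of the differential-penalty
    fit; the same fold assignments are reused for every candidate so
    comparisons are paired.  A cluster joins the model only when its paired
    per-fold AUC improvement is significant (one-sided paired t, p < 0.01):
    a cluster must be independently informative in the context of the
    clusters already included, not merely improve the point estimate —
    a plain any-improvement rule demonstrably admits noise clusters.
    Ties break toward fewer clusters, then lower cluster index.
    ``exhaustive=True`` searches all subsets by mean CV AUC instead
    (feasible only for small cluster counts).  Returns the chosen cluster
    ids and their CV AUC.
    """
    y = d.phenotypes.column("cancer_status").to_numpy(dtype=int)
    base = pd.DataFrame({
        "GG": cov["GG"].to_numpy(dtype=float),
        "GS": cov["GS"].to_numpy(dtype=float),
        "GPY": cov["GPY"].to_numpy(dtype=float),
        "Age": d.phenotypes.column("age").to_numpy(dtype=float),
    }, index=d.sample_ids)
    means = pd.DataFrame({
        c: d.expression.subset_genes(g).values.mean(axis=0)
        for c, g in representatives.items()}, index=d.sample_ids)

    sss = StratifiedShuffleSplit(n_splits=reps, test_size=holdout,
                                 random_state=seed)
    folds = [(tr, te) for tr, te in sss.split(np.zeros(len(y)), y)]

    def evaluate(subset: tuple[int, ...]) -> np.ndarray:
        feats = base.copy()
        for c in subset:
            feats[f"CA{c}"] = means[c]
        return _cv_auc(feats, y, folds, penalty_clusters)

    if exhaustive:
        from itertools import combinations

        best_subset, best_auc = (), float(evaluate(()).mean())
        ids = sorted(representatives)
        for k in range(1, len(ids) + 1):
            for comb in combinations(ids, k):
                auc = float(evaluate(comb).mean())
                if auc > best_auc:
                    best_subset, best_auc = comb, auc
        return list(best_subset), best_auc

    chosen: list[int] = []
    current = evaluate(())
    remaining = sorted(representatives)
    while remaining:
        cand = [(evaluate(tuple(chosen + [c])), c) for c in remaining]
        best_aucs, best_c = max(cand, key=lambda t: (t[0].mean(), -t[1]))
        diffs = best_aucs - current
        if diffs.size > 1 and diffs.std(ddof=1) > 0:
            from scipy import stats as _st

            tstat = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(diffs.size))
            significant = _st.t.sf(tstat, diffs.size - 1) < 0.01
        else:
            significant = diffs.mean() > 0
        if significant:
            chosen.append(best_c)
            remaining.remove(best_c)
            current = best_aucs
        else:
            break
    return sorted(chosen), float(current.mean())
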