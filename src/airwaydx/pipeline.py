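"""End-to-end derivation pipeline and scoring helpers.

:func:`derive` runs the complete multi-step derivation on a training
dataset — CFGC sub-models, the clinical baseline, residual-based cancer-gene
selection, correlation clustering, cluster reduction, cross-validated
cluster-subset search, the differential-penalty final fit, and the
sensitivity-targeted decision threshold — and packages the outcome as a
:class:`~airwaydx.classifier.LockedClassifier` of the same schema as the
published model, with per-gene training means attached for later
cross-platform use.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cfgc import CfgcModel, apply_cfgc, fit_cfgc, select_covariate_genes
from .classifier import (FinalFit, LockedClassifier, choose_threshold,
                         compute_features, fit_final, score)
from .cohort_io import Dataset, ExpressionMatrix
from .gene_selection import (BaselineModel, GeneClusterSet, cluster_genes,
                             fit_baseline, reduce_cluster,
                             select_cancer_genes, select_cluster_subset)

__all__ = ["PipelineConfig", "DerivationResult", "derive", "score_dataset",
           "clinical_model_scores"]

log = logging.getLogger("airwaydx")

_FACTORS = ("sex", "smoking_status", "pack_years")
_FACTOR_TO_FEATURE = {"sex": "GG", "smoking_status": "GS",
                      "pack_years": "GPY"}


@dataclass
class PipelineConfig:
    """Derivation thresholds; the defaults are the published ones."""

    p_cut: float = 0.001              # CFGC gene selection p cutoff
    t_cut: float = 2.7                # cancer-gene moderated |T| cutoff
    n_clusters: int = 11              # dendrogram cut target
    k_max: int = 4                    # max representatives per cluster
    r_target: float = 0.95            # subset-mean vs cluster-mean corr stop
    cluster_cv_reps: int = 100        # holdout repetitions in subset search
    cluster_cv_holdout: float = 0.10
    penalty_covariates: float = 0.0
    penalty_clusters: float = 10.0
    penalty: str = "l2"
    target_sensitivity: float = 0.90  # threshold rule, non-diagnostic subgroup
    cfgc_gene_targets: dict = field(default_factory=lambda: {
        "sex": 1, "smoking_status": 3, "pack_years": 2})
    max_candidates: int = 200         # CFGC LASSO candidate cap (ranked by p)
    exhaustive_subset: bool = False


@dataclass
class DerivationResult:
    """Everything one pipeline run produces."""

    cfgc_models: dict[str, CfgcModel]
    covariates: pd.DataFrame                  # per-sample GG, GS, GPY
    baseline: BaselineModel
    cancer_t_scores: pd.Series                # selected genes, signed T
    cluster_set: GeneClusterSet
    final_fit: FinalFit | None
    model: LockedClassifier
    train_scores: pd.Series
    threshold: float
    subset_cv_auc: float

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "selected_genes": {g: float(t)
                               for g, t in self.cancer_t_scores.items()},
            "clusters": {int(c): list(m) for c, m in
                         self.cluster_set.representatives.items()},
            "cluster_assignments": {g: int(c) for g, c in
                                    self.cluster_set.assignments.items()},
            "chosen_clusters": [int(c) for c in
                                self.cluster_set.chosen_clusters],
            "subset_cv_auc": self.subset_cv_auc,
            "threshold": self.threshold,
        }


def derive(d: Dataset, config: PipelineConfig | None = None, seed: int = 0
           ) -> DerivationResult:
    """Run the full derivation on a training dataset."""
    cfg = config or PipelineConfig()

    # 1. CFGC sub-models.  On cohorts where no gene clears the p cutoff for
    # a factor the top-ranked genes at the configured count target are used
    # instead, so the pipeline stays runnable on null cohorts.
    cfgc_models: dict[str, CfgcModel] = {}
    for factor in _FACTORS:
        target = cfg.cfgc_gene_targets.get(factor)
        hits = select_covariate_genes(d, factor, p_cut=cfg.p_cut,
                                      min_genes=target or 1)
        candidates = list(hits.index[:cfg.max_candidates])
        cfgc_models[factor] = fit_cfgc(d, factor, candidates,
                                       n_genes=target, seed=seed)
        log.info("CFGC %s: %d candidates -> %d genes (AUC %.3f)", factor,
                 len(candidates), len(cfgc_models[factor].genes),
                 cfgc_models[factor].training_auc)

    cov = pd.DataFrame(
        {_FACTOR_TO_FEATURE[f]: apply_cfgc(m, d.expression)
         for f, m in cfgc_models.items()},
        index=d.sample_ids)

    # 2. clinical baseline and residual-based cancer-gene selection
    baseline = fit_baseline(d, cov)
    t_scores = select_cancer_genes(d, baseline.residuals, t_cut=cfg.t_cut)
    log.info("cancer-gene selection: %d genes with |T| > %.2f",
             len(t_scores), cfg.t_cut)

    # 3. clustering, reduction, subset search
    genes = list(t_scores.index)
    representatives: dict[int, list[str]] = {}
    rep_r: dict[int, float] = {}
    if len(genes) >= 2:
        n_clusters = min(cfg.n_clusters, len(genes))
        assignments = cluster_genes(d, genes, n_clusters=n_clusters)
        for c in sorted(assignments.unique()):
            members = list(assignments.index[assignments == c])
            if len(members) == 1:
                representatives[c], rep_r[c] = members, 1.0
            else:
                representatives[c], rep_r[c] = reduce_cluster(
                    d, members, k_max=cfg.k_max, r_target=cfg.r_target)
        chosen, cv_auc = select_cluster_subset(
            d, representatives, cov, reps=cfg.cluster_cv_reps,
            holdout=cfg.cluster_cv_holdout, seed=seed,
            penalty_clusters=cfg.penalty_clusters,
            exhaustive=cfg.exhaustive_subset)
    else:
        assignments = pd.Series(dtype=int, name="cluster")
        chosen, cv_auc = [], float("nan")
    cluster_set = GeneClusterSet(
        t_scores=t_scores, assignments=assignments,
        representatives=representatives, representative_r=rep_r,
        chosen_clusters=chosen)
    log.info("cluster subset: chose %s (CV AUC %.3f)", chosen, cv_auc)

    # 4. final differential-penalty fit on covariates + chosen cluster means
    features = cov.copy()
    features["Age"] = d.phenotypes.column("age").to_numpy(dtype=float)
    memberships = {f"CA{c}": representatives[c] for c in chosen}
    for name, members in memberships.items():
        features[name] = (d.expression.subset_genes(members)
                          .values.mean(axis=0))
    final_fit = fit_final(features, d.phenotypes.column("cancer_status"),
                          penalty_covariates=cfg.penalty_covariates,
                          penalty_clusters=cfg.penalty_clusters,
                          penalty=cfg.penalty)

    ref_genes = (sum((m.genes for m in cfgc_models.values()), [])
                 + [g for mem in memberships.values() for g in mem])
    ref_means = {g: float(d.expression.gene(g).mean())
                 for g in dict.fromkeys(ref_genes)}
    model = LockedClassifier(
        intercept=final_fit.intercept,
        coefficients={k: float(v) for k, v in
                      final_fit.coefficients.items()},
        clusters=memberships,
        cfgc={_FACTOR_TO_FEATURE[f]: m.to_sub_model()
              for f, m in cfgc_models.items()},
        threshold=0.65,  # provisional; replaced below
        reference_means=ref_means,
        name="derived classifier",
    )

    # 5. decision threshold targeting ~90% sensitivity in the
    # non-diagnostic-bronchoscopy subgroup (all samples if not recorded)
    train_scores = score(features, model)
    y = d.phenotypes.column("cancer_status").to_numpy(dtype=int)
    if "bronchoscopy_diagnostic" in d.phenotypes.data.columns:
        subgroup = (d.phenotypes.column("bronchoscopy_diagnostic")
                    .to_numpy(dtype=int) == 0)
        if not (subgroup & (y == 1)).any():
            subgroup = None
    else:
        subgroup = None
    threshold = choose_threshold(train_scores.to_numpy(), y, subgroup,
                                 target_sensitivity=cfg.target_sensitivity)
    model = dataclasses.replace(model, threshold=threshold)
    return DerivationResult(
        cfgc_models=cfgc_models, covariates=cov, baseline=baseline,
        cancer_t_scores=t_scores, cluster_set=cluster_set,
        final_fit=final_fit, model=model, train_scores=train_scores,
        threshold=threshold, subset_cv_auc=cv_auc)


def score_dataset(expr: ExpressionMatrix, age: pd.Series,
                  model: LockedClassifier) -> pd.Series:
    """Score every sample of an expression matrix with a model."""
    return score(compute_features(expr, age, model), model)


def clinical_model_scores(d: Dataset) -> pd.Series:
    """Scores of the clinical-factors-only logistic model.

    Uses age, sex, smoking status and pack-years as reported (no gene
    expression); the comparison baseline for the genomic classifier.
    """
    import statsmodels.api as sm

    ph = d.phenotypes
    X = pd.DataFrame({
        "Age": ph.column("age").to_numpy(dtype=float),
        "female": (ph.column("sex").to_numpy() == "female").astype(float),
        "current": (ph.column("smoking_status").to_numpy()
                    == "current").astype(float),
        "pack_years": ph.column("pack_years").to_numpy(dtype=float),
    }, index=d.sample_ids)
    y = ph.column("cancer_status").to_numpy(dtype=int)
    fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0, maxiter=200)
    return pd.Series(np.asarray(fit.predict(sm.add_constant(X))),
                     index=d.sample_ids, name="clinical_score")
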