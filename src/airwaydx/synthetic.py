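"""Synthetic cohorts with the statistical structure the derivation assumes.

Two generators are provided:

* :func:`simulate_cohort` — a planted-structure cohort for exercising the
  derivation pipeline: log2-scale Gaussian expression with (a) a configurable
  number of cancer-associated gene clusters, each realized as a shared
  per-cluster latent factor plus independent gene noise, shifted by a signed
  per-cluster effect in cancer samples; (b) strongly bimodal sex-marker genes
  (separated means much larger than the noise, emulating a Y-linked
  transcript); (c) smoking-status and pack-year associated genes; (d) pure
  noise for everything else.
* :func:`simulate_from_locked` — a cohort drawn *from* a locked classifier:
  the model's own genes are generated with realistic log2 distributions,
  features are computed exactly as the scorer computes them, and cancer
  status is drawn Bernoulli from the model's score.  Used for parameter
  recovery and cross-platform round trips.

All randomness uses :func:`numpy.random.default_rng` (PCG64); identical
configs and seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import Dataset, ExpressionMatrix, PhenotypeTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_platform_shift",
    "simulate_from_locked",
]

# Default signed cancer effects for the 11 planted clusters (log2 units):
# clusters 4 and 7 up-regulated, 1, 2, 9 and 10 down-regulated, the other
# five null — mirroring the module structure the derivation is meant to find.
_DEFAULT_EFFECTS = (-1.0, -1.0, 0.0, 1.0, 0.0, 0.0, 1.0, 0.0, -1.0, -1.0, 0.0)


@dataclass
class SimulationConfig:
    """Knobs of the planted-structure cohort generator.

    The defaults emulate the derivation cohort: 223 cancer-positive and 76
    benign current/former smokers, 11 correlated cancer gene clusters with
    |effect| = 1 log2 units in six of them, within-cluster correlation 0.6,
    unit log2 noise.
    """

    n_cancer: int = 223
    n_benign: int = 76
    n_genes: int = 2000
    n_clusters: int = 11
    genes_per_cluster: int = 20
    cluster_effect_sizes: tuple[float, ...] = _DEFAULT_EFFECTS
    within_cluster_correlation: float = 0.6
    n_sex_genes: int = 5
    n_smoking_genes: int = 50
    n_py_genes: int = 30
    sex_separation: float = 5.0       # log2 gap between male/female means
    smoking_effect: float = 2.0       # log2 shift in current smokers
    py_effect: float = 1.5            # log2 shift for pack-years > 10
    noise_sd: float = 1.0
    baseline_mean_range: tuple[float, float] = (4.0, 10.0)
    # (mean, sd) of age per class, clipped to >= 35
    age_cancer: tuple[float, float] = (65.0, 10.0)
    age_benign: tuple[float, float] = (56.0, 12.0)
    # (mean, sd) of pack-years per class, clipped to >= 0
    py_cancer: tuple[float, float] = (43.0, 25.0)
    py_benign: tuple[float, float] = (30.0, 22.0)
    prop_female: float = 0.4
    prop_current: float = 0.42
    seed: int = 0

    def validate(self) -> None:
        counts = dict(n_cancer=self.n_cancer, n_benign=self.n_benign,
                      n_genes=self.n_genes, n_clusters=self.n_clusters,
                      genes_per_cluster=self.genes_per_cluster)
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if not 0 <= self.within_cluster_correlation < 1:
            raise ValueError("within_cluster_correlation must be in [0, 1)")
        if len(self.cluster_effect_sizes) != self.n_clusters:
            raise ValueError("cluster_effect_sizes must have length n_clusters")
        n_planted = (self.n_clusters * self.genes_per_cluster
                     + self.n_sex_genes + self.n_smoking_genes
                     + self.n_py_genes)
        if n_planted > self.n_genes:
            raise ValueError("n_genes smaller than the planted gene count")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def null_config(seed: int = 0, n_genes: int = 2000, n_cancer: int = 223,
                n_benign: int = 76) -> SimulationConfig:
    """A fully null cohort: every planted effect zero, class-matched ages
    and pack-years.  Used for calibration checks (uniform p-values,
    chance-level classifiers)."""
    return SimulationConfig(
        n_cancer=n_cancer, n_benign=n_benign, n_genes=n_genes,
        cluster_effect_sizes=(0.0,) * 11, sex_separation=0.0,
        smoking_effect=0.0, py_effect=0.0,
        age_cancer=(60.0, 10.0), age_benign=(60.0, 10.0),
        py_cancer=(38.0, 24.0), py_benign=(38.0, 24.0), seed=seed)


@dataclass
class GroundTruth:
    """What was planted: gene roles, cluster structure, latent attributes."""

    cluster_members: dict[int, list[str]]
    cluster_effects: dict[int, float]
    sex_genes: list[str]
    smoking_genes: list[str]
    py_genes: list[str]
    factors: pd.DataFrame = field(repr=False)  # samples x clusters latent factors

    @property
    def cancer_genes(self) -> list[str]:
        """Planted genes carrying a nonzero cancer effect."""
        return [g for c, genes in self.cluster_members.items()
                for g in genes if self.cluster_effects[c] != 0.0]

    def cluster_of(self) -> pd.Series:
        pairs = {g: c for c, genes in self.cluster_members.items()
                 for g in genes}
        return pd.Series(pairs, name="cluster")


def simulate_cohort(config: SimulationConfig) -> tuple[Dataset, GroundTruth]:
    """Generate a planted-structure cohort; reproducible given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cancer + config.n_benign
    samples = [f"S{i + 1:04d}" for i in range(n)]
    cancer = np.concatenate([np.ones(config.n_cancer, dtype=int),
                             np.zeros(config.n_benign, dtype=int)])

    # clinical attributes (independent apart from the class-linked age and
    # pack-year distributions)
    age = np.where(
        cancer == 1,
        rng.normal(*config.age_cancer, size=n),
        rng.normal(*config.age_benign, size=n)).clip(min=35.0).round(1)
    pack_years = np.where(
        cancer == 1,
        rng.normal(*config.py_cancer, size=n),
        rng.normal(*config.py_benign, size=n)).clip(min=0.0).round(1)
    female = rng.random(n) < config.prop_female
    current = rng.random(n) < config.prop_current
    heavy = pack_years > 10.0

    sd = config.noise_sd
    rho = config.within_cluster_correlation
    loading = sd * np.sqrt(rho / (1.0 - rho)) if rho > 0 else 0.0

    rows: list[np.ndarray] = []
    genes: list[str] = []
    lo, hi = config.baseline_mean_range

    def baselines(k: int) -> np.ndarray:
        return rng.uniform(lo, hi, size=k)

    cluster_members: dict[int, list[str]] = {}
    cluster_effects: dict[int, float] = {}
    factors = np.empty((n, config.n_clusters))
    for c in range(config.n_clusters):
        eff = float(config.cluster_effect_sizes[c])
        f = rng.standard_normal(n)
        factors[:, c] = f
        shared = loading * f + eff * cancer
        mus = baselines(config.genes_per_cluster)
        members = [f"CL{c + 1:02d}_G{j + 1:03d}"
                   for j in range(config.genes_per_cluster)]
        for mu, name in zip(mus, members):
            rows.append(mu + shared + rng.normal(0.0, sd, size=n))
            genes.append(name)
        cluster_members[c + 1] = members
        cluster_effects[c + 1] = eff

    sex_genes = [f"SEXG{j + 1:02d}" for j in range(config.n_sex_genes)]
    for mu, name in zip(baselines(config.n_sex_genes), sex_genes):
        shift = np.where(female, -config.sex_separation / 2.0,
                         config.sex_separation / 2.0)
        rows.append(mu + config.sex_separation / 2.0 + shift
                    + rng.normal(0.0, sd / 2.0, size=n))
        genes.append(name)

    smoking_genes = [f"SMKG{j + 1:03d}" for j in range(config.n_smoking_genes)]
    smk_signs = rng.choice([-1.0, 1.0], size=config.n_smoking_genes)
    for mu, sign, name in zip(baselines(config.n_smoking_genes), smk_signs,
                              smoking_genes):
        rows.append(mu + sign * config.smoking_effect * current
                    + rng.normal(0.0, sd, size=n))
        genes.append(name)

    py_genes = [f"PYG{j + 1:03d}" for j in range(config.n_py_genes)]
    py_signs = rng.choice([-1.0, 1.0], size=config.n_py_genes)
    for mu, sign, name in zip(baselines(config.n_py_genes), py_signs,
                              py_genes):
        rows.append(mu + sign * config.py_effect * heavy
                    + rng.normal(0.0, sd, size=n))
        genes.append(name)

    n_noise = config.n_genes - len(genes)
    for j, mu in enumerate(baselines(n_noise)):
        rows.append(mu + rng.normal(0.0, sd, size=n))
        genes.append(f"NULLG{j + 1:04d}")

    expr = ExpressionMatrix(
        pd.DataFrame(np.vstack(rows), index=pd.Index(genes, name="gene"),
                     columns=samples))
    pheno = PhenotypeTable(pd.DataFrame(
        {
            "cancer_status": cancer,
            "sex": np.where(female, "female", "male"),
            "smoking_status": np.where(current, "current", "former"),
            "pack_years": pack_years,
            "age": age,
            # bronchoscopy detects ~half of the cancers, no false positives
            "bronchoscopy_diagnostic": (cancer == 1)
            & (rng.random(n) < 0.5),
        },
        index=pd.Index(samples, name="sample_id"),
    ).assign(bronchoscopy_diagnostic=lambda d:
             d["bronchoscopy_diagnostic"].astype(int)))
    truth = GroundTruth(
        cluster_members=cluster_members, cluster_effects=cluster_effects,
        sex_genes=sex_genes, smoking_genes=smoking_genes, py_genes=py_genes,
        factors=pd.DataFrame(factors, index=samples,
                             columns=[f"cluster_{c+1}" for c in
                                      range(config.n_clusters)]))
    return Dataset(expr, pheno), truth


def simulate_platform_shift(
    d: Dataset,
    offsets_sd: float,
    dropped_genes: list[str] | tuple[str, ...] = (),
    seed: int = 0,
) -> Dataset:
    """Emulate measuring the cohort on a second platform.

    Every gene's values are shifted by a gene-wise constant drawn
    ``N(0, offsets_sd)`` — the systematic per-gene offset the mean-shift
    adjustment must undo — and the listed genes are removed entirely
    (absent probesets on the second platform).
    """
    unknown = [g for g in dropped_genes if g not in d.expression.data.index]
    if unknown:
        raise KeyError(f"dropped genes not in expression matrix: {unknown}")
    rng = np.random.default_rng(seed)
    df = d.expression.data.copy()
    offsets = rng.normal(0.0, offsets_sd, size=df.shape[0]) \
        if offsets_sd > 0 else np.zeros(df.shape[0])
    df = df.add(offsets, axis=0)
    if dropped_genes:
        df = df.drop(index=list(dropped_genes))
    return Dataset(ExpressionMatrix(df), d.phenotypes)


# feature-level generating distributions for simulate_from_locked:
# (mean_reference, shift, sd) where the shift applies to the indicated group.
_SMOKING_GENE_PARAMS = {   # shift applies to current smokers
    "SLC7A11": (8.3, -0.8, 1.0),
    "CLND10": (9.6, -0.8, 0.6),
    "TKT": (10.1, -0.5, 0.5),
}
_PY_GENE_PARAMS = {        # shift applies to pack-years > 10
    "RUNX1T1": (3.8, 0.6, 0.6),
    "AKR1C2": (4.2, -0.4, 0.6),
}
# latent per-sample means of the six cancer-cluster features (log2)
_CLUSTER_FEATURE_MEANS = {
    "CA1": 8.0, "CA2": 9.0, "CA4": 7.0, "CA7": 5.5, "CA9": 8.0, "CA10": 8.0,
}


def simulate_from_locked(
    model,
    n_samples: int,
    seed: int = 0,
    feature_sd: float = 1.0,
    member_noise_sd: float = 0.4,
    n_noise_genes: int = 300,
) -> tuple[Dataset, pd.DataFrame]:
    """Draw a cohort whose cancer status follows a locked classifier.

    The model's own genes are generated at log2 scale (bimodal RPS4Y1 by
    sex; smoking/pack-year genes coupled to the drawn clinical attributes;
    each cancer cluster as a latent per-sample feature plus per-gene noise),
    features are computed exactly as the scorer computes them, and cancer
    status is Bernoulli in the model's score.  Returns the dataset and the
    per-sample feature/score table (the generative truth).
    """
    from .classifier import compute_features, score as score_fn

    rng = np.random.default_rng(seed)
    n = n_samples
    samples = [f"T{i + 1:04d}" for i in range(n)]

    female = rng.random(n) < 0.4
    current = rng.random(n) < 0.42
    age = rng.normal(62.0, 10.0, size=n).clip(min=35.0).round(1)
    pack_years = rng.normal(38.0, 24.0, size=n).clip(min=0.0).round(1)
    heavy = pack_years > 10.0

    rows: dict[str, np.ndarray] = {}
    rows["RPS4Y1"] = np.where(female, rng.normal(5.0, 0.5, size=n),
                              rng.normal(10.0, 0.5, size=n))
    for gene, (mu, shift, sdev) in _SMOKING_GENE_PARAMS.items():
        rows[gene] = mu + shift * current + rng.normal(0.0, sdev, size=n)
    for gene, (mu, shift, sdev) in _PY_GENE_PARAMS.items():
        rows[gene] = mu + shift * heavy + rng.normal(0.0, sdev, size=n)

    for ca, members in model.clusters.items():
        latent = rng.normal(_CLUSTER_FEATURE_MEANS[ca], feature_sd, size=n)
        for gene in members:
            rows[gene] = latent + rng.normal(0.0, member_noise_sd, size=n)

    for j in range(n_noise_genes):
        mu = rng.uniform(4.0, 10.0)
        rows[f"NULLG{j + 1:04d}"] = mu + rng.normal(0.0, 1.0, size=n)

    expr = ExpressionMatrix(pd.DataFrame(
        rows, index=pd.Index(samples, name="sample_id")).T
        .rename_axis(index="gene"))

    features = compute_features(expr, pd.Series(age, index=samples), model)
    scores = score_fn(features, model)
    cancer = (rng.random(n) < scores.to_numpy()).astype(int)
    bronch = ((cancer == 1) & (rng.random(n) < 0.5)).astype(int)

    pheno = PhenotypeTable(pd.DataFrame(
        {
            "cancer_status": cancer,
            "sex": np.where(female, "female", "male"),
            "smoking_status": np.where(current, "current", "former"),
            "pack_years": pack_years,
            "age": age,
            "bronchoscopy_diagnostic": bronch,
        },
        index=pd.Index(samples, name="sample_id")))
    truth = features.assign(score=scores, cancer_status=cancer)
    return Dataset(expr, pheno), truth
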