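"""Validation-time cross-platform adjustments.

A classifier locked on one microarray platform cannot be applied directly to
expression values from another: per-gene intensities carry platform-specific
offsets, and some genes may have no probeset at all on the second platform.
Two adjustments make scoring possible:

* :func:`mean_shift_adjust` — add a gene-wise constant so that each gene's
  mean in the new cohort equals its mean in the training cohort (the shift is
  ``training mean - test mean``, computed separately per gene).  Within-cohort
  variance and sample ranking per gene are untouched.
* :func:`impute_missing_genes` — any model gene absent from the new platform
  is added as a constant row equal to its training-set mean (in the published
  validation this applied to LYPD2 and RNF150).

Both require per-gene training means (:class:`ReferenceMeans`).  The
published model's training means were never printed, so the packaged locked
model carries none; scoring a real foreign-platform cohort requires a
user-supplied reference, while synthetic workflows compute one from the
simulated training cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import ExpressionMatrix

__all__ = [
    "ReferenceMeans",
    "reference_means_from",
    "mean_shift_adjust",
    "impute_missing_genes",
]

log = logging.getLogger("airwaydx")


@dataclass(frozen=True)
class ReferenceMeans:
    """Per-gene training-set mean log2 expression."""

    means: pd.Series          # gene -> mean
    n_train: int
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        if not np.isfinite(self.means.to_numpy(dtype=float)).all():
            raise ValueError("reference means must be finite")

    def to_dict(self) -> dict:
        return {"means": {g: float(v) for g, v in self.means.items()},
                "n_train": self.n_train, "provenance": self.provenance}

    @classmethod
    def from_dict(cls, doc: dict) -> "ReferenceMeans":
        return cls(means=pd.Series(doc["means"], dtype=float),
                   n_train=int(doc["n_train"]),
                   provenance=doc.get("provenance", "unspecified"))


def reference_means_from(expr: ExpressionMatrix,
                         provenance: str = "training cohort"
                         ) -> ReferenceMeans:
    """Compute per-gene means of a (training) expression matrix."""
    return ReferenceMeans(means=expr.data.mean(axis=1),
                          n_train=len(expr.sample_ids),
                          provenance=provenance)


def mean_shift_adjust(test: ExpressionMatrix, ref: ReferenceMeans
                      ) -> ExpressionMatrix:
    """Shift each shared gene so its test-cohort mean equals the reference.

    Genes absent from the reference pass through unchanged (with a warning
    log); the adjustment needs at least two test samples for a per-gene
    mean to be estimable.  Idempotent: adjusting an adjusted matrix is a
    no-op.
    """
    if len(test.sample_ids) < 2:
        raise ValueError("mean-shift adjustment needs >= 2 test samples")
    shared = test.data.index.intersection(ref.means.index)
    if shared.empty:
        raise ValueError("no genes shared between test matrix and reference")
    unshared = test.data.index.difference(ref.means.index)
    if len(unshared):
        log.warning("mean_shift_adjust: %d genes absent from reference pass "
                    "through unadjusted", len(unshared))
    df = test.data.copy()
    offsets = ref.means.loc[shared] - df.loc[shared].mean(axis=1)
    df.loc[shared] = df.loc[shared].add(offsets, axis=0)
    return ExpressionMatrix(df)


def impute_missing_genes(test: ExpressionMatrix, ref: ReferenceMeans,
                         required: list[str]) -> ExpressionMatrix:
    """Add each missing required gene as a constant training-mean row."""
    missing = [g for g in required if g not in test.data.index]
    if not missing:
        return test
    no_ref = [g for g in missing if g not in ref.means.index]
    if no_ref:
        raise KeyError(f"missing genes absent from reference too: {no_ref}")
    df = test.data.copy()
    for g in missing:
        df.loc[g] = float(ref.means[g])
        log.info("impute_missing_genes: %s imputed at training mean %.4f",
                 g, ref.means[g])
    return ExpressionMatrix(df)
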