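"""Cohort data model and file readers/writers.

The package works on three kinds of files:

* expression matrices — tab-separated text, genes in rows (first column is the
  gene symbol), samples in columns, header row of sample ids; values are
  RMA-style log2 intensities (typically 2-14);
* phenotype tables — CSV with one row per sample carrying the clinical truth
  (cancer status, sex, smoking status, pack-years, age, bronchoscopy outcome);
* model files — versioned JSON documents holding a full classifier
  parameterization (see :mod:`airwaydx.classifier`).

Gene identity is by symbol string, canonicalized to the spelling used in the
published model definition.  A small alias map translates common variant
spellings (``CLDN10`` -> ``CLND10``, ``CLDN22`` -> ``CLND22``) at read time so
that matrices produced with either spelling score identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "SchemaError",
    "GENE_ALIASES",
    "ExpressionMatrix",
    "PhenotypeTable",
    "Dataset",
    "read_expression",
    "write_expression",
    "read_phenotypes",
    "write_phenotypes",
    "align",
    "save_model",
    "load_model",
]

log = logging.getLogger("airwaydx")


class FormatError(ValueError):
    """An input file violates the documented dialect."""


class SchemaError(ValueError):
    """A model file is incomplete or has an unsupported schema version."""


#: Read-time gene-symbol canonicalization: keys are variant spellings, values
#: are the symbols used by the locked model definition.
GENE_ALIASES: dict[str, str] = {
    "CLDN10": "CLND10",
    "CLDN22": "CLND22",
}

# Controlled vocabularies for the phenotype sheet.
_SEX_LEVELS = {"female", "male"}
_SMOKING_LEVELS = {"current", "former"}
_REQUIRED_PHENO_COLS = ("sample_id", "cancer_status", "sex", "smoking_status",
                        "pack_years", "age")
_OPTIONAL_PHENO_COLS = ("bronchoscopy_diagnostic", "mass_size_class",
                        "mass_location", "histology")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of log2 expression intensities.

    Invariants (checked at construction): unique gene ids, unique sample ids,
    all values finite, dimensions consistent.
    """

    data: pd.DataFrame  # index = gene symbols, columns = sample ids

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dupes}")
        values = df.to_numpy()
        if values.size and not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite expression value at gene {df.index[bad[0]]!r}, "
                f"sample {df.columns[bad[1]]!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def gene(self, symbol: str) -> np.ndarray:
        """Per-sample values for one gene; raises KeyError naming the gene."""
        if symbol not in self.data.index:
            raise KeyError(f"gene {symbol!r} not in expression matrix")
        return self.data.loc[symbol].to_numpy(dtype=float)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            raise KeyError(f"genes not in expression matrix: {missing}")
        return ExpressionMatrix(self.data.loc[list(gene_ids)])


@dataclass(frozen=True)
class PhenotypeTable:
    """Per-sample clinical table indexed by sample id."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dupes}")
        if "cancer_status" in df.columns:
            bad = set(df["cancer_status"].unique()) - {0, 1}
            if bad:
                raise FormatError(f"cancer_status outside {{0,1}}: {bad}")
        if "age" in df.columns and (df["age"] <= 0).any():
            raise FormatError("age must be > 0")
        if "pack_years" in df.columns and (df["pack_years"] < 0).any():
            raise FormatError("pack_years must be >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def column(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"phenotype column {name!r} missing")
        return self.data[name]

    def subset(self, sample_ids) -> "PhenotypeTable":
        return PhenotypeTable(self.data.loc[list(sample_ids)])


@dataclass(frozen=True)
class Dataset:
    """An expression matrix and phenotype table over the same ordered samples."""

    expression: ExpressionMatrix
    phenotypes: PhenotypeTable

    def __post_init__(self) -> None:
        if self.expression.sample_ids != self.phenotypes.sample_ids:
            raise FormatError("expression and phenotype sample ids differ "
                              "(run align() first)")

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def _canonicalize_genes(index: pd.Index) -> pd.Index:
    return pd.Index([GENE_ALIASES.get(g, g) for g in index], name=index.name)


def read_expression(path) -> ExpressionMatrix:
    """Read a genes-in-rows TSV expression file.

    The first column holds gene symbols; the header row holds sample ids.
    Alias spellings are canonicalized.  Duplicate ids and non-numeric cells
    are format errors naming the offending row/column.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except Exception as exc:  # pandas raises several parser error types
        raise FormatError(f"cannot parse expression file {path}: {exc}") from exc
    if df.columns.empty:
        raise FormatError(f"{path}: no sample columns (missing header row?)")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise FormatError(
                f"{path}: non-numeric value in sample column {col!r} at gene "
                f"{bad.index[0]!r}")
    df.index = _canonicalize_genes(df.index.astype(str))
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float))


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene")


def read_phenotypes(path) -> PhenotypeTable:
    """Read the per-sample clinical CSV.

    Required columns: sample_id, cancer_status, sex, smoking_status,
    pack_years, age.  Optional: bronchoscopy_diagnostic, mass_size_class,
    mass_location, histology.  Unknown categories in optional categorical
    fields are preserved as ``"unknown"``.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot parse phenotype file {path}: {exc}") from exc
    missing = [c for c in _REQUIRED_PHENO_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    df["sample_id"] = df["sample_id"].astype(str)
    df = df.set_index("sample_id")

    for col, caster in (("age", float), ("pack_years", float),
                        ("cancer_status", int)):
        try:
            df[col] = df[col].astype(caster)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: unparseable {col}: {exc}") from exc
    for col, levels in (("sex", _SEX_LEVELS), ("smoking_status",
                                               _SMOKING_LEVELS)):
        df[col] = df[col].astype(str).str.lower()
        bad = set(df[col].unique()) - levels
        if bad:
            raise FormatError(f"{path}: {col} has values outside {sorted(levels)}: "
                              f"{sorted(bad)}")
    if "bronchoscopy_diagnostic" in df.columns:
        df["bronchoscopy_diagnostic"] = df["bronchoscopy_diagnostic"].astype(int)
    for col in ("mass_size_class", "mass_location", "histology"):
        if col in df.columns:
            df[col] = df[col].astype(str).str.lower().fillna("unknown")
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.data.to_csv(path, index_label="sample_id")


def align(expr: ExpressionMatrix, pheno: PhenotypeTable) -> Dataset:
    """Restrict both tables to their common samples, in a common order.

    The order is the expression matrix's column order restricted to the
    intersection.  Dropped-sample counts are logged.  Empty intersection is
    an error.
    """
    common = [s for s in expr.sample_ids if s in set(pheno.sample_ids)]
    if not common:
        raise FormatError("no samples shared between expression matrix and "
                          "phenotype table")
    dropped_expr = len(expr.sample_ids) - len(common)
    dropped_pheno = len(pheno.sample_ids) - len(common)
    if dropped_expr or dropped_pheno:
        log.info("align: dropped %d expression-only and %d phenotype-only "
                 "samples; %d retained", dropped_expr, dropped_pheno,
                 len(common))
    return Dataset(expr.subset_samples(common), pheno.subset(common))


def save_model(model, path) -> None:
    """Serialize a classifier (see :mod:`airwaydx.classifier`) to JSON."""
    import json

    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2, sort_keys=True)


def load_model(path):
    """Load a classifier JSON written by :func:`save_model`."""
    import json

    from .classifier import LockedClassifier

    try:
        with open(path) as fh:
            doc = json.load(fh)
    except Exception as exc:
        raise SchemaError(f"cannot parse model file {path}: {exc}") from exc
    return LockedClassifier.from_dict(doc)
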