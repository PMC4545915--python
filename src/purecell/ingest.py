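"""Reading and harmonising expression tables.

All downstream analyses operate on a shared-gene log2(TPM+1) matrix. Input
tables may arrive on three scales: FPKM (length-normalised, needs within-sample
renormalisation), RSEM "scaled estimate" (relative abundance summing to 1 per
sample, needs a factor of 1e6), or TPM. Conversion, log transform and the
shared-gene merge live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateSampleError,
    InvalidInputError,
    ScaleError,
    ScaleMismatchWarning,
)

SCALES = ("fpkm", "scaled_estimate", "tpm", "log2_tpm_plus1")
SOURCES = ("cell_line", "tumour")
ER_STATUSES = ("positive", "negative", "unknown")
SUBTYPES = ("luminal", "basal", "claudin_low", "unknown")

TPM_SUM = 1e6

ANNOTATION_COLUMNS = ["source", "er_status", "subtype"]


def make_annotations(
    sample_ids,
    source,
    er_status=None,
    subtype=None,
) -> pd.DataFrame:
    """Build a sample annotation table (index: sample_id).

    ``source`` is required per sample; ``er_status`` and ``subtype`` default to
    ``unknown``.
    """
    sample_ids = list(sample_ids)
    if len(set(sample_ids)) != len(sample_ids):
        raise InvalidInputError("duplicate sample ids in annotations")
    n = len(sample_ids)
    er_status = list(er_status) if er_status is not None else ["unknown"] * n
    subtype = list(subtype) if subtype is not None else ["unknown"] * n
    ann = pd.DataFrame(
        {"source": list(source), "er_status": er_status, "subtype": subtype},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    bad = set(ann["source"]) - set(SOURCES)
    if bad:
        raise InvalidInputError(f"unknown sample sources: {sorted(bad)}")
    bad = set(ann["er_status"]) - set(ER_STATUSES)
    if bad:
        raise InvalidInputError(f"unknown ER statuses: {sorted(bad)}")
    bad = set(ann["subtype"]) - set(SUBTYPES)
    if bad:
        raise InvalidInputError(f"unknown subtypes: {sorted(bad)}")
    return ann


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance table with an explicit scale tag.

    ``values`` is a DataFrame indexed by gene id with one column per sample;
    ``annotations`` is indexed by sample id and aligned with the columns.
    """

    values: pd.DataFrame
    scale: str
    annotations: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if self.scale not in SCALES:
            raise ScaleError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise InvalidInputError(f"duplicate gene ids: {list(dups[:5])}")
        if self.values.columns.duplicated().any():
            raise InvalidInputError("duplicate sample ids in matrix columns")
        if self.annotations is None:
            self.annotations = make_annotations(
                self.values.columns, ["tumour"] * self.values.shape[1]
            )
        if list(self.annotations.index) != list(self.values.columns):
            raise InvalidInputError("annotation rows do not match matrix columns")
        if self.scale != "log2_tpm_plus1" and (self.values.values < 0).any():
            raise InvalidInputError(f"negative values in a {self.scale} matrix")
        if self.scale == "tpm":
            sums = self.values.sum(axis=0).to_numpy()
            if not np.allclose(sums, TPM_SUM, rtol=1e-3):
                raise InvalidInputError(
                    "TPM columns must sum to 1e6 (worst relative deviation "
                    f"{np.abs(sums / TPM_SUM - 1).max():.2e})"
                )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        return ExpressionMatrix(
            self.values[sample_ids],
            self.scale,
            self.annotations.loc[sample_ids],
        )

    def tumour_ids(self) -> list:
        return list(self.annotations.index[self.annotations["source"] == "tumour"])

    def cell_line_ids(self) -> list:
        return list(self.annotations.index[self.annotations["source"] == "cell_line"])


def fpkm_to_tpm(column) -> np.ndarray:
    """Renormalise one sample's FPKM values to TPM.

    FPKM is already gene-length-normalised, so TPM is just the within-sample
    renormalisation output_g = input_g / sum_h input_h * 1e6.
    """
    col = np.asarray(column, dtype=float)
    if (col < 0).any():
        raise InvalidInputError("negative FPKM value")
    total = col.sum()
    if total <= 0:
        raise DegenerateSampleError("all-zero FPKM column cannot be renormalised")
    return col / total * TPM_SUM


def scaled_estimate_to_tpm(column, strict: bool = True) -> np.ndarray:
    """Convert RSEM scaled-estimate values (summing to ~1) to TPM (x 1e6)."""
    col = np.asarray(column, dtype=float)
    if (col < 0).any():
        raise InvalidInputError("negative scaled-estimate value")
    total = col.sum()
    if total <= 0:
        raise DegenerateSampleError("all-zero scaled-estimate column")
    if not (0.99 <= total <= 1.01):
        msg = f"scaled-estimate column sums to {total:.4g}, expected ~1"
        if strict:
            raise InvalidInputError(msg)
        warnings.warn(msg, ScaleMismatchWarning)
    return col * TPM_SUM


def to_tpm(matrix: ExpressionMatrix, strict: bool = True) -> ExpressionMatrix:
    """Bring a matrix on any linear scale to TPM."""
    if matrix.scale == "tpm":
        return matrix
    if matrix.scale == "fpkm":
        conv = matrix.values.apply(fpkm_to_tpm, axis=0)
    elif matrix.scale == "scaled_estimate":
        conv = matrix.values.apply(lambda c: scaled_estimate_to_tpm(c, strict), axis=0)
    else:
        raise ScaleError(f"cannot convert scale {matrix.scale!r} to TPM")
    return ExpressionMatrix(conv, "tpm", matrix.annotations)


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1); the +1 avoids infinities for zero-abundance genes."""
    if matrix.scale != "tpm":
        raise ScaleError(f"log_transform expects TPM input, got {matrix.scale!r}")
    return ExpressionMatrix(
        np.log2(matrix.values + 1.0), "log2_tpm_plus1", matrix.annotations
    )


def merge_datasets(a: ExpressionMatrix, b: ExpressionMatrix) -> ExpressionMatrix:
    """Combine two same-scale matrices on their shared genes.

    Genes are intersected (lexicographic order); samples are concatenated.
    """
    if a.scale != b.scale:
        raise ScaleError(f"cannot merge scales {a.scale!r} and {b.scale!r}")
    shared = sorted(set(a.gene_ids) & set(b.gene_ids))
    if not shared:
        raise InvalidInputError("gene intersection of the two datasets is empty")
    overlap = set(a.sample_ids) & set(b.sample_ids)
    if overlap:
        raise InvalidInputError(f"duplicate sample ids across inputs: {sorted(overlap)[:5]}")
    values = pd.concat([a.values.loc[shared], b.values.loc[shared]], axis=1)
    ann = pd.concat([a.annotations, b.annotations], axis=0)
    merged = ExpressionMatrix(values, a.scale, ann)
    return merged


def read_expression(path, scale: str, annotations: pd.DataFrame = None) -> ExpressionMatrix:
    """Read a gene x sample TSV (first column gene id, header sample ids)."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index.name = "gene_id"
    return ExpressionMatrix(values, scale, annotations)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format="%.10g", index_label="gene_id")


def read_annotations(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col="sample_id", dtype=str)
    return make_annotations(ann.index, ann["source"], ann["er_status"], ann["subtype"])


def write_annotations(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, sep="\t", index_label="sample_id")
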