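"""Stromal/immune scoring and gene-score correlation.

Per-sample stromal and immune scores are single-sample rank-based enrichment
scores of marker signatures, following the ESTIMATE paradigm: within a sample,
all genes are ranked by abundance and the score integrates the difference
between the weighted empirical distribution of signature genes along the
ranked list and the uniform distribution of the background genes. Higher
scores indicate a larger non-malignant contribution, so the negated composite
(stromal + immune) score serves as the tumour-purity proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import (
    DegenerateSignatureError,
    InsufficientSamplesError,
    InvalidInputError,
)
from .ingest import ExpressionMatrix

DEFAULT_EXPONENT = 0.25


@dataclass(frozen=True)
class GeneSignature:
    """A named, duplicate-free, nonempty gene list."""

    name: str
    genes: tuple

    def __post_init__(self):
        if len(self.genes) == 0:
            raise InvalidInputError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise InvalidInputError(f"signature {self.name!r} has duplicate genes")


@dataclass
class PurityScores:
    """Per-sample stromal, immune and composite enrichment scores."""

    table: pd.DataFrame  # index sample_id; columns stromal_score, immune_score, composite_score

    def __post_init__(self):
        t = self.table
        if not np.allclose(
            t["composite_score"], t["stromal_score"] + t["immune_score"], atol=0
        ):
            raise InvalidInputError("composite score must equal stromal + immune exactly")

    @property
    def stromal(self) -> pd.Series:
        return self.table["stromal_score"]

    @property
    def immune(self) -> pd.Series:
        return self.table["immune_score"]

    @property
    def composite(self) -> pd.Series:
        return self.table["composite_score"]

    @property
    def purity_proxy(self) -> pd.Series:
        """Negated composite score: higher means purer (fewer non-malignant cells)."""
        return -self.table["composite_score"]

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.10g", index_label="sample_id")


def _column_values(column) -> tuple:
    if isinstance(column, pd.Series):
        return column.to_numpy(dtype=float), np.asarray(column.index, dtype=object)
    values = np.asarray(column, dtype=float)
    return values, np.arange(len(values)).astype(object)


def ssgsea_score(column, signature: GeneSignature, exponent: float = DEFAULT_EXPONENT) -> float:
    """Single-sample enrichment score of ``signature`` in one sample column.

    Genes are walked in order of descending abundance (ties broken by gene id;
    tie *weights* use average ranks, so the score is permutation-invariant).
    Signature genes contribute increments proportional to rank^exponent
    (normalised to sum to 1, where the most abundant gene has the largest
    rank); background genes contribute 1/(G - m) each. The score is the sum
    over positions of (cumulative signature weight - cumulative background
    weight). Rank-based, hence invariant under any strictly increasing
    transform of the column.
    """
    if exponent < 0:
        raise InvalidInputError("exponent must be nonnegative")
    values, ids = _column_values(column)
    member = np.isin(ids, np.asarray(signature.genes, dtype=object))
    G = len(values)
    m = int(member.sum())
    if m == 0:
        raise DegenerateSignatureError(
            f"signature {signature.name!r} has no genes in the matrix"
        )
    if m == G:
        raise DegenerateSignatureError(
            f"signature {signature.name!r} equals the whole gene universe"
        )
    ranks = rankdata(values)  # average ranks; most abundant gene ranks highest
    order = np.lexsort((ids, -values))
    member_o = member[order]
    weights = np.where(member_o, ranks[order] ** exponent, 0.0)
    weights = weights / weights.sum()
    background = np.where(member_o, 0.0, 1.0 / (G - m))
    return float(np.sum(np.cumsum(weights) - np.cumsum(background)))


def estimate_scores(
    matrix,
    stromal_signature: GeneSignature,
    immune_signature: GeneSignature,
    exponent: float = DEFAULT_EXPONENT,
) -> PurityScores:
    """Score every sample of ``matrix`` with both signatures.

    Typically applied to the tumour submatrix on the log2(TPM+1) scale (the
    log is cosmetic for a rank statistic but is the documented convention).
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    rows = {}
    for sample in values.columns:
        col = values[sample]
        s = ssgsea_score(col, stromal_signature, exponent)
        i = ssgsea_score(col, immune_signature, exponent)
        rows[sample] = (s, i, s + i)
    table = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["stromal_score", "immune_score", "composite_score"],
    )
    table.index.name = "sample_id"
    return PurityScores(table)


def _pearson_rows(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each row of X against y; NaN for zero-variance rows."""
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    ynorm = np.sqrt((yc**2).sum())
    xnorm = np.sqrt((Xc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / (xnorm * ynorm)
    r[xnorm == 0] = np.nan
    if ynorm == 0:
        r[:] = np.nan
    return r


def gene_purity_correlation(matrix, scores: PurityScores) -> pd.DataFrame:
    """Per-gene Pearson correlation with the stromal, immune and composite scores.

    Returns a DataFrame indexed by gene id with columns ``stromal_r``,
    ``immune_r``, ``composite_r`` and a boolean ``undefined`` flag for
    zero-variance genes (whose correlations are NaN, not 0).
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if set(values.columns) != set(scores.table.index):
        raise InvalidInputError("sample sets of matrix and scores differ")
    if values.shape[1] < 3:
        raise InsufficientSamplesError(
            f"need >= 3 samples for gene-score correlation, got {values.shape[1]}"
        )
    ordered = scores.table.loc[values.columns]
    X = values.to_numpy(dtype=float)
    out = pd.DataFrame(
        {
            "stromal_r": _pearson_rows(X, ordered["stromal_score"].to_numpy()),
            "immune_r": _pearson_rows(X, ordered["immune_score"].to_numpy()),
            "composite_r": _pearson_rows(X, ordered["composite_score"].to_numpy()),
        },
        index=values.index,
    )
    out["undefined"] = out["stromal_r"].isna() & out["immune_r"].isna()
    return out
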