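"""Differential expression between cell lines and tumours.

Per-gene Welch t tests (unequal variances, Satterthwaite degrees of freedom)
on the log2(TPM+1) scale, Benjamini-Hochberg adjustment, top-fraction
selection, and the purity filter that removes genes correlated with the
stromal or immune scores (|r| > tau) so the remaining ranking reflects
culture-intrinsic change rather than missing non-malignant compartments.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientSamplesError, InvalidInputError
from .ingest import ExpressionMatrix

DEFAULT_TAU = 0.2
DEFAULT_REPORT_R = 0.5

DE_COLUMNS = [
    "t_statistic", "dof", "p_value", "q_value",
    "mean_cell_line", "mean_tumour", "direction",
    "stromal_r", "immune_r", "purity_filtered", "highly_stromal",
]


def welch_t_per_gene(matrix, labels=None) -> pd.DataFrame:
    """Welch's t per gene between the cell_line and tumour groups.

    ``labels``: per-sample group membership (Series or mapping); defaults to
    the matrix annotations' ``source`` column. t > 0 means higher in cell
    lines. Genes with zero variance in both groups get t = 0, p = 1 when the
    means are equal and p = 0 otherwise.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if labels is None:
        labels = matrix.annotations["source"]
    labels = pd.Series(labels).loc[values.columns]
    groups = set(labels)
    if groups != {"cell_line", "tumour"}:
        raise InvalidInputError(f"labels must be cell_line/tumour, got {sorted(groups)}")
    A = values.loc[:, labels == "cell_line"].to_numpy(dtype=float)
    B = values.loc[:, labels == "tumour"].to_numpy(dtype=float)
    n1, n2 = A.shape[1], B.shape[1]
    if n1 < 2 or n2 < 2:
        raise InsufficientSamplesError(
            f"each group needs >= 2 samples (got {n1} cell lines, {n2} tumours)"
        )
    m1, m2 = A.mean(axis=1), B.mean(axis=1)
    v1, v2 = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        dof = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    degenerate = se2 == 0
    t = np.where(degenerate & (diff == 0), 0.0, t)
    t = np.where(degenerate & (diff != 0), np.where(diff > 0, np.inf, -np.inf), t)
    dof = np.where(degenerate, n1 + n2 - 2, dof)
    p = 2 * stats.t.sf(np.abs(t), dof)
    p = np.where(degenerate & (diff == 0), 1.0, p)
    p = np.where(degenerate & (diff != 0), 0.0, p)
    out = pd.DataFrame(
        {
            "t_statistic": t,
            "dof": dof,
            "p_value": p,
            "mean_cell_line": m1,
            "mean_tumour": m2,
            "direction": np.sign(diff),
        },
        index=values.index,
    )
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_de_table(
    matrix,
    purity_correlation: pd.DataFrame = None,
    labels=None,
    tau: float = DEFAULT_TAU,
    report_r: float = DEFAULT_REPORT_R,
) -> pd.DataFrame:
    """Full differential-expression table: Welch stats, BH q-values and,
    when gene-score correlations are supplied, the purity flags.

    ``purity_filtered`` marks genes whose |stromal_r| or |immune_r| exceeds
    ``tau``; ``highly_stromal`` marks stromal_r or immune_r above
    ``report_r`` (the reporting threshold, distinct from the filter).
    """
    de = welch_t_per_gene(matrix, labels)
    de["q_value"] = bh_adjust(de["p_value"].to_numpy())
    if purity_correlation is not None:
        aligned = purity_correlation.reindex(de.index)
        de["stromal_r"] = aligned["stromal_r"]
        de["immune_r"] = aligned["immune_r"]
        sr, ir = de["stromal_r"], de["immune_r"]
        de["purity_filtered"] = (sr.abs() > tau) | (ir.abs() > tau)
        de["highly_stromal"] = (sr > report_r) | (ir > report_r)
        de[["purity_filtered", "highly_stromal"]] = de[
            ["purity_filtered", "highly_stromal"]
        ].fillna(False)
    return de


def top_fraction(de: pd.DataFrame, fraction: float) -> list:
    """The ceil(fraction * n) most significant genes, in significance order.

    Ordering: ascending q, then ascending p, then descending |t|, then gene
    id — fully deterministic.
    """
    if de.shape[0] == 0:
        raise InvalidInputError("empty differential-expression table")
    if not 0 < fraction <= 1:
        raise InvalidInputError(f"fraction must be in (0, 1], got {fraction}")
    n = math.ceil(fraction * de.shape[0])
    ranked = de.assign(_neg_abs_t=-de["t_statistic"].abs()).sort_index().sort_values(
        ["q_value", "p_value", "_neg_abs_t"], kind="mergesort"
    )
    return list(ranked.index[:n])


def purity_filter(de: pd.DataFrame, tau: float = DEFAULT_TAU) -> tuple:
    """Drop genes correlated with the stromal or immune score (|r| > tau).

    Genes with undefined (NaN) correlations are retained. Returns
    (filtered table in original row order, list of removed gene ids).
    """
    if not 0 <= tau <= 1:
        raise InvalidInputError(f"tau must be in [0, 1], got {tau}")
    for col in ("stromal_r", "immune_r"):
        if col not in de.columns:
            raise InvalidInputError("DE table lacks purity correlations; "
                                    "build it with purity_correlation")
    sr, ir = de["stromal_r"], de["immune_r"]
    removed_mask = (sr.abs() > tau) | (ir.abs() > tau)  # NaN compares False
    removed = list(de.index[removed_mask])
    return de.loc[~removed_mask].copy(), removed
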