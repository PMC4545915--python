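"""Gene-set level differences between cell lines and tumours.

Each candidate set's member genes' Welch t statistics (cell line vs tumour)
are compared against the non-member background by a two-sample (Welch) test;
a set's headline statistic is the arithmetic mean of its members' t values.
Per set, "essential" genes — individually significant members whose direction
matches the set call — are identified, and the mean stromal/immune/purity
correlations of those genes quantify how much of the set's perturbation is
attributable to the missing non-malignant compartments rather than to the
malignant cells themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust
from .errors import InvalidInputError

DEFAULT_MAX_SIZE = 200
DEFAULT_MEMBER_ALPHA = 0.05
DEFAULT_SET_Q_CUTOFF = 1e-4


@dataclass
class GeneSet:
    set_id: str
    name: str
    genes: tuple

    def __post_init__(self):
        self.genes = tuple(self.genes)
        if not self.genes:
            raise InvalidInputError(f"gene set {self.set_id!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise InvalidInputError(f"gene set {self.set_id!r} has duplicate genes")


@dataclass
class GeneSetResult:
    set_id: str
    name: str
    mean_t: float
    set_size: int
    p_value: float
    q_value: float = np.nan
    direction: str = ""
    essential_genes: tuple = ()
    mean_stromal_r: float = np.nan
    mean_immune_r: float = np.nan
    mean_purity_r: float = np.nan


def gage_test(de: pd.DataFrame, sets, max_size: int = DEFAULT_MAX_SIZE) -> list:
    """Test each gene set's member t statistics against the background.

    Sets with fewer than 2 or at least ``max_size`` members present in the
    table are excluded (the size rule is strict: "fewer than max_size").
    Significance: two-sided Welch test of member t values versus all
    non-member t values; direction is the sign of (member mean - background
    mean); q-values by BH across the tested sets.
    """
    t_all = de["t_statistic"]
    results = []
    for gs in sets:
        members = [g for g in gs.genes if g in t_all.index]
        m = len(members)
        if m < 2 or m >= max_size:
            continue
        member_t = t_all.loc[members].to_numpy(dtype=float)
        background = t_all.drop(index=members).to_numpy(dtype=float)
        tt = stats.ttest_ind(member_t, background, equal_var=False)
        mean_t = float(member_t.mean())
        results.append(
            GeneSetResult(
                set_id=gs.set_id,
                name=gs.name,
                mean_t=mean_t,
                set_size=m,
                p_value=float(tt.pvalue),
                direction="up" if mean_t >= background.mean() else "down",
            )
        )
    if not results:
        warnings.warn("no gene sets survive the size filter", UserWarning)
        return []
    q = bh_adjust([r.p_value for r in results])
    for r, qi in zip(results, q):
        r.q_value = float(qi)
    return results


def essential_genes(
    result: GeneSetResult,
    gene_set: GeneSet,
    de: pd.DataFrame,
    member_alpha: float = DEFAULT_MEMBER_ALPHA,
) -> tuple:
    """Members that individually drive the set call: q < alpha with a t sign
    matching the set direction."""
    sign = 1.0 if result.direction == "up" else -1.0
    present = [g for g in gene_set.genes if g in de.index]
    ess = tuple(
        g for g in present
        if de.at[g, "q_value"] < member_alpha
        and np.sign(de.at[g, "t_statistic"]) == sign
    )
    result.essential_genes = ess
    return ess


def attribute_purity(result: GeneSetResult, purity_correlation: pd.DataFrame) -> GeneSetResult:
    """Mean stromal/immune/purity correlation over the set's essential genes.

    The purity proxy correlation is the negated composite-score correlation
    (higher composite = more non-malignant content = lower purity). Empty
    essential sets get NaN means.
    """
    ess = [g for g in result.essential_genes if g in purity_correlation.index]
    if not ess:
        result.mean_stromal_r = np.nan
        result.mean_immune_r = np.nan
        result.mean_purity_r = np.nan
        return result
    sub = purity_correlation.loc[ess]
    result.mean_stromal_r = float(sub["stromal_r"].mean())
    result.mean_immune_r = float(sub["immune_r"].mean())
    result.mean_purity_r = float((-sub["composite_r"]).mean())
    return result


def enrichment_analysis(
    de: pd.DataFrame,
    sets,
    purity_correlation: pd.DataFrame = None,
    max_size: int = DEFAULT_MAX_SIZE,
    member_alpha: float = DEFAULT_MEMBER_ALPHA,
) -> list:
    """gage_test + essential genes + purity attribution for every tested set."""
    sets = list(sets)
    by_id = {gs.set_id: gs for gs in sets}
    results = gage_test(de, sets, max_size)
    for r in results:
        essential_genes(r, by_id[r.set_id], de, member_alpha)
        if purity_correlation is not None:
            attribute_purity(r, purity_correlation)
    return results


def results_table(results) -> pd.DataFrame:
    """Tabulate set results in the reporting layout (one row per set)."""
    rows = [
        {
            "set_id": r.set_id,
            "name": r.name,
            "mean_t": r.mean_t,
            "set_size": r.set_size,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "direction": r.direction,
            "n_essential": len(r.essential_genes),
            "mean_stromal_r": r.mean_stromal_r,
            "mean_immune_r": r.mean_immune_r,
            "mean_purity_r": r.mean_purity_r,
        }
        for r in results
    ]
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values("mean_t", ascending=False, kind="mergesort")
    return table.reset_index(drop=True)
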