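"""Ground-truth recovery benchmark on the reference synthetic cohort.

Runs the full analysis on the canonical study conditions (the CohortConfig
defaults: 200 tumours, 50 cell lines, 2000 genes, 8-fold stromal/immune
compartment effects, 4-fold culture effects, malignant fraction ~ Beta(5, 2),
log2 noise sd 0.3) and measures how well each stage recovers the generator's
latent truth: score-vs-fraction correlation, the purity axis in PCA,
precision of the top differentially expressed lists before and after the
purity filter, subtype separation of the cell-line ranking, and the gene-set
contrast between culture-induced and stroma-attributable programs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.metrics import roc_auc_score

from .cohort import CohortConfig, builtin_signatures, generate_cohort
from .de import build_de_table, purity_filter, top_fraction
from .gsea import enrichment_analysis
from .ingest import ExpressionMatrix, log_transform
from .pipeline import _synthetic_gene_sets
from .purity import estimate_scores, gene_purity_correlation
from .structure import (
    COMPARISON_SUBTYPE,
    _pair_correlations,
    correlate_pc_with_scores,
    rank_cell_lines,
    run_pca,
    select_top_variance_genes,
)


def reference_cohort_config(seed: int = 1) -> CohortConfig:
    """The benchmark cohort: generator defaults with the given seed."""
    return dataclasses.replace(CohortConfig(), seed=seed)


def subtype_separation_auc(log_matrix, selected_genes) -> float:
    """AUC separating matched from mismatched subtype assignments.

    Each cell line contributes one mean correlation per tumour subtype
    (positives: its own comparison subtype; negatives: the other subtypes),
    mirroring the mean-correlation ranking statistic.
    """
    ann = log_matrix.annotations
    lines = log_matrix.cell_line_ids()
    tumours = log_matrix.tumour_ids()
    values = log_matrix.values.loc[selected_genes]
    pair_r = _pair_correlations(values, lines, tumours)
    tumour_subtypes = sorted(set(ann.loc[tumours, "subtype"]))
    labels, stats = [], []
    for line in lines:
        own = COMPARISON_SUBTYPE.get(ann.at[line, "subtype"], ann.at[line, "subtype"])
        for subtype in tumour_subtypes:
            cols = [t for t in tumours if ann.at[t, "subtype"] == subtype]
            labels.append(int(subtype == own))
            stats.append(float(pair_r.loc[line, cols].mean()))
    return float(roc_auc_score(labels, stats))


def run_recovery_benchmark(seed: int = 1, de_fraction: float = 0.01) -> dict:
    """All benchmark quantities for one seed, as a flat dict."""
    config = reference_cohort_config(seed)
    matrix, truth = generate_cohort(config)
    log = log_transform(matrix)
    mechanism = truth.gene_mechanism

    stromal_sig, immune_sig = builtin_signatures(truth)
    tumours = log.subset_samples(log.tumour_ids())
    scores = estimate_scores(tumours, stromal_sig, immune_sig)
    truth_stromal = truth.tumour_fractions.loc[scores.table.index, "stromal"]
    r_score_truth = float(np.corrcoef(scores.stromal, truth_stromal)[0, 1])

    selected = select_top_variance_genes(log, min(5000, config.n_genes))
    pca = run_pca(log.values.loc[selected])
    r_pc1_stromal, _ = correlate_pc_with_scores(pca, log.tumour_ids(), scores)

    corr = gene_purity_correlation(tumours, scores)
    de = build_de_table(log, corr)
    top = top_fraction(de, de_fraction)
    top_si = float(np.mean([mechanism[g] in ("stromal", "immune") for g in top]))
    filtered, removed = purity_filter(de)
    top_filtered = top_fraction(filtered, de_fraction)
    top_culture = float(
        np.mean([mechanism[g] in ("culture_up", "culture_down") for g in top_filtered])
    )
    si_in_top = [g for g in top if mechanism[g] in ("stromal", "immune")]
    si_removed = (
        float(np.mean([g in set(removed) for g in si_in_top])) if si_in_top else np.nan
    )

    sub = ExpressionMatrix(log.values.loc[selected], log.scale, log.annotations)
    ranking = rank_cell_lines(sub)
    auc = subtype_separation_auc(log, selected)

    sets = _synthetic_gene_sets(truth)
    results = {r.set_id: r for r in enrichment_analysis(de, sets, corr)}
    culture_up = results["culture_up"]
    stromal_set = results["stromal"]

    return {
        "config": config,
        "stromal_score_truth_r": r_score_truth,
        "pc1_stromal_abs_r": abs(float(r_pc1_stromal)),
        "top_list_size": len(top),
        "top_stromal_immune_fraction": top_si,
        "top_removed_by_filter_fraction": si_removed,
        "filtered_top_list_size": len(top_filtered),
        "filtered_top_culture_fraction": top_culture,
        "n_removed_by_filter": len(removed),
        "subtype_auc": auc,
        "ranking": ranking,
        "culture_up_direction": culture_up.direction,
        "culture_up_q": culture_up.q_value,
        "culture_up_mean_stromal_r": culture_up.mean_stromal_r,
        "stromal_set_mean_stromal_r": stromal_set.mean_stromal_r,
        "stromal_set_direction": stromal_set.direction,
    }
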