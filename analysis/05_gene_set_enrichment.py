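#!/usr/bin/env python
"""Gene-set enrichment with stromal/immune attribution.

Tests mechanism-block gene sets (stromal, immune, culture-induced,
culture-repressed programs) for coordinated shifts between cell lines and
tumours, then averages each set's essential genes' stromal/immune/purity
correlations — separating perturbation caused by the missing
microenvironment from malignant-intrinsic culture change. Writes
results/gene_set_results.tsv.
"""

from pathlib import Path

from purecell import (
    build_de_table,
    builtin_signatures,
    enrichment_analysis,
    estimate_scores,
    gene_purity_correlation,
    generate_cohort,
    results_table,
)
from purecell.benchmark import reference_cohort_config
from purecell.ingest import log_transform
from purecell.pipeline import _synthetic_gene_sets

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main():
    RESULTS.mkdir(parents=True, exist_ok=True)
    matrix, truth = generate_cohort(reference_cohort_config(seed=SEED))
    log = log_transform(matrix)
    stromal_sig, immune_sig = builtin_signatures(truth)
    tumours = log.subset_samples(log.tumour_ids())
    scores = estimate_scores(tumours, stromal_sig, immune_sig)
    corr = gene_purity_correlation(tumours, scores)
    de = build_de_table(log, corr)

    sets = _synthetic_gene_sets(truth)
    results = enrichment_analysis(de, sets, corr)
    table = results_table(results)
    table["significant"] = table["q_value"] < 1e-4
    table.to_csv(RESULTS / "gene_set_results.tsv", sep="\t",
                 float_format="%.4g", index=False)

    print(table.to_string(index=False,
                          columns=["set_id", "mean_t", "set_size", "q_value",
                                   "direction", "mean_stromal_r", "mean_immune_r",
                                   "mean_purity_r"]))
    up = table.set_index("set_id")
    print(
        "\nculture-induced set mean stromal r = %.3f vs stromal program %.3f: "
        "the up-call is malignant-intrinsic, the down-calls are "
        "microenvironment loss" % (
            up.at["culture_up", "mean_stromal_r"],
            up.at["stromal", "mean_stromal_r"],
        )
    )
    print(f"wrote {RESULTS / 'gene_set_results.tsv'}")


if __name__ == "__main__":
    main()
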