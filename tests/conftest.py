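import numpy as np
import pandas as pd
import pytest

from purecell import CohortConfig, builtin_signatures, generate_cohort
from purecell.gmt import write_gmt
from purecell.ingest import log_transform, write_annotations, write_expression

SMALL = CohortConfig(n_tumours=60, n_cell_lines=50, n_genes=400, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-gene, 60-tumour/50-line cohort shared across unit tests."""
    matrix, truth = generate_cohort(SMALL)
    return matrix, truth


@pytest.fixture(scope="session")
def small_log(small_cohort):
    matrix, truth = small_cohort
    return log_transform(matrix), truth


@pytest.fixture(scope="session")
def small_scores(small_log):
    from purecell import estimate_scores

    log, truth = small_log
    stromal, immune = builtin_signatures(truth)
    tumours = log.subset_samples(log.tumour_ids())
    return estimate_scores(tumours, stromal, immune), tumours, truth


@pytest.fixture()
def files_mode_inputs(tmp_path):
    """A tiny on-disk cohort (20 genes x 12 samples) for files-mode runs."""
    cfg = CohortConfig(
        n_tumours=8, n_cell_lines=4, n_genes=20,
        frac_stromal_genes=0.2, frac_immune_genes=0.2,
        frac_culture_up=0.1, frac_culture_down=0.1,
        frac_subtype_genes=0.1, seed=5,
    )
    matrix, truth = generate_cohort(cfg)
    write_expression(matrix, tmp_path / "expression.tsv")
    write_annotations(matrix.annotations, tmp_path / "annotations.tsv")
    write_gmt(builtin_signatures(truth), tmp_path / "signatures.gmt")
    return {
        "expression": str(tmp_path / "expression.tsv"),
        "annotations": str(tmp_path / "annotations.tsv"),
        "signatures": str(tmp_path / "signatures.gmt"),
    }


@pytest.fixture()
def toy_matrix():
    """4 genes x 4 samples with hand-readable values."""
    return pd.DataFrame(
        np.array(
            [
                [1.0, 1.0, 1.0, 1.0],
                [1.0, 5.0, 1.0, 5.0],
                [2.0, 3.0, 4.0, 5.0],
                [9.0, 7.0, 5.0, 3.0],
            ]
        ),
        index=["gA", "gB", "gC", "gD"],
        columns=["s1", "s2", "s3", "s4"],
    )
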