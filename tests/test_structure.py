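import numpy as np
import pandas as pd
import pytest

from purecell import (
    ExpressionMatrix,
    average_cell_line,
    correlate_pc_with_scores,
    correlation_cluster,
    rank_cell_lines,
    run_pca,
    select_top_variance_genes,
    to_newick,
)
from purecell.errors import InsufficientSamplesError, InvalidInputError
from purecell.ingest import make_annotations
from purecell.purity import PurityScores
from purecell.structure import correlation_distance

from .oracles import ward_d2_oracle


class TestSelectTopVarianceGenes:
    def test_orders_by_descending_variance(self):
        df = pd.DataFrame(
            {
                "s1": [5.0, 0.0, 1.0],
                "s2": [5.0, 4.0, 3.0],
            },
            index=["flat", "wide", "mid"],
        )
        # variances: flat 0, wide 8, mid 2
        assert select_top_variance_genes(df, 2) == ["wide", "mid"]
        assert select_top_variance_genes(df, 3) == ["wide", "mid", "flat"]

    def test_tie_broken_lexicographically(self):
        df = pd.DataFrame({"s1": [1.0, 1.0], "s2": [3.0, 3.0]}, index=["b", "a"])
        assert select_top_variance_genes(df, 1) == ["a"]

    def test_k_beyond_gene_count_rejected(self):
        df = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["a"])
        with pytest.raises(InvalidInputError):
            select_top_variance_genes(df, 2)


class TestRunPca:
    def test_rank_one_data_explained_by_pc1(self):
        t = np.linspace(-2, 2, 6)
        df = pd.DataFrame(
            np.outer([1.0, 2.0, -1.0], t) + 5.0,
            index=["g1", "g2", "g3"],
            columns=[f"s{i}" for i in range(6)],
        )
        pca = run_pca(df)
        assert pca.variance_explained[0] == pytest.approx(1.0, abs=1e-9)

    def test_correlated_pair_loading_is_diagonal(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        df = pd.DataFrame([t, t + 1], index=["g1", "g2"], columns=list("abcd"))
        pca = run_pca(df)
        np.testing.assert_allclose(
            pca.component_loadings["PC1"], [1 / np.sqrt(2)] * 2, atol=1e-9
        )

    def test_scores_are_projection_of_centred_data(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(6, 5)),
                          index=[f"g{i}" for i in range(6)],
                          columns=[f"s{i}" for i in range(5)])
        pca = run_pca(df)
        X = df.to_numpy().T
        Xc = X - X.mean(axis=0)
        np.testing.assert_allclose(
            Xc @ pca.component_loadings.to_numpy(), pca.sample_scores, atol=1e-8
        )

    def test_reconstruction_with_all_components(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(5, 5)),
                          index=[f"g{i}" for i in range(5)],
                          columns=[f"s{i}" for i in range(5)])
        pca = run_pca(df)
        X = df.to_numpy().T
        Xc = X - X.mean(axis=0)
        recon = pca.sample_scores.to_numpy() @ pca.component_loadings.to_numpy().T
        np.testing.assert_allclose(recon, Xc, atol=1e-8)

    def test_variance_explained_nonincreasing_and_loadings_orthonormal(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(8, 7)),
                          index=[f"g{i}" for i in range(8)],
                          columns=[f"s{i}" for i in range(7)])
        pca = run_pca(df)
        ve = pca.variance_explained
        assert (np.diff(ve) <= 1e-12).all() and ve.sum() <= 1 + 1e-9
        L = pca.component_loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)

    def test_constant_matrix_rejected(self):
        df = pd.DataFrame(np.ones((3, 4)), index=list("abc"), columns=list("wxyz"))
        with pytest.raises(InvalidInputError):
            run_pca(df)


class TestCorrelatePcWithScores:
    def _scores(self, stromal, immune):
        table = pd.DataFrame(
            {
                "stromal_score": stromal,
                "immune_score": immune,
                "composite_score": np.asarray(stromal) + np.asarray(immune),
            },
            index=[f"s{i}" for i in range(len(stromal))],
        )
        return PurityScores(table)

    def test_scores_equal_to_pc_give_r_one(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(6, 5)),
                          index=[f"g{i}" for i in range(6)],
                          columns=[f"s{i}" for i in range(5)])
        pca = run_pca(df)
        pc1 = pca.sample_scores["PC1"].to_numpy()
        scores = self._scores(pc1, -pc1)
        r_s, r_i = correlate_pc_with_scores(pca, df.columns, scores)
        assert r_s == pytest.approx(1.0) and r_i == pytest.approx(-1.0)

    def test_too_few_tumours_rejected(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 4)),
                          index=list("abcd"), columns=[f"s{i}" for i in range(4)])
        pca = run_pca(df)
        with pytest.raises(InsufficientSamplesError):
            correlate_pc_with_scores(pca, ["s0", "s1"], self._scores([1, 2], [1, 2]))


class TestCorrelationCluster:
    def test_identical_samples_merge_first_at_zero_height(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=8)
        df = pd.DataFrame(
            {"a": base, "b": base, "c": rng.normal(size=8), "d": rng.normal(size=8)},
            index=[f"g{i}" for i in range(8)],
        )
        cluster = correlation_cluster(df)
        assert cluster.heights[0] == pytest.approx(0.0, abs=1e-7)
        assert set(cluster.linkage_matrix[0, :2]) == {0.0, 1.0}

    def test_anticorrelated_samples_at_distance_two(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        df = pd.DataFrame({"a": x, "b": -x}, index=[f"g{i}" for i in range(4)])
        d = correlation_distance(df)
        assert d.at["a", "b"] == pytest.approx(2.0)

    def test_distances_lie_in_zero_two(self, small_log):
        log, _ = small_log
        d = correlation_distance(log.values.iloc[:, :20]).to_numpy()
        assert (d >= -1e-12).all() and (d <= 2 + 1e-12).all()

    def test_merge_heights_nondecreasing(self, small_log):
        log, _ = small_log
        cluster = correlation_cluster(log.values.iloc[:, :30])
        assert (np.diff(cluster.heights) >= -1e-10).all()

    def test_matches_exhaustive_ward_d2_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            df = pd.DataFrame(rng.normal(size=(12, 6)),
                              index=[f"g{i}" for i in range(12)],
                              columns=[f"s{i}" for i in range(6)])
            cluster = correlation_cluster(df)
            d = correlation_distance(df).to_numpy()
            expected = ward_d2_oracle(d)
            # same merge heights in the same order
            np.testing.assert_allclose(
                cluster.heights, [h for _, _, h in expected], rtol=1e-8
            )
            # and the same cluster compositions at each step
            n = d.shape[0]
            members = {i: frozenset([i]) for i in range(n)}
            for step, (left, right, _) in enumerate(expected):
                i, j = int(cluster.linkage_matrix[step, 0]), int(cluster.linkage_matrix[step, 1])
                got = members[i] | members[j]
                members[n + step] = got
                assert got == left | right

    def test_zero_variance_sample_named_in_error(self):
        df = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [4.0, 4.0, 4.0]},
                          index=list("abc"))
        with pytest.raises(InvalidInputError, match="flat"):
            correlation_cluster(df)

    def test_newick_export_contains_all_leaves(self, small_log):
        log, _ = small_log
        sub = log.values.iloc[:, :10]
        nwk = to_newick(correlation_cluster(sub))
        assert nwk.endswith(";") and nwk.count(",") == 9
        for sample in sub.columns:
            assert sample in nwk


def _toy_ranking_matrix():
    """3 lines (one claudin-low) and 3 tumours with designed correlations."""
    rng = np.random.default_rng(8)
    lum = rng.normal(size=30)
    bas = rng.normal(size=30)
    values = pd.DataFrame(
        {
            "lineL": lum + rng.normal(0, 0.1, 30),
            "lineB": bas + rng.normal(0, 0.1, 30),
            "lineCL": bas + rng.normal(0, 0.5, 30),
            "tumL": lum + rng.normal(0, 0.1, 30),
            "tumB1": bas + rng.normal(0, 0.1, 30),
            "tumB2": bas + rng.normal(0, 0.1, 30),
        },
        index=[f"g{i}" for i in range(30)],
    )
    ann = make_annotations(
        values.columns,
        ["cell_line", "cell_line", "cell_line", "tumour", "tumour", "tumour"],
        subtype=["luminal", "basal", "claudin_low", "luminal", "basal", "basal"],
    )
    return ExpressionMatrix(values, "log2_tpm_plus1", ann)


class TestRankCellLines:
    def test_exact_match_tops_ranking(self):
        x = np.random.default_rng(9).normal(size=20)
        values = pd.DataFrame(
            {"line": x, "tum": x},
            index=[f"g{i}" for i in range(20)],
        )
        ann = make_annotations(["line", "tum"], ["cell_line", "tumour"],
                               subtype=["basal", "basal"])
        table = rank_cell_lines(ExpressionMatrix(values, "log2_tpm_plus1", ann))
        assert table.loc[0, "mean_correlation"] == pytest.approx(1.0)
        assert table.loc[0, "rank"] == 1

    def test_claudin_low_compared_with_basal_tumours(self):
        table = rank_cell_lines(_toy_ranking_matrix())
        row = table[table.cell_line_id == "lineCL"].iloc[0]
        assert row["comparison_subtype"] == "basal"
        # the noisier claudin-low line ranks below the clean basal line
        assert row["rank"] == 2

    def test_ranks_are_permutation_within_group(self, small_log):
        log, _ = small_log
        table = rank_cell_lines(log)
        for _, group in table.groupby("comparison_subtype"):
            assert sorted(group["rank"]) == list(range(1, len(group) + 1))
            assert group["mean_correlation"].is_monotonic_decreasing

    def test_tumour_order_irrelevant(self):
        matrix = _toy_ranking_matrix()
        shuffled = ExpressionMatrix(
            matrix.values[["tumB2", "lineCL", "tumL", "lineL", "tumB1", "lineB"]],
            matrix.scale,
            matrix.annotations.loc[["tumB2", "lineCL", "tumL", "lineL", "tumB1", "lineB"]],
        )
        a = rank_cell_lines(matrix).set_index("cell_line_id")["mean_correlation"]
        b = rank_cell_lines(shuffled).set_index("cell_line_id")["mean_correlation"]
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())

    def test_missing_tumour_subtype_rejected(self):
        matrix = _toy_ranking_matrix()
        keep = ["lineL", "lineB", "lineCL", "tumL"]  # no basal tumours
        with pytest.raises(InvalidInputError, match="basal"):
            rank_cell_lines(matrix.subset_samples(keep))


class TestAverageCellLine:
    def test_identical_lines_average_to_themselves(self):
        x = np.random.default_rng(10).normal(size=15)
        values = pd.DataFrame(
            {"l1": x, "l2": x, "tum": x + 0.1},
            index=[f"g{i}" for i in range(15)],
        )
        ann = make_annotations(values.columns,
                               ["cell_line", "cell_line", "tumour"],
                               subtype=["basal"] * 3)
        matrix = ExpressionMatrix(values, "log2_tpm_plus1", ann)
        profile, mean_r = average_cell_line(matrix, "basal")
        np.testing.assert_allclose(profile, x)
        assert mean_r == pytest.approx(1.0)

    def test_average_beats_typical_line(self, small_log):
        """Noise averaging: the fictional mean profile correlates with
        tumours at least as well as the average individual line."""
        log, _ = small_log
        table = rank_cell_lines(log)
        for subtype, group in table.groupby("comparison_subtype"):
            _, avg_r = average_cell_line(log, subtype)
            assert avg_r >= group["mean_correlation"].mean()

    def test_single_line_rejected(self):
        x = np.random.default_rng(11).normal(size=10)
        values = pd.DataFrame({"l1": x, "tum": x},
                              index=[f"g{i}" for i in range(10)])
        ann = make_annotations(values.columns, ["cell_line", "tumour"],
                               subtype=["basal", "basal"])
        with pytest.raises(InvalidInputError):
            average_cell_line(ExpressionMatrix(values, "log2_tpm_plus1", ann), "basal")
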