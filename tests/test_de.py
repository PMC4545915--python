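import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from purecell import bh_adjust, build_de_table, purity_filter, top_fraction, welch_t_per_gene
from purecell.errors import InsufficientSamplesError, InvalidInputError

from .oracles import bh_oracle, welch_oracle


def _two_group_frame(cell_lines, tumours):
    """One-gene frame with the given per-group values."""
    cl = [f"c{i}" for i in range(len(cell_lines))]
    tm = [f"t{i}" for i in range(len(tumours))]
    df = pd.DataFrame([list(cell_lines) + list(tumours)], index=["g"],
                      columns=cl + tm, dtype=float)
    labels = pd.Series(["cell_line"] * len(cl) + ["tumour"] * len(tm), index=cl + tm)
    return df, labels


class TestWelchT:
    def test_hand_computed_example(self):
        """Groups {1,2,3} vs {2,3,4}: means 2 vs 3, both variances 1,
        se = sqrt(2/3), so t = -1.2247, df = 4, p = 0.2879."""
        df, labels = _two_group_frame([1, 2, 3], [2, 3, 4])
        out = welch_t_per_gene(df, labels)
        assert out.at["g", "t_statistic"] == pytest.approx(-1.224745, abs=1e-6)
        assert out.at["g", "dof"] == pytest.approx(4.0, abs=1e-9)
        assert out.at["g", "p_value"] == pytest.approx(0.287864, abs=1e-6)

    def test_equal_means_give_zero_t(self):
        df, labels = _two_group_frame([1, 2, 3], [0, 2, 4])
        out = welch_t_per_gene(df, labels)
        assert out.at["g", "t_statistic"] == 0.0
        assert out.at["g", "p_value"] == pytest.approx(1.0)

    def test_label_swap_negates_t(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(5, 10)),
                          index=[f"g{i}" for i in range(5)],
                          columns=[f"s{i}" for i in range(10)])
        labels = pd.Series(["cell_line"] * 4 + ["tumour"] * 6, index=df.columns)
        swapped = labels.map({"cell_line": "tumour", "tumour": "cell_line"})
        a = welch_t_per_gene(df, labels)
        b = welch_t_per_gene(df, swapped)
        np.testing.assert_allclose(a["t_statistic"], -b["t_statistic"], atol=1e-12)
        np.testing.assert_allclose(a["p_value"], b["p_value"], atol=1e-12)

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(20, 12)),
                          index=[f"g{i}" for i in range(20)],
                          columns=[f"s{i}" for i in range(12)])
        labels = pd.Series(["cell_line"] * 5 + ["tumour"] * 7, index=df.columns)
        out = welch_t_per_gene(df, labels)
        for g in df.index:
            t, dof, p = welch_oracle(df.loc[g][:5], df.loc[g][5:])
            assert out.at[g, "t_statistic"] == pytest.approx(t, abs=1e-10)
            assert out.at[g, "dof"] == pytest.approx(dof, abs=1e-10)
            assert out.at[g, "p_value"] == pytest.approx(p, abs=1e-10)

    def test_degenerate_zero_variance_genes(self):
        df = pd.DataFrame(
            [[2.0, 2.0, 2.0, 2.0, 2.0], [1.0, 1.0, 3.0, 3.0, 3.0]],
            index=["flat_equal", "flat_shifted"],
            columns=[f"s{i}" for i in range(5)],
        )
        labels = pd.Series(["cell_line"] * 2 + ["tumour"] * 3, index=df.columns)
        out = welch_t_per_gene(df, labels)
        assert out.at["flat_equal", "t_statistic"] == 0.0
        assert out.at["flat_equal", "p_value"] == 1.0
        assert out.at["flat_shifted", "t_statistic"] == -np.inf
        assert out.at["flat_shifted", "p_value"] == 0.0

    def test_small_group_rejected(self):
        df, labels = _two_group_frame([1], [2, 3, 4])
        with pytest.raises(InsufficientSamplesError):
            welch_t_per_gene(df, labels)


class TestBhAdjust:
    def test_step_up_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.37]), [0.37])

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            bh_adjust([0.1, 1.5])

    @given(
        st.lists(
            st.sampled_from([0.001, 0.01, 0.02, 0.04, 0.2, 0.5, 0.77, 1.0]),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_definition_oracle(self, p_values):
        np.testing.assert_allclose(bh_adjust(p_values), bh_oracle(p_values), atol=1e-12)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all()


def _dummy_de(n, seed=0):
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=n)
    de = pd.DataFrame(
        {
            "t_statistic": rng.normal(size=n),
            "p_value": p,
            "q_value": bh_adjust(p),
        },
        index=[f"g{i:05d}" for i in range(n)],
    )
    return de


class TestTopFraction:
    def test_counts_use_ceiling(self):
        assert len(top_fraction(_dummy_de(1000), 0.01)) == 10
        assert len(top_fraction(_dummy_de(1000), 0.0101)) == 11

    def test_fraction_one_returns_everything(self):
        de = _dummy_de(37)
        assert set(top_fraction(de, 1.0)) == set(de.index)

    def test_ordered_by_significance(self):
        de = _dummy_de(200, seed=3)
        top = top_fraction(de, 0.05)
        qs = de.loc[top, "q_value"]
        assert qs.is_monotonic_increasing
        assert qs.max() <= de["q_value"].drop(top).min() + 1e-12

    def test_ties_resolved_deterministically(self):
        de = pd.DataFrame(
            {
                "t_statistic": [2.0, -3.0, 2.0],
                "p_value": [0.01, 0.01, 0.01],
                "q_value": [0.03, 0.03, 0.03],
            },
            index=["b", "a", "c"],
        )
        # equal q and p: larger |t| first, then gene id
        assert top_fraction(de, 1.0) == ["a", "b", "c"]

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            top_fraction(_dummy_de(10), 0.0)
        with pytest.raises(InvalidInputError):
            top_fraction(_dummy_de(10).iloc[:0], 0.5)


class TestPurityFilter:
    def _with_corr(self, stromal_r, immune_r=None):
        n = len(stromal_r)
        de = _dummy_de(n, seed=4)
        de["stromal_r"] = stromal_r
        de["immune_r"] = immune_r if immune_r is not None else [0.0] * n
        return de

    def test_threshold_is_strict_absolute(self):
        de = self._with_corr([0.5, 0.1, -0.3])
        filtered, removed = purity_filter(de, tau=0.2)
        assert removed == ["g00000", "g00002"]
        assert list(filtered.index) == ["g00001"]

    def test_tau_one_removes_nothing(self):
        de = self._with_corr([0.99, -1.0, 0.0])
        _, removed = purity_filter(de, tau=1.0)
        assert removed == []

    def test_tau_zero_removes_all_nonzero(self):
        de = self._with_corr([0.01, 0.0, -0.02], immune_r=[0.0, 0.0, 0.0])
        filtered, removed = purity_filter(de, tau=0.0)
        assert set(removed) == {"g00000", "g00002"}

    def test_undefined_correlations_retained(self):
        de = self._with_corr([np.nan, 0.9], immune_r=[np.nan, 0.0])
        filtered, removed = purity_filter(de, tau=0.2)
        assert list(filtered.index) == ["g00000"]
        assert removed == ["g00001"]

    def test_immune_correlation_also_filters(self):
        de = self._with_corr([0.0, 0.0], immune_r=[0.5, -0.1])
        _, removed = purity_filter(de, tau=0.2)
        assert removed == ["g00000"]

    def test_filtered_ranking_is_subsequence_of_unfiltered(self):
        rng = np.random.default_rng(5)
        de = self._with_corr(rng.uniform(-1, 1, 300), rng.uniform(-1, 1, 300))
        full = top_fraction(de, 1.0)
        filtered, _ = purity_filter(de, tau=0.3)
        sub = top_fraction(filtered, 1.0)
        it = iter(full)
        assert all(g in it for g in sub)  # subsequence check

    def test_bad_tau_rejected(self):
        with pytest.raises(InvalidInputError):
            purity_filter(self._with_corr([0.1]), tau=1.5)

    def test_missing_columns_rejected(self):
        with pytest.raises(InvalidInputError):
            purity_filter(_dummy_de(5), tau=0.2)


def test_build_de_table_flags_consistent(small_log, small_scores):
    log, truth = small_log
    scores, tumours, _ = small_scores
    from purecell import gene_purity_correlation

    corr = gene_purity_correlation(tumours, scores)
    de = build_de_table(log, corr, tau=0.2, report_r=0.5)
    assert (de["q_value"] >= de["p_value"] - 1e-12).all()
    expected_flag = (de["stromal_r"].abs() > 0.2) | (de["immune_r"].abs() > 0.2)
    assert de["purity_filtered"].equals(expected_flag.fillna(False))
    expected_high = (de["stromal_r"] > 0.5) | (de["immune_r"] > 0.5)
    assert de["highly_stromal"].equals(expected_high.fillna(False))
    assert len(de) == log.values.shape[0]
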