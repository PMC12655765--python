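"""Correlation engine: coefficients, Holm step-down, QC and retention."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pgxnet as px
from pgxnet import correlation as corr


class TestCoefficients:
    @pytest.mark.parametrize(
        ("x", "y", "expected"),
        [
            ([1, 2, 3], [2, 4, 6], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
        ],
    )
    def test_pearson_values(self, x, y, expected):
        r, p, n = px.pearson_correlation(x, y)
        assert r == pytest.approx(expected, abs=1e-12)
        assert n == len(x)
        assert 0 <= p <= 1

    @pytest.mark.parametrize(
        ("x", "y", "expected"),
        [
            ([1, 2, 3], [1, 4, 9], 1.0),
            ([1, 2, 3], [9, 4, 1], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
        ],
    )
    def test_spearman_values(self, x, y, expected):
        rho, p, n = px.spearman_correlation(x, y)
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_pairwise_deletion(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 1.0, 3.0, np.nan, 4.0]
        r_xy = px.pearson_correlation(x, y)
        r_yx = px.pearson_correlation(y, x)
        assert r_xy == r_yx
        assert r_xy[2] == 3  # only 3 complete positions

    def test_untestable_pairs_flagged_not_raised(self):
        r, p, n = px.pearson_correlation([1, np.nan, np.nan], [1, 2, 3])
        assert np.isnan(r) and n == 1
        r, p, n = px.pearson_correlation([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(r)

    def test_pvalue_matches_scipy(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        from scipy import stats
        r, p, _ = px.pearson_correlation(x, y)
        r_sp, p_sp = stats.pearsonr(x, y)
        assert r == pytest.approx(r_sp, abs=1e-12)
        assert p == pytest.approx(p_sp, rel=1e-6)


class TestHolm:
    @pytest.mark.parametrize(
        ("p", "expected"),
        [
            ([0.01, 0.02, 0.03], [0.03, 0.04, 0.04]),
            ([0.5], [0.5]),
            ([0.05, 0.05], [0.10, 0.10]),
        ],
    )
    def test_step_down_examples(self, p, expected):
        np.testing.assert_allclose(px.holm_adjust(p), expected, atol=1e-12)

    def test_invalid_values_raise(self):
        with pytest.raises(ValueError):
            px.holm_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            px.holm_adjust([-0.1])

    @settings(max_examples=200, derandomize=True)
    @given(p=st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_bracketed_by_raw_and_bonferroni(self, p):
        adj = px.holm_adjust(p)
        m = len(p)
        for raw, a in zip(p, adj):
            assert raw - 1e-12 <= a <= min(1.0, m * raw) + 1e-12

    @settings(max_examples=100, derandomize=True)
    @given(p=st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=20),
           seed=st.integers(0, 10))
    def test_permutation_invariance(self, p, seed):
        perm = np.random.default_rng(seed).permutation(len(p))
        adj = px.holm_adjust(p)
        adj_perm = px.holm_adjust(np.asarray(p)[perm])
        np.testing.assert_allclose(adj_perm, adj[perm], atol=1e-12)


class TestQC:
    def test_removals(self):
        act = pd.DataFrame(
            np.random.default_rng(0).standard_normal((5, 60)),
            index=[f"D{i}" for i in range(5)],
            columns=[f"c{i}" for i in range(60)],
        )
        act.iloc[0, :] = np.nan                 # all missing
        act.iloc[1, :] = 3.14                   # constant
        act.iloc[2, 10:] = np.nan               # only 10 observations
        kept, log = px.qc_filter_drugs(act)
        assert list(kept.index) == ["D3", "D4"]
        assert set(log["drug_id"]) == {"D0", "D1", "D2"}
        assert (log.set_index("drug_id").loc["D1", "reason"] == "low_variance")

    def test_all_removed_raises(self):
        act = pd.DataFrame(np.ones((2, 60)), index=["a", "b"])
        with pytest.raises(ValueError):
            px.qc_filter_drugs(act)


class TestCorrelateAll:
    def test_cardinality_and_determinism(self, small_panel):
        E = small_panel.expression.iloc[:3]
        A = small_panel.activity.iloc[:2]
        recs = px.correlate_all(E, A)
        assert len(recs) == 6
        pd.testing.assert_frame_equal(recs, px.correlate_all(E, A))

    def test_planted_pair_recovered_exactly(self, small_panel):
        recs = px.correlate_all(small_panel.expression, small_panel.activity)
        anchors = small_panel.anchor_genes()
        for d, g in anchors.items():
            row = recs[(recs.drug_id == d) & (recs.gene_id == g)].iloc[0]
            assert row.pearson_r == pytest.approx(0.6, abs=1e-12)

    def test_cell_line_mismatch_names_offenders(self, small_panel):
        A = small_panel.activity.rename(columns={"BREA_1": "WRONG"})
        with pytest.raises(ValueError, match="WRONG"):
            px.correlate_all(small_panel.expression, A)

    def test_pair_with_too_few_obs_flagged(self):
        cols = [f"c{i}" for i in range(5)]
        E = pd.DataFrame([[1.0, 2.0, np.nan, np.nan, np.nan]],
                         index=["g"], columns=cols)
        A = pd.DataFrame([[1.0, 0.5, 2.0, 3.0, 1.5]], index=["d"], columns=cols)
        recs = px.correlate_all(E, A)
        assert not recs.iloc[0]["testable"]
        assert np.isnan(recs.iloc[0]["holm_p"])

    def test_dense_path_agrees_with_pairwise_path(self, small_panel):
        E = small_panel.expression.iloc[:6].copy()
        A = small_panel.activity.iloc[:3].copy()
        dense = px.correlate_all(E, A)
        E2 = E.copy()
        E2.iloc[0, 0] = np.nan  # forces the pairwise-complete path
        sparse = px.correlate_all(E2, A)
        unaffected = sparse[sparse.gene_id != E.index[0]].reset_index(drop=True)
        dense_match = dense[dense.gene_id != E.index[0]].reset_index(drop=True)
        for col in ("pearson_r", "pearson_p", "spearman_rho", "spearman_p"):
            np.testing.assert_allclose(unaffected[col], dense_match[col], atol=1e-10)


class TestFilter:
    def _record(self, r, holm_p, rho=None):
        return pd.DataFrame({
            "drug_id": ["d"], "gene_id": ["g"], "n_obs": [60],
            "pearson_r": [r], "pearson_p": [0.001],
            "spearman_rho": [rho if rho is not None else r], "spearman_p": [0.001],
            "holm_p": [holm_p], "holm_p_spearman": [holm_p], "testable": [True],
        })

    def test_thresholds_inclusive(self):
        assert len(px.filter_records(self._record(0.334, 0.05))) == 1

    def test_boundary_below_dropped(self):
        assert len(px.filter_records(self._record(0.333, 0.001))) == 0

    def test_negative_r_dropped_under_positive_sign_mode(self):
        assert len(px.filter_records(self._record(-0.9, 1e-8))) == 0
        both = corr.FilterPolicy(sign_mode="both")
        assert len(px.filter_records(self._record(-0.9, 1e-8), both)) == 1

    def test_modes(self):
        rec = self._record(0.2, 0.01, rho=0.9)
        assert len(px.filter_records(rec)) == 0
        either = corr.FilterPolicy(coefficient_mode="either")
        assert len(px.filter_records(rec, either)) == 1
        both = corr.FilterPolicy(coefficient_mode="both")
        assert len(px.filter_records(rec, both)) == 0

    def test_sorted_by_drug_then_descending_r(self, small_records):
        kept = px.filter_records(small_records)
        for _, sub in kept.groupby("drug_id"):
            assert (sub["pearson_r"].diff().dropna() <= 1e-12).all()


def test_holm_against_statsmodels_oracle(small_records):
    from statsmodels.stats.multitest import multipletests
    testable = small_records[small_records.testable]
    for _, sub in testable.groupby("drug_id"):
        _, expected, _, _ = multipletests(sub["pearson_p"], method="holm")
        np.testing.assert_allclose(sub["holm_p"], expected, atol=1e-12)


def test_correlation_table_round_trip(tmp_path, small_records):
    path = tmp_path / "corr.tsv"
    corr.write_correlation_table(small_records, path)
    back = corr.read_correlation_table(path)
    assert len(back) == len(small_records)
    assert back["retained"].sum() == len(px.filter_records(small_records))
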