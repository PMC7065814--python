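"""Splitting, summary statistics, correlation screen and model scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wheatgpc import (
    FitReport,
    compare_models,
    correlation_matrix,
    score,
    split_samples,
    standard_error,
    summary_stats,
)
from wheatgpc.errors import EvaluationError
from wheatgpc.evaluation import render_markdown, summary_table


class TestSplit:
    def test_study_sized_split(self, rng):
        y = rng.normal(12, 1.4, 255)
        split = split_samples(y, seed=1)
        assert split.modeling_ids.size == 153
        assert split.verification_ids.size == 102

    def test_extremes_forced_into_modeling(self, rng):
        y = rng.normal(12, 1.4, 255)
        for seed in range(10):
            split = split_samples(y, seed=seed)
            assert int(np.argmin(y)) in split.modeling_ids
            assert int(np.argmax(y)) in split.modeling_ids

    def test_minimal_split(self):
        y = np.array([3.0, 1.0, 2.0, 5.0, 4.0])
        split = split_samples(y, seed=0)
        assert split.modeling_ids.size == 3
        assert 1 in split.modeling_ids and 3 in split.modeling_ids

    def test_partition_properties(self, rng):
        y = rng.normal(size=101)
        split = split_samples(y, seed=3)
        union = np.union1d(split.modeling_ids, split.verification_ids)
        np.testing.assert_array_equal(union, np.arange(101))
        assert np.intersect1d(split.modeling_ids, split.verification_ids).size == 0
        assert split.modeling_ids.size == round(0.6 * 101)

    def test_determinism(self, rng):
        y = rng.normal(size=60)
        a = split_samples(y, seed=9)
        b = split_samples(y, seed=9)
        np.testing.assert_array_equal(a.modeling_ids, b.modeling_ids)

    def test_too_small_rejected(self):
        with pytest.raises(EvaluationError):
            split_samples(np.arange(4))


class TestSummary:
    @pytest.mark.parametrize("sd,n,expected", [(1.33, 153, 0.11), (1.42, 102, 0.14)])
    def test_standard_error_table_values(self, sd, n, expected):
        assert round(standard_error(sd, n), 2) == expected

    def test_summary_stats_fields(self, rng):
        y = rng.normal(12, 1.4, 100)
        s = summary_stats(y)
        assert s["n"] == 100
        assert s["sd"] == pytest.approx(np.std(y, ddof=1))
        assert s["se"] == pytest.approx(s["sd"] / 10)
        assert s["min"] == y.min() and s["max"] == y.max()

    def test_constant_vector(self):
        s = summary_stats(np.full(10, 12.0))
        assert s["sd"] == 0.0 and s["se"] == 0.0

    def test_summary_table_rows(self, rng):
        y = rng.normal(12, 1.4, 50)
        split = split_samples(y, seed=0)
        t = summary_table(y, split)
        assert list(t.index) == ["modeling", "verification"]
        assert t.loc["modeling", "n"] == split.modeling_ids.size


class TestCorrelation:
    def test_matches_direct_formula_oracle(self, table_255):
        screen = correlation_matrix(table_255)
        r = screen.r
        assert list(r.columns)[0] == "GPC"
        # textbook covariance formula on a spot-checked pair
        x = table_255.data["NDVI"].to_numpy()
        y = table_255.y.to_numpy()
        rxy = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r.loc["NDVI", "GPC"] == pytest.approx(rxy, abs=1e-12)

    def test_symmetry_diagonal_range(self, table_255):
        r = correlation_matrix(table_255).r.to_numpy()
        np.testing.assert_allclose(r, r.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(r), 1.0, atol=1e-12)
        assert np.all(np.abs(r) <= 1.0 + 1e-12)

    def test_significance_flags(self, table_255):
        screen = correlation_matrix(table_255)
        # NDVI-GPC is a strong correlation at n=255: flagged at both levels
        assert screen.sig_01.loc["NDVI", "GPC"]
        assert screen.sig_05.loc["NDVI", "GPC"]

    def test_no_response_rejected(self, table_255):
        stripped = type(table_255)(data=table_255.data.copy(), y=None)
        with pytest.raises(EvaluationError):
            correlation_matrix(stripped)


class TestScore:
    def test_perfect_prediction(self):
        y = np.array([10.0, 11.0, 13.0])
        rep = score(y, y)
        assert rep.rmse == 0.0
        assert rep.r2 == pytest.approx(1.0)
        assert rep.accuracy == pytest.approx(100.0)
        assert rep.slope == pytest.approx(1.0) and rep.intercept == pytest.approx(0.0)

    def test_rmse_hand_value(self):
        rep = score(np.array([0.0, 2.0]), np.array([1.0, 1.0]))
        assert rep.rmse == pytest.approx(1.0)

    def test_literal_mae_definition(self):
        rep = score(
            np.array([10.0, 12.0, 14.0]),
            np.array([11.0, 12.0, 13.0]),
            accuracy_definition="mae",
        )
        assert rep.mae == pytest.approx(2.0 / 3.0)
        assert rep.accuracy == pytest.approx(2.0 / 3.0)
        assert rep.accuracy_definition == "mae"

    def test_relative_accuracy_definition(self):
        rep = score(np.array([10.0, 12.0, 14.0]), np.array([11.0, 12.0, 13.0]))
        assert rep.accuracy == pytest.approx((1 - (2.0 / 3.0) / 12.0) * 100)

    def test_rmse_at_least_mae(self, rng):
        for _ in range(20):
            y = rng.normal(12, 1.4, 30)
            yhat = y + rng.normal(0, 0.5, 30)
            rep = score(y, yhat)
            assert rep.rmse >= rep.mae - 1e-15

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(12, 1.4, 25)
        yhat = y + rng.normal(0, 0.4, 25)
        perm = rng.permutation(25)
        a, b = score(y, yhat), score(y[perm], yhat[perm])
        assert a.rmse == pytest.approx(b.rmse, abs=1e-12)
        assert a.r2 == pytest.approx(b.r2, abs=1e-12)
        assert a.accuracy == pytest.approx(b.accuracy, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(EvaluationError):
            score(np.arange(4), np.arange(5))


def make_report(label, n, accuracy):
    return FitReport(
        label=label, n=n, rmse=0.5, mae=0.4, r2=0.8, r2_identity=0.8,
        accuracy=accuracy, accuracy_definition="relative", slope=1.0, intercept=0.0,
    )


class TestCompare:
    def test_pairwise_accuracy_deltas(self):
        reports = {
            "PLS": {"modeling": make_report("modeling", 153, 94.7),
                    "verification": make_report("verification", 102, 91.8)},
            "LR": {"modeling": make_report("modeling", 153, 74.1),
                   "verification": make_report("verification", 102, 69.4)},
            "PCA": {"modeling": make_report("modeling", 153, 79.3),
                    "verification": make_report("verification", 102, 75.5)},
        }
        cmpres = compare_models(reports)
        d = cmpres.accuracy_deltas.set_index(["algorithm_a", "algorithm_b", "set"])
        assert d.loc[("PLS", "LR", "modeling"), "accuracy_delta"] == pytest.approx(20.6)
        assert d.loc[("PLS", "LR", "verification"), "accuracy_delta"] == pytest.approx(22.4)
        assert d.loc[("PLS", "PCA", "modeling"), "accuracy_delta"] == pytest.approx(15.4)
        assert d.loc[("PLS", "PCA", "verification"), "accuracy_delta"] == pytest.approx(16.3)

    def test_identical_reports_zero_deltas(self):
        reports = {
            "A": {"modeling": make_report("modeling", 10, 90.0)},
            "B": {"modeling": make_report("modeling", 10, 90.0)},
        }
        cmpres = compare_models(reports)
        assert (cmpres.accuracy_deltas["accuracy_delta"] == 0).all()

    def test_mismatched_splits_rejected(self):
        reports = {
            "A": {"modeling": make_report("modeling", 10, 90.0)},
            "B": {"modeling": make_report("modeling", 12, 90.0)},
        }
        with pytest.raises(EvaluationError, match="mismatched"):
            compare_models(reports)


def test_render_markdown_rounds():
    frame = pd.DataFrame({"a": [1.23456], "b": ["x"]})
    text = render_markdown(frame)
    assert "1.23" in text and "| a | b |" in text
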