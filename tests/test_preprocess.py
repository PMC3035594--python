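"""Quantile normalization and presence-call contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ildnet import ExpressionMatrix, quantile_normalize, call_presence, apply_presence_filter
from ildnet.matrix import MIRNA


def _mat(arr, kind="mrna"):
    arr = np.asarray(arr, dtype=float)
    return ExpressionMatrix(pd.DataFrame(
        arr, index=[f"f{i}" for i in range(arr.shape[0])],
        columns=[f"s{j}" for j in range(arr.shape[1])]), kind)


class TestQuantileNormalize:
    def test_two_column_hand_example(self):
        # per-rank means of [1,2,3] and [4,5,6] are [2.5, 3.5, 4.5]
        out = quantile_normalize(_mat([[1, 4], [2, 5], [3, 6]]))
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        np.testing.assert_allclose(out.values.to_numpy(), expected)

    def test_identical_columns_unchanged(self):
        m = _mat([[1, 1], [5, 5], [3, 3]])
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_ranks_preserved_within_columns(self):
        rng = np.random.default_rng(0)
        m = _mat(rng.standard_normal((30, 5)))
        out = quantile_normalize(m)
        for j in range(5):
            a = m.values.iloc[:, j].to_numpy()
            b = out.values.iloc[:, j].to_numpy()
            assert (np.argsort(a, kind="stable") == np.argsort(b, kind="stable")).all()

    def test_ties_get_mean_of_rank_range(self):
        # sorted columns [1,1,5] and [3,4,7] give reference [2, 2.5, 6];
        # the tie at ranks 0-1 of column 0 takes mean(2, 2.5) = 2.25
        out = quantile_normalize(_mat([[1, 3], [1, 4], [5, 7]]))
        col0 = out.values.iloc[:, 0].to_numpy()
        np.testing.assert_allclose(col0, [2.25, 2.25, 6.0])

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        m = _mat(rng.standard_normal((50, 4)))
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(once.values.to_numpy(), twice.values.to_numpy(), atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_columns_share_sorted_values(self, seed):
        # defining property: after normalization all columns hold the
        # identical multiset of values (tie-free input)
        rng = np.random.default_rng(seed)
        out = quantile_normalize(_mat(rng.standard_normal((12, 3)))).values.to_numpy()
        for j in range(1, 3):
            np.testing.assert_allclose(np.sort(out[:, 0]), np.sort(out[:, j]))

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            ExpressionMatrix(pd.DataFrame([[1.0, np.nan]], index=["f"], columns=["a", "b"]))


class TestPresenceCalls:
    def test_symmetric_mixture_boundary_at_midpoint(self):
        rng = np.random.default_rng(0)
        low = 4 + 0.5 * rng.standard_normal(500)
        high = 10 + 0.5 * rng.standard_normal(500)
        x = np.concatenate([low, high])
        m = _mat(np.repeat(x[:, None], 3, axis=1))
        calls = call_presence(m)
        p = calls.params
        assert not p.fallback
        boundary = (p.mu_low + p.mu_high) / 2  # equal weights & variance
        assert abs(boundary - 7.0) < 0.2
        below = calls.table["mean_log2"] < boundary - 0.01
        above = calls.table["mean_log2"] > boundary + 0.01
        assert (calls.table.loc[below, "call"] == "absent").all()
        assert (calls.table.loc[above, "call"] == "present").all()

    def test_calls_monotone_in_mean(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([3 + rng.standard_normal(200), 9 + rng.standard_normal(200)])
        calls = call_presence(_mat(np.repeat(x[:, None], 2, axis=1)))
        tbl = calls.table.sort_values("mean_log2")
        seq = (tbl["call"] == "present").to_numpy()
        # once present, always present at higher mean
        first_present = np.argmax(seq) if seq.any() else len(seq)
        assert seq[first_present:].all()

    def test_six_sigma_separation_recovers_planted_labels(self):
        rng = np.random.default_rng(3)
        n, frac_absent, sigma = 1000, 0.3, 0.5
        absent = rng.random(n) < frac_absent
        # component means 6 sigma apart
        means = np.where(absent, 8.0 - 6 * sigma, 8.0) + sigma * rng.standard_normal(n)
        m = _mat(np.repeat(means[:, None], 4, axis=1))
        calls = call_presence(m)
        match = (calls.table["call"].to_numpy() == np.where(absent, "absent", "present")).mean()
        assert match >= 0.99

    def test_degenerate_single_cluster_falls_back(self):
        x = np.full(100, 5.0)
        with pytest.warns(RuntimeWarning, match="median"):
            calls = call_presence(_mat(np.repeat(x[:, None], 2, axis=1)))
        assert calls.params.fallback

    def test_too_few_features_rejected(self):
        with pytest.raises(ValueError):
            call_presence(_mat(np.ones((5, 3))))


class TestPresenceFilter:
    def test_mrna_filtered_to_present(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([3 + 0.3 * rng.standard_normal(100), 9 + 0.3 * rng.standard_normal(300)])
        m = _mat(np.repeat(x[:, None], 2, axis=1))
        calls = call_presence(m)
        out = apply_presence_filter(m, calls)
        assert out.n_features == len(calls.present_ids)
        assert 250 < out.n_features < 350

    def test_mirna_passes_unfiltered(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([3 + 0.3 * rng.standard_normal(50), 9 + 0.3 * rng.standard_normal(50)])
        m = _mat(np.repeat(x[:, None], 2, axis=1), kind=MIRNA)
        calls = call_presence(m)
        out = apply_presence_filter(m, calls)
        assert out.values.equals(m.values)

    def test_mismatched_features_rejected(self):
        rng = np.random.default_rng(6)
        m = _mat(rng.standard_normal((20, 3)))
        calls = call_presence(_mat(np.concatenate(
            [np.full(10, 3.0), np.full(10, 9.0)])[:, None] @ np.ones((1, 3))))
        other = _mat(rng.standard_normal((21, 3)))
        with pytest.raises(ValueError):
            apply_presence_filter(other, calls)
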