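import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from restfc import (
    PearsonConnectivity,
    SymmetricEdgeMatrix,
    global_mean_fc,
    group_mean_fc,
    mad_outliers,
    pearson_fc,
)


def brute_force_pearson(values):
    """Definitional oracle: mean-centred dot products."""
    x = values - values.mean(axis=0)
    n = x.shape[1]
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            out[i, j] = (x[:, i] @ x[:, j]) / np.sqrt(
                (x[:, i] @ x[:, i]) * (x[:, j] @ x[:, j])
            )
    return out


class TestPearsonFC:
    def test_identical_columns_r_one(self, make_ts):
        ts = make_ts(np.column_stack([[1, 2, 5, 3]] * 2))
        assert pearson_fc(ts).values[0, 1] == pytest.approx(1.0)

    def test_negated_column_r_minus_one(self, make_ts):
        x = np.array([1.0, 2, 5, 3])
        ts = make_ts(np.column_stack([x, -x]))
        assert pearson_fc(ts).values[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_value(self, make_ts):
        # centred dot product 4, each centred norm^2 = 5 -> r = 4/5
        ts = make_ts(np.column_stack([[1, 2, 3, 4], [1, 3, 2, 4]]))
        assert pearson_fc(ts).values[0, 1] == pytest.approx(0.8)

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(100):
            values = rng.normal(size=(10, 6))
            ts_fc = pearson_fc(
                __import__("restfc").RoiTimeSeriesMatrix(
                    "s", tuple("ABCDEF"), values, 3.0
                )
            )
            np.testing.assert_allclose(
                ts_fc.values, brute_force_pearson(values), atol=1e-12
            )

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        scale=st.floats(0.01, 100),
        offset=st.floats(-50, 50),
    )
    def test_affine_invariance_positive_slope(self, seed, scale, offset):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(12, 4))
        rescaled = values.copy()
        rescaled[:, 2] = scale * rescaled[:, 2] + offset
        from restfc import RoiTimeSeriesMatrix

        a = pearson_fc(RoiTimeSeriesMatrix("s", tuple("WXYZ"), values, 3.0))
        b = pearson_fc(RoiTimeSeriesMatrix("s", tuple("WXYZ"), rescaled, 3.0))
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_constant_column_rejected(self, make_ts):
        with pytest.raises(ValueError, match="constant"):
            pearson_fc(make_ts([[1, 2], [1, 3], [1, 5]]))


class TestGlobalMeanFC:
    def _fc(self, values):
        return SymmetricEdgeMatrix(
            tuple(f"R{i}" for i in range(values.shape[0])), values, "pearson_r"
        )

    def test_two_by_two(self):
        m = self._fc(np.array([[1.0, 0.5], [0.5, 1.0]]))
        assert global_mean_fc(m) == pytest.approx(0.5)

    def test_identity_is_zero(self):
        assert global_mean_fc(self._fc(np.eye(3))) == 0.0

    def test_equals_upper_triangle_enumeration(self, rng):
        corr = np.corrcoef(rng.normal(size=(40, 4)), rowvar=False)
        np.fill_diagonal(corr, 1.0)
        m = self._fc(corr)
        manual = np.mean([corr[i, j] for i in range(4) for j in range(i + 1, 4)])
        assert global_mean_fc(m) == pytest.approx(manual, abs=1e-14)


class TestGroupMeanFC:
    def _fc_with_edge(self, r):
        v = np.array([[1.0, r], [r, 1.0]])
        return SymmetricEdgeMatrix(("A", "B"), v, "pearson_r")

    def test_identical_subjects_zero_sd(self):
        mats = {"G": [self._fc_with_edge(0.4), self._fc_with_edge(0.4)]}
        mean, sd = group_mean_fc(mats)["G"]
        np.testing.assert_allclose(sd, 0.0, atol=1e-15)

    def test_hand_computed_mean_sd(self):
        mats = {"G": [self._fc_with_edge(r) for r in (0.1, 0.2, 0.3)]}
        mean, sd = group_mean_fc(mats)["G"]
        assert mean[0, 1] == pytest.approx(0.2)
        assert sd[0, 1] == pytest.approx(0.1)

    def test_single_subject_group_rejected(self):
        with pytest.raises(ValueError, match="need >= 2"):
            group_mean_fc({"G": [self._fc_with_edge(0.1)]})


class TestMadOutliers:
    def test_hand_computed_flag(self):
        mask = mad_outliers([10, 12, 11, 30], ["a", "b", "c", "d"])
        assert mask.excluded_subject_ids == frozenset({"d"})

    def test_all_equal_nothing_flagged(self, caplog):
        mask = mad_outliers([5, 5, 5, 5])
        assert not mask.excluded_subject_ids

    def test_degenerate_mad_flags_off_median(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="restfc.connectivity"):
            mask = mad_outliers([5, 5, 5, 9], ["a", "b", "c", "d"])
        assert mask.excluded_subject_ids == frozenset({"d"})
        assert any("degenerate" in r.message for r in caplog.records)

    def test_clean_symmetric_sample_empty(self):
        assert not mad_outliers([1, 2, 3, 4, 5]).excluded_subject_ids

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_removal_never_increases_sd(self, seed):
        rng = np.random.default_rng(seed)
        x = np.concatenate([rng.normal(size=10), rng.normal(8, 1, size=2)])
        mask = mad_outliers(x, [str(i) for i in range(12)])
        kept = np.array(
            [v for i, v in enumerate(x) if str(i) not in mask.excluded_subject_ids]
        )
        if kept.size >= 2:
            assert kept.std(ddof=1) <= x.std(ddof=1) + 1e-12


class TestPearsonConnectivityEstimator:
    def test_vectorized_output_matches_function(self, rng, make_ts):
        xs = [rng.normal(size=(30, 4)) for _ in range(3)]
        feats = PearsonConnectivity().fit(xs).transform(xs)
        assert feats.shape == (3, 6)
        manual = pearson_fc(make_ts(xs[0])).upper_triangle()
        np.testing.assert_allclose(feats[0], manual, atol=1e-12)

    def test_composes_in_sklearn_pipeline(self, rng):
        from sklearn.pipeline import Pipeline

        from restfc import EdgewiseAnovaScreen

        xs = [rng.normal(size=(40, 4)) for _ in range(8)]
        y = np.array(["A"] * 4 + ["B"] * 4)
        pipe = Pipeline(
            [("fc", PearsonConnectivity()), ("screen", EdgewiseAnovaScreen())]
        )
        pipe.fit(xs, y)
        assert pipe.named_steps["screen"].p_.shape == (6,)
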