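import numpy as np
import pandas as pd
import pytest

from restfc import (
    CohortManifest,
    EdgewiseAnovaScreen,
    GeneratorConfig,
    ManifestEntry,
    SymmetricEdgeMatrix,
    edgewise_screen,
    one_way_anova,
    posthoc_pairwise,
    scalar_anova_table,
    simulate_cohort,
)


class TestOneWayAnova:
    def test_identical_means_f_zero(self):
        res = one_way_anova([[1, 2, 3], [2, 1, 3]])
        assert res.f == 0.0 and res.p == 1.0

    def test_hand_decomposition(self):
        res = one_way_anova([[1, 2], [3, 4]])
        assert res.f == pytest.approx(8.0)
        assert (res.df_between, res.df_within) == (1, 2)
        assert res.p == pytest.approx(0.10557, abs=1e-4)

    def test_within_group_permutation_invariance(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=5)
        r1 = one_way_anova([a, b])
        r2 = one_way_anova([rng.permutation(a), rng.permutation(b)])
        assert r1.f == pytest.approx(r2.f, rel=1e-12)
        assert r1.p == pytest.approx(r2.p, rel=1e-12)

    def test_matches_scipy_reference_on_random_data(self, rng):
        from scipy.stats import f_oneway

        for _ in range(1000):
            groups = [rng.normal(size=rng.integers(3, 8)) for _ in range(rng.integers(2, 5))]
            ours = one_way_anova(groups)
            ref = f_oneway(*groups)
            assert ours.f == pytest.approx(ref.statistic, abs=1e-9, rel=1e-9)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_zero_within_variance_degenerate(self):
        res = one_way_anova([[1, 1], [2, 2]])
        assert res.p == 0.0 and res.degenerate


class TestPosthocPairwise:
    def _four_groups(self, rng):
        return [rng.normal(loc=m, size=6) for m in (0, 0.1, 0.2, 3.0)]

    def test_four_groups_six_comparisons(self, rng):
        groups = self._four_groups(rng)
        comps = posthoc_pairwise(groups, list("ABCD"), one_way_anova(groups))
        assert len(comps) == 6

    def test_bonferroni_arithmetic_and_clamp(self, rng):
        groups = self._four_groups(rng)
        comps = posthoc_pairwise(groups, list("ABCD"), one_way_anova(groups))
        for c in comps:
            assert c.p_adjusted == pytest.approx(min(1.0, c.p_raw * 6))
            assert c.p_adjusted >= c.p_raw

    def test_direction_sign_matches_means(self, rng):
        groups = [[0.0, 0.1, -0.1], [5.0, 5.1, 4.9]]
        comps = posthoc_pairwise(groups, ["lo", "hi"], one_way_anova(groups))
        assert comps[0].pair == ("lo", "hi") and comps[0].direction == -1


def _edge_cohort(data, groups):
    """Wrap an (n_subjects, 2x2-edge) scalar per subject into matrices."""
    entries, mats = [], {}
    for k, (val, g) in enumerate(zip(data, groups)):
        sid = f"s{k}"
        entries.append(ManifestEntry(sid, g, f"{sid}.tsv"))
        v = np.array([[1.0, val], [val, 1.0]])
        mats[sid] = SymmetricEdgeMatrix(("A", "B"), v, "pearson_r")
    manifest = CohortManifest(tuple(entries), tuple(dict.fromkeys(groups)))
    return mats, manifest


class TestEdgewiseScreen:
    def test_duplicated_groups_nothing_significant(self, rng):
        vals = rng.uniform(-0.5, 0.5, size=6)
        data = np.concatenate([vals, vals])
        groups = ["A"] * 6 + ["B"] * 6
        mats, manifest = _edge_cohort(data, groups)
        table = edgewise_screen(mats, manifest)
        assert not table.significant.any()

    def test_planted_shift_found_with_direction(self, rng):
        data = np.concatenate([rng.normal(0.1, 0.05, 10), rng.normal(0.6, 0.05, 10)])
        groups = ["A"] * 10 + ["B"] * 10
        mats, manifest = _edge_cohort(data, groups)
        table = edgewise_screen(mats, manifest)
        top = table.iloc[0]
        assert top.significant
        assert top.pair == "A-B" and top.direction == -1
        assert top.p_posthoc_adj < 0.05

    def test_posthoc_rows_only_for_screened_edges(self, rng):
        data = np.concatenate([rng.normal(0.1, 0.05, 10), rng.normal(0.6, 0.05, 10)])
        groups = ["A"] * 10 + ["B"] * 10
        mats, manifest = _edge_cohort(data, groups)
        table = edgewise_screen(mats, manifest)
        assert (table.loc[table.significant, "pair"] != "").all()
        assert (table.loc[~table.significant, "pair"] == "").all()

    def test_outlier_rescreen_reports_both(self, rng):
        base = rng.normal(0.1, 0.03, 10)
        shifted = rng.normal(0.5, 0.03, 10)
        shifted[0] = 0.2  # outlier inside group B, far beyond 3 scaled MADs
        mats, manifest = _edge_cohort(
            np.concatenate([base, shifted]), ["A"] * 10 + ["B"] * 10
        )
        table = edgewise_screen(mats, manifest, outlier_policy="rescreen")
        sig = table[table.significant]
        assert {"F_post_outlier", "p_post_outlier", "n_excluded"} <= set(sig.columns)
        assert (sig.n_excluded >= 1).all()
        # removing the gross outlier sharpens the group separation
        assert (sig.p_post_outlier <= sig.p).all()

    def test_mixed_metric_kinds_rejected(self, rng):
        mats, manifest = _edge_cohort(
            rng.uniform(0, 0.5, 4), ["A", "A", "B", "B"]
        )
        bad = SymmetricEdgeMatrix(("A", "B"), np.zeros((2, 2)), "sd_across_windows")
        mats["s0"] = bad
        with pytest.raises(ValueError, match="mixed metric"):
            edgewise_screen(mats, manifest)

    def test_family_scope_controls_screen_correction(self, rng):
        cfg = GeneratorConfig(n_per_group={"A": 6, "B": 6}, n_rois=8, seed=21)
        manifest, cohort = simulate_cohort(cfg)
        from restfc.pipeline import stage_fc

        mats = stage_fc(cohort)
        raw = edgewise_screen(mats, manifest, alpha=0.5, family_scope="none")
        corrected = edgewise_screen(mats, manifest, alpha=0.5, family_scope="edges_bonferroni")
        n_edges = 8 * 7 // 2
        np.testing.assert_allclose(
            corrected.drop_duplicates(["roi_i", "roi_j"]).p_screen,
            np.minimum(1.0, raw.drop_duplicates(["roi_i", "roi_j"]).p * n_edges),
        )
        assert corrected.significant.sum() <= raw.significant.sum()


class TestScalarAnovaTable:
    def _manifest(self, groups):
        entries = tuple(
            ManifestEntry(f"s{k}", g, "") for k, g in enumerate(groups)
        )
        return CohortManifest(entries, tuple(dict.fromkeys(groups)))

    def test_identical_groups_no_significant_pairs(self, rng):
        vals = rng.normal(size=8)
        groups = ["A"] * 4 + ["B"] * 4
        records = pd.DataFrame(
            {"subject_id": [f"s{k}" for k in range(8)],
             "m1": np.concatenate([vals[:4], vals[:4]])}
        )
        table = scalar_anova_table(records, self._manifest(groups))
        assert table.significant_pairs.iloc[0] == ""

    def test_planted_shift_flagged_with_direction(self, rng):
        groups = ["A"] * 6 + ["B"] * 6
        records = pd.DataFrame(
            {"subject_id": [f"s{k}" for k in range(12)],
             "m1": np.concatenate([rng.normal(0, 0.1, 6), rng.normal(3, 0.1, 6)])}
        )
        table = scalar_anova_table(records, self._manifest(groups))
        assert table.significant_pairs.iloc[0] == "A<B"

    def test_one_row_per_measure(self, rng):
        groups = ["A"] * 4 + ["B"] * 4
        records = pd.DataFrame(
            {"subject_id": [f"s{k}" for k in range(8)],
             "m1": rng.normal(size=8), "m2": rng.normal(size=8),
             "m3": rng.normal(size=8)}
        )
        assert len(scalar_anova_table(records, self._manifest(groups))) == 3


class TestEdgewiseAnovaScreenEstimator:
    def test_fit_attributes_and_transform(self, rng):
        x = rng.normal(size=(20, 5))
        x[10:, 2] += 2.0
        y = np.array(["A"] * 10 + ["B"] * 10)
        est = EdgewiseAnovaScreen().fit(x, y)
        assert est.p_.shape == (5,)
        assert est.significant_[2]
        assert est.transform(x).shape[1] == est.significant_.sum()

    def test_posthoc_subset_of_uncorrected(self, rng):
        x = rng.normal(size=(24, 4))
        x[:6, 0] += 1.5
        y = np.array(["A"] * 6 + ["B"] * 6 + ["C"] * 6 + ["D"] * 6)
        est = EdgewiseAnovaScreen().fit(x, y)
        comps = est.posthoc(x, y, 0)
        assert len(comps) == 6
        for c in comps:
            if c.p_adjusted < 0.05:
                assert c.p_raw < 0.05

    def test_sklearn_clone(self):
        from sklearn.base import clone

        est = EdgewiseAnovaScreen(alpha=0.01, family_scope="both")
        assert clone(est).get_params() == est.get_params()
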