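"""Segmentation, ROI statistics, longitudinal rates, matching, outlier
screening and the statistical battery."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dscmicro.roi_stats import (
    segment_lesion, ROISpec, extract_roi_stats, normalize_to_reference,
    monthly_relative_change, match_by_age, grubbs_outliers, grubbs_critical,
    hedges_g, welch_anova, dunnett_vs_control, t_test, logistic_regression,
    run_group_comparisons,
)


class TestSegmentLesion:
    def test_volume_arithmetic(self):
        vol = np.zeros((10, 10, 3))
        vol[2:7, 3:5, 1] = 5.0   # 10-voxel blob
        mask, ml = segment_lesion(vol, threshold=1.0, voxel_volume=8.0)
        assert mask.sum() == 10
        assert ml == pytest.approx(0.08)

    def test_threshold_above_max_gives_empty(self):
        mask, ml = segment_lesion(np.ones((4, 4, 2)), threshold=10.0)
        assert not mask.any() and ml == 0.0

    def test_min_component_filter(self):
        vol = np.zeros((20, 20, 1))
        vol[1:6, 1:11, 0] = 2.0   # 50-voxel blob
        vol[15, 10:15, 0] = 2.0   # 5-voxel blob
        mask, _ = segment_lesion(vol, threshold=1.0, min_component=10)
        assert mask.sum() == 50
        assert not mask[15, 10:15, 0].any()

    def test_non_finite_map_rejected(self):
        vol = np.full((3, 3, 1), np.nan)
        with pytest.raises(ValueError):
            segment_lesion(vol, threshold=0.0)


class TestRoiExtraction:
    def test_constant_map(self):
        maps = {"cbf": np.full((6, 6, 2), 2.0)}
        m = np.zeros((6, 6, 2), dtype=bool)
        m[1:3, 1:3, 0] = True
        res = extract_roi_stats(maps, [ROISpec("r1", mask=m)])
        assert res[0].mean == 2.0 and res[0].sd == 0.0 and res[0].n_voxels == 4

    def test_hand_computed_mean(self):
        rng = np.random.default_rng(2)
        vol = rng.normal(size=(5, 5, 2))
        m = np.zeros_like(vol, dtype=bool)
        m[0, :, 0] = True
        res = extract_roi_stats({"x": vol}, [ROISpec("r", mask=m)])
        assert res[0].mean == pytest.approx(vol[0, :, 0].mean(), abs=1e-12)

    def test_bilateral_pooling(self):
        vol = np.zeros((4, 4, 1))
        vol[0, 0, 0] = 1.0
        vol[3, 3, 0] = 3.0
        left = np.zeros_like(vol, dtype=bool); left[0, 0, 0] = True
        right = np.zeros_like(vol, dtype=bool); right[3, 3, 0] = True
        res = extract_roi_stats(
            {"x": vol}, [ROISpec("bi", mask=left, mask_contralateral=right)])
        assert res[0].mean == 2.0 and res[0].n_voxels == 2

    def test_empty_roi_named_in_error(self):
        with pytest.raises(ValueError, match="r9"):
            extract_roi_stats({"x": np.full((3, 3, 1), np.nan)},
                              [ROISpec("r9", mask=np.ones((3, 3, 1), bool))])


class TestNormalization:
    def test_simple_ratio(self):
        from dscmicro.roi_stats import ROIResult
        v = ROIResult("lesion", "kapp", mean=3.0, sd=0.1, n_voxels=24)
        refs = [ROIResult(f"ref{i}", "kapp", 2.0, 0.1, 24) for i in range(9)]
        assert normalize_to_reference(v, refs) == pytest.approx(1.5)

    def test_nine_roi_self_normalization_averages_one(self):
        rng = np.random.default_rng(3)
        vol = rng.uniform(1.0, 3.0, size=(12, 12, 1))
        rois = []
        for i in range(9):
            m = np.zeros_like(vol, dtype=bool)
            m[i, 2:6, 0] = True
            rois.append(ROISpec(f"ref{i}", mask=m))
        res = extract_roi_stats({"cbf": vol}, rois)
        rel = [normalize_to_reference(r, res) for r in res]
        assert np.mean(rel) == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_reference_rejected(self):
        from dscmicro.roi_stats import ROIResult
        v = ROIResult("a", "m", 1.0, 0.0, 4)
        refs = [ROIResult("r", "m", -2.0, 0.0, 4)]
        with pytest.raises(ValueError):
            normalize_to_reference(v, refs)


class TestMonthlyRelativeChange:
    def test_ten_percent_per_month(self):
        # 10 -> 13 mL over 3.0 months (91.32 d): +10 %/month
        rates = monthly_relative_change([0.0, 91.32], [10.0, 13.0])
        assert rates[0] == pytest.approx(10.0, rel=1e-9)

    def test_constant_series_zero(self):
        rates = monthly_relative_change([0, 30, 60], [5.0, 5.0, 5.0])
        np.testing.assert_allclose(rates, 0.0)

    def test_unit_invariance(self):
        d = [0.0, 40.0, 100.0]
        v = np.array([8.0, 9.5, 7.0])
        np.testing.assert_allclose(monthly_relative_change(d, v),
                                   monthly_relative_change(d, 1000 * v))

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = rng.integers(2, 6)
            days = np.sort(rng.uniform(0, 700, n))
            while np.any(np.diff(days) <= 0):
                days = np.sort(rng.uniform(0, 700, n))
            vals = rng.uniform(1.0, 20.0, n)
            rates = monthly_relative_change(days, vals)
            for i in range(n - 1):
                months = (days[i + 1] - days[i]) / 30.44
                expected = 100.0 * (vals[i + 1] - vals[i]) / vals[i] / months
                assert rates[i] == pytest.approx(expected, rel=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            monthly_relative_change([0, 0], [1.0, 2.0])
        with pytest.raises(ValueError):
            monthly_relative_change([0, 30], [0.0, 2.0])


class TestAgeMatching:
    def test_exact_pairing(self):
        pairs, mean, sd = match_by_age([5.0, 9.0], [9.0, 5.0])
        assert dict(pairs) == {0: 1, 1: 0}
        assert mean == 0.0 and sd == 0.0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            n_case = int(rng.integers(2, 5))
            n_ctrl = int(rng.integers(n_case, 7))
            cases = rng.uniform(3, 15, n_case)
            ctrls = rng.uniform(3, 15, n_ctrl)
            pairs, _, _ = match_by_age(cases, ctrls)
            total = sum(abs(cases[i] - ctrls[j]) for i, j in pairs)
            best = min(
                sum(abs(cases[i] - ctrls[p[i]]) for i in range(n_case))
                for p in itertools.permutations(range(n_ctrl), n_case)
            )
            assert total == pytest.approx(best, abs=1e-12)

    def test_never_worse_than_greedy(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            cases = rng.uniform(3, 15, 6)
            ctrls = rng.uniform(3, 15, 9)
            pairs, _, _ = match_by_age(cases, ctrls)
            total = sum(abs(cases[i] - ctrls[j]) for i, j in pairs)
            # greedy nearest neighbour in case order
            avail = list(range(len(ctrls)))
            greedy = 0.0
            for i in range(len(cases)):
                j = min(avail, key=lambda j: abs(cases[i] - ctrls[j]))
                greedy += abs(cases[i] - ctrls[j])
                avail.remove(j)
            assert total <= greedy + 1e-12

    def test_empty_cases_rejected(self):
        with pytest.raises(ValueError):
            match_by_age([], [5.0])


class TestGrubbs:
    def test_single_gross_outlier_removed(self):
        # G = (12 - 3.75)/5.50 = 1.4998 > crit(4, .05) = 1.4813: remove;
        # then G = 1.0 < crit(3, .05) = 1.1543: stop
        kept, removed = grubbs_outliers([1.0, 1.1, 0.9, 12.0])
        assert removed == [3]
        assert sorted(kept) == [0.9, 1.0, 1.1]

    def test_tight_cluster_untouched(self):
        kept, removed = grubbs_outliers([1.0, 1.01, 0.99, 1.02])
        assert removed == []

    def test_identical_values_untouched(self):
        kept, removed = grubbs_outliers([2.0, 2.0, 2.0, 2.0])
        assert removed == [] and len(kept) == 4

    def test_critical_value_monotone_in_n(self):
        crits = [grubbs_critical(n, 0.05) for n in range(3, 30)]
        assert np.all(np.diff(crits) > 0)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            grubbs_outliers([1.0, 2.0])


class TestHedgesG:
    def test_identical_groups_zero(self):
        assert hedges_g([1, 2, 3], [1, 2, 3]) == 0.0

    def test_zero_pooled_sd_sentinel(self):
        assert np.isnan(hedges_g([0.0, 0.0], [1.0, 1.0]))

    def test_small_sample_correction_direction(self):
        # g is shrunk relative to the uncorrected d
        a = [0.0, 1.0, 2.0, 3.0]
        b = [2.0, 3.0, 4.0, 5.0]
        d = (np.mean(a) - np.mean(b)) / np.sqrt(
            (np.var(a, ddof=1) + np.var(b, ddof=1)) / 2)
        assert abs(hedges_g(a, b)) < abs(d)


class TestBattery:
    def test_welch_anova_matches_r_oneway(self):
        # frozen oracle from R: oneway.test(..., var.equal=FALSE)
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.5, 2, 10)
        c = rng.normal(1, 0.5, 6)
        r = welch_anova([a, b, c])
        assert r.statistic == pytest.approx(14.633827, abs=1e-5)
        assert r.dof == pytest.approx(13.858809, abs=1e-5)
        assert r.p_value == pytest.approx(0.0003834, abs=1e-6)

    def test_dunnett_orders_p_values_sensibly(self):
        rng = np.random.default_rng(8)
        control = rng.normal(0, 1, 15)
        near = rng.normal(0.1, 1, 15)
        far = rng.normal(2.5, 1, 15)
        res = dunnett_vs_control([near, far], control, names=["near", "far"])
        assert res[1].p_value < res[0].p_value
        assert res[1].p_value < 0.01

    def test_identical_groups_t(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r = t_test(x, x.copy())
        assert r.estimate == 0.0 and r.p_value == pytest.approx(1.0)

    def test_logistic_odds_ratio_matches_cross_product(self):
        # 2x2 table: x=0 -> 10/30 odds; x=1 -> 18/12 odds; OR = 4.5
        x = np.r_[np.zeros(40), np.ones(30)]
        y = np.r_[np.zeros(30), np.ones(10), np.zeros(12), np.ones(18)]
        r = logistic_regression(x, y)
        assert r.estimate == pytest.approx(4.5, rel=1e-4)
        assert r.p_value < 0.01

    def test_logistic_separation_flagged(self):
        x = np.r_[-np.ones(10) - np.arange(10), np.ones(10) + np.arange(10)]
        y = np.r_[np.zeros(10), np.ones(10)]
        r = logistic_regression(x, y)
        assert "separation" in r.note

    def test_mixed_effects_detects_within_subject_trend(self):
        from dscmicro.synthgen import CohortDesign, make_cohort

        df = make_cohort(CohortDesign(seed=21))
        gt = df[df.group == "GT"]
        out = run_group_comparisons(gt, [
            {"name": "rth_trend", "test": "mixed", "metric": "rth",
             "fixed": "visit_day"},
        ])
        row = out.iloc[0]
        assert row["estimate"] < 0          # treatment lowers RTH over time
        assert row["p_value"] < 0.05
        assert "MixedLM" in row["note"]

    def test_plan_runner_and_errors(self):
        df = pd.DataFrame({
            "group": ["A"] * 6 + ["B"] * 6,
            "visit_day": [0, 0, 0, 730, 730, 730] * 2,
            "rth": [1.1, 1.2, 1.15, 0.9, 0.95, 1.0,
                    1.1, 1.05, 1.2, 1.12, 1.08, 1.18],
            "vcn": [0.5, 1.0, 2.0] * 4,
        })
        out = run_group_comparisons(df, [
            {"name": "a_vs_b", "test": "t", "metric": "rth",
             "groups": ["A", "B"], "visit_day_a": 730, "visit_day_b": 730},
            {"name": "slope", "test": "ols", "metric": "rth", "x": "vcn"},
        ])
        assert set(out["name"]) == {"a_vs_b", "slope"}
        assert ((out["p_value"] >= 0) & (out["p_value"] <= 1)).all()
        with pytest.raises(KeyError):
            run_group_comparisons(df, [{"test": "t", "metric": "nope",
                                        "groups": ["A", "B"]}])
        with pytest.raises(ValueError):
            run_group_comparisons(df, [{"test": "welch_anova",
                                        "metric": "rth", "groups": ["A"]}])
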